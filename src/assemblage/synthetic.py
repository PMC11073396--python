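"""Synthetic multi-lake, multi-polymer, multi-timepoint community generator.

Emulates a plastisphere colonization experiment: pellets of several polymer
types incubated in contrasting lakes and collected at a series of
colonization times, alongside particle-associated (WP) and free-living (WF)
water-community samples. The generator's defaults reproduce the study
design arithmetic: 4 lakes x 8 polymers x 5 days = 160 plastisphere samples
plus 4 lakes x 5 days x 2 fractions = 40 water samples.

Mechanism
---------
Each lake has a species pool drawn from a shared mother composition; the
``pool_divergence`` knob controls how far lake pools sit from one another.
A plastisphere sample on polymer *p* in lake *l* at day *t* has an
effective composition

    pi(t) = (1 - m(t)) * start(l, p) + m(t) * attractor,   m(t) = 1 - exp(-kappa * t)

where ``start(l, p)`` is the lake pool tilted by a polymer-specific
enrichment and ``attractor`` is a single mature-biofilm composition shared
by all lakes — so ``kappa > 0`` encodes cross-lake, cross-polymer
convergent succession as testable ground truth, and ``kappa = 0`` disables
it.

Assembly regimes modify how counts are realised from pi(t):

* ``neutral`` — two-stage stochastic assembly: taxa enter the sample by a
  uniform draw without replacement (membership is pure chance, carrying no
  phylogenetic or abundance information), then sequencing depth is filled
  multinomially proportional to pi among the members. Occupancy is flat in
  expectation and abundances mirror the regional pool, which is exactly
  the structure a Raup–Crick style assembly null assumes — so null models
  should stay calibrated on neutral data.
* ``homogeneous_selection`` — the plastisphere environment filters: each
  plastisphere sample's composition is concentrated onto the tips of one
  clade (log-scale strength sigma) before assembly, so biofilm communities
  are phylogenetically clustered far beyond a tip-shuffle null. Water
  communities remain diverse — they are the regional source pool — which
  is what gives the null its contrast.
* ``dispersal_limitation`` — each sample instead occupies a uniformly
  random taxon subset with its own spiky (low-concentration Dirichlet)
  abundances: membership is phylogenetically random, but pairs of samples
  are far more dissimilar than a common-pool assembly null expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skbio import TreeNode

from .io_core import (
    AbundanceTable,
    ENV_VARIABLES,
    PLASTISPHERE,
    SampleMetadata,
    WATER_SENTINEL,
)

import pandas as pd

DEFAULT_POLYMERS = ("PP", "PE", "PVC", "PS", "PLA", "PHA", "PBS", "PBAT")
DEFAULT_DAYS = (3, 7, 15, 30, 60)
REGIMES = ("neutral", "homogeneous_selection", "dispersal_limitation")


@dataclass
class DesignConfig:
    """Sampling design. Defaults reproduce the study arithmetic:
    160 plastisphere + 40 water samples."""

    n_lakes: int = 4
    polymers: tuple[str, ...] = DEFAULT_POLYMERS
    days: tuple[int, ...] = DEFAULT_DAYS
    water_fractions: tuple[str, ...] = ("WP", "WF")
    n_taxa: int = 300
    sequencing_depth: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lakes < 1 or self.n_taxa < 2 or self.sequencing_depth < 1:
            raise ValueError("invalid design configuration")

    @property
    def lakes(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_lakes)]


@dataclass
class RegimeConfig:
    """Ecological ground truth for the generated communities.

    pool_divergence  — between-lake pool contrast (0 = identical pools)
    convergence_rate — kappa, per-day mixing toward the shared attractor
    polymer_effect   — sd of the per-polymer log-enrichment tilt
    assembly_regime  — neutral | homogeneous_selection | dispersal_limitation
    selection_strength — sigma, log-scale clade mass concentration
    env_coupling     — rho in [0,1], share of environmental variance tied
                       to the lake/day structure
    richness_fraction / dispersal params are generator internals with
    field-plausible defaults.
    """

    pool_divergence: float = 1.0
    convergence_rate: float = 0.03
    polymer_effect: float = 1.0
    assembly_regime: str = "neutral"
    selection_strength: float = 6.0
    env_coupling: float = 0.6
    richness_fraction: float = 0.1
    pool_concentration: float = 1.0
    dispersal_richness_fraction: float = 0.25
    dispersal_evenness: float = 0.15

    def __post_init__(self) -> None:
        for name in ("pool_divergence", "convergence_rate", "polymer_effect",
                     "selection_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.env_coupling <= 1:
            raise ValueError("env_coupling must lie in [0, 1]")
        if self.assembly_regime not in REGIMES:
            raise ValueError(
                f"assembly_regime must be one of {REGIMES}, got "
                f"'{self.assembly_regime}'"
            )


def generate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Random rooted bifurcating tree by a pure-birth construction.

    Starting from two lineages, each split event follows an exponential(1)
    waiting time during which every active branch elongates; a uniformly
    chosen active lineage then bifurcates. Deterministic given seed.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None, length=None)
    a, b = TreeNode(name=None, length=0.0), TreeNode(name=None, length=0.0)
    root.extend([a, b])
    active = [a, b]
    while len(active) < n_taxa:
        dt = rng.exponential(1.0)
        for node in active:
            node.length += dt
        k = rng.integers(len(active))
        parent = active.pop(k)
        c1, c2 = TreeNode(name=None, length=0.0), TreeNode(name=None, length=0.0)
        parent.extend([c1, c2])
        active.extend([c1, c2])
    dt = rng.exponential(1.0)
    for node in active:
        node.length += dt
    # label tips in a stable traversal order
    for i, tip in enumerate(root.tips()):
        tip.name = f"ASV{i + 1:04d}"
    return root


def _clade_mask(tree: TreeNode, n_taxa: int, lo_fraction: float = 0.12,
                hi_fraction: float = 0.25) -> np.ndarray:
    """Boolean mask over tip order selecting the favoured clade.

    Homogeneous selection is modelled as a filter on a conserved trait, so
    among clades whose tip count falls in [lo, hi] x n_taxa the
    phylogenetically tightest one (smallest mean within-clade patristic
    distance) is favoured; when no clade lands in the window the one
    closest to the window midpoint is used.
    """
    tip_names = [t.name for t in tree.tips()]
    index = {n: i for i, n in enumerate(tip_names)}
    dm = tree.tip_tip_distances()
    pos = {n: i for i, n in enumerate(dm.ids)}
    lo = max(2, int(lo_fraction * n_taxa))
    hi = max(lo, int(hi_fraction * n_taxa))
    best, best_score = None, np.inf
    for node in tree.non_tips():
        names = [t.name for t in node.tips()]
        if not (lo <= len(names) <= hi):
            continue
        ix = [pos[n] for n in names]
        score = dm.data[np.ix_(ix, ix)].mean()
        if score < best_score:
            best, best_score = names, score
    if best is None:
        target = 0.5 * (lo + hi)
        for node in tree.non_tips():
            names = [t.name for t in node.tips()]
            if len(names) >= n_taxa:
                continue
            gap = abs(len(names) - target)
            if gap < best_score:
                best, best_score = names, gap
    mask = np.zeros(n_taxa, dtype=bool)
    mask[[index[n] for n in best]] = True
    return mask


@dataclass
class StudyTruth:
    """Ground-truth record written alongside generated data."""

    design: dict = field(default_factory=dict)
    regime: dict = field(default_factory=dict)
    clade_taxa: list[str] = field(default_factory=list)


def _draw_richness(rng: np.random.Generator, fraction: float, n: int) -> int:
    """Per-sample richness: Poisson around fraction * n, clipped to [2, n]."""
    return int(min(n, max(2, rng.poisson(fraction * n))))


def generate_study(
    design: DesignConfig, regime: RegimeConfig
) -> tuple[AbundanceTable, SampleMetadata, TreeNode, pd.DataFrame, StudyTruth]:
    """Generate (table, metadata, tree, env, truth) for one kingdom's survey."""
    rng = np.random.default_rng(design.seed)
    n = design.n_taxa
    tree = generate_tree(n, seed=int(rng.integers(2**31 - 1)))
    taxa = [t.name for t in tree.tips()]

    # mother composition: Dirichlet(pool_concentration); 1.0 is the uniform
    # simplex prior, values < 1 give heavier-tailed rank-abundance curves
    mother = rng.dirichlet(np.full(n, regime.pool_concentration))
    clade_taxa: list[str] = []
    clade_tilt = np.ones(n)
    if regime.assembly_regime == "homogeneous_selection":
        mask = _clade_mask(tree, n)
        clade_tilt = np.where(mask, np.exp(regime.selection_strength), 1.0)
        clade_taxa = [t for t, m in zip(taxa, mask) if m]

    # lake pools around the mother; attractor shared by all lakes
    pools = {}
    for lake in design.lakes:
        if regime.pool_divergence == 0:
            pools[lake] = mother.copy()
        else:
            conc = mother * (500.0 / regime.pool_divergence) + 1e-9
            pools[lake] = rng.dirichlet(conc)
    if regime.pool_divergence == 0:
        attractor = mother.copy()
    else:
        attractor = rng.dirichlet(mother * 500.0 + 1e-9)

    # polymer enrichment tilts, shared across lakes
    poly_tilt = {
        p: np.exp(regime.polymer_effect * rng.standard_normal(n))
        for p in design.polymers
    }
    frac_tilt = {
        f: np.exp(0.3 * rng.standard_normal(n)) for f in design.water_fractions
    }

    # membership preference fields: who colonizes (incidence) carries the
    # same lake/polymer/attractor structure as the composition, eroding as
    # the community mixes toward the attractor. Polymer surfaces select
    # their early colonizers; a mature biofilm recruits the attractor's
    # taxa regardless of polymer. With all effect knobs at zero every
    # field is flat and membership reduces to a uniform draw.
    lake_logw = {lake: regime.pool_divergence * rng.standard_normal(n)
                 for lake in design.lakes}
    poly_logw = {p: regime.polymer_effect * rng.standard_normal(n)
                 for p in design.polymers}
    attr_logw = rng.standard_normal(n)
    # universal successional drift: a Brownian field on the stage clock
    # u = kappa * t, shared by every lake and polymer. Communities keep
    # turning species over along one successional path (driving time-decay
    # of similarity) without re-diverging across polymers or lakes.
    stage_logw = {}
    walk = np.zeros(n)
    u_prev = 0.0
    for day in sorted(design.days):
        u = regime.convergence_rate * day
        walk = walk + np.sqrt(max(u - u_prev, 0.0)) * rng.standard_normal(n)
        stage_logw[day] = walk.copy()
        u_prev = u

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    columns: list[np.ndarray] = []

    def draw_sample(pi: np.ndarray, logw: np.ndarray | None,
                    plastisphere: bool) -> np.ndarray:
        """Realise counts from an effective composition per the regime.

        ``logw`` is the sample's membership log-preference field (None for
        a flat field). The assembly regime shapes plastisphere (biofilm)
        samples only; water samples are always neutral draws from their
        composition — they are the diverse regional source communities.
        """
        regime_here = regime.assembly_regime if plastisphere else "neutral"
        if regime_here == "dispersal_limitation":
            r = _draw_richness(rng, regime.dispersal_richness_fraction, n)
            members = rng.choice(n, size=r, replace=False)
            weights = rng.dirichlet(np.full(r, regime.dispersal_evenness))
        elif regime_here == "homogeneous_selection":
            # the same environmental filter acts on every sample: membership
            # is drawn (near-)uniformly from the favoured clade's tips, so
            # each sample establishes its own subset of close relatives;
            # abundances still follow the regional composition
            w = clade_tilt / clade_tilt.sum()
            r = _draw_richness(rng, regime.richness_fraction, n)
            members = rng.choice(n, size=r, replace=False, p=w)
            weights = pi[members] / pi[members].sum()
        else:
            # neutral: membership follows the preference field (uniform
            # chance when the field is flat), abundances follow the pool
            r = _draw_richness(rng, regime.richness_fraction, n)
            if logw is None or not np.any(logw):
                members = rng.choice(n, size=r, replace=False)
            else:
                w = np.exp(logw - logw.max())
                members = rng.choice(n, size=r, replace=False, p=w / w.sum())
            weights = pi[members] / pi[members].sum()
        counts = np.zeros(n, dtype=np.int64)
        counts[members] = 1
        extra = rng.multinomial(design.sequencing_depth - r, weights)
        counts[members] += extra
        return counts

    for lake in design.lakes:
        for polymer in design.polymers:
            start = pools[lake] * poly_tilt[polymer]
            start /= start.sum()
            for day in design.days:
                m = 1.0 - np.exp(-regime.convergence_rate * day)
                pi = (1.0 - m) * start + m * attractor
                logw = ((1.0 - m) * (lake_logw[lake] + poly_logw[polymer])
                        + m * attr_logw + stage_logw[day])
                sid = f"{lake}_{polymer}_d{day:02d}"
                sample_ids.append(sid)
                meta_rows.append(
                    dict(sample_id=sid, lake=lake, day=day, polymer=polymer,
                         fraction=PLASTISPHERE)
                )
                columns.append(draw_sample(pi, logw, True))
        for frac in design.water_fractions:
            wpi = pools[lake] * frac_tilt[frac]
            wpi /= wpi.sum()
            for day in design.days:
                sid = f"{lake}_{frac}_d{day:02d}"
                sample_ids.append(sid)
                meta_rows.append(
                    dict(sample_id=sid, lake=lake, day=day,
                         polymer=WATER_SENTINEL, fraction=frac)
                )
                columns.append(draw_sample(wpi, lake_logw[lake], False))

    table = AbundanceTable(taxa, sample_ids, np.column_stack(columns))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    env = _generate_env(design, regime, rng)
    truth = StudyTruth(design=asdict(design), regime=asdict(regime),
                       clade_taxa=clade_taxa)
    return table, metadata, tree, env, truth


def _generate_env(design: DesignConfig, regime: RegimeConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Environmental variables per (lake, day), coupled to the lake/day
    structure with weight rho and white noise with weight 1 - rho."""
    rho = regime.env_coupling
    rows = []
    lake_base = {lake: rng.standard_normal(len(ENV_VARIABLES))
                 for lake in design.lakes}
    trend = rng.standard_normal(len(ENV_VARIABLES))
    day_scale = max(design.days)
    for lake in design.lakes:
        for day in design.days:
            signal = lake_base[lake] + trend * (day / day_scale)
            noise = rng.standard_normal(len(ENV_VARIABLES))
            values = rho * signal + (1.0 - rho) * noise
            rows.append({"lake": lake, "day": day,
                         **dict(zip(ENV_VARIABLES, values))})
    return pd.DataFrame(rows)
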