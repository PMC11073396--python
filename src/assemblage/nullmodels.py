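"""Phylogenetic and taxonomic null models for community assembly inference.

The workflow classifies every within-group sample pair into one of five
ecological assembly processes:

1. betaMNTD — abundance-weighted mean distance from each taxon in one
   community to its nearest phylogenetic neighbour in the other.
2. betaNTI — z-score of the observed betaMNTD against a null distribution
   obtained by shuffling taxon labels across the tips of the phylogeny
   (abundances stay attached to their taxon slots). betaNTI > +2 indicates
   heterogeneous selection, betaNTI < -2 homogeneous selection.
3. RCbray — for pairs not resolved by selection (|betaNTI| <= 2), the
   observed Bray–Curtis dissimilarity is located within a null distribution
   of randomly assembled communities that preserve each sample's richness
   (taxon inclusion probability proportional to pool occupancy) and total
   abundance (filled proportionally to pool relative abundance), rescaled
   to [-1, 1]. RC > +0.95 indicates dispersal limitation, RC < -0.95
   homogenizing dispersal, and anything in between drift.

Null replicates within a group share one randomisation per replicate
across all pairs (as picante does for betaNTI); every pair's marginal null
distribution is unchanged and the group-level computation stays tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from skbio import TreeNode

from .io_core import AbundanceTable, SampleMetadata, patristic_distances

logger = logging.getLogger(__name__)

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


@dataclass
class NullConfig:
    """Randomisation settings for the assembly null models."""

    n_null: int = 999
    seed: int = 0
    abundance_weighted: bool = True
    pool_scope: str = "per_lake_kingdom"  # or "global"

    def __post_init__(self) -> None:
        if self.n_null < 99:
            raise ValueError("n_null must be >= 99")
        if self.pool_scope not in ("per_lake_kingdom", "global"):
            raise ValueError(f"unknown pool_scope '{self.pool_scope}'")


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _bmntd_core(D: np.ndarray, ix: np.ndarray, fx: np.ndarray,
                iy: np.ndarray, fy: np.ndarray) -> float:
    sub = D[np.ix_(ix, iy)]
    return 0.5 * (fx @ sub.min(axis=1) + fy @ sub.min(axis=0))


def _weights(counts: np.ndarray, idx: np.ndarray, weighted: bool) -> np.ndarray:
    if weighted:
        w = counts[idx].astype(float)
        return w / w.sum()
    return np.full(len(idx), 1.0 / len(idx))


def bmntd(tree: TreeNode, x, y, abundance_weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance.

    ``x`` and ``y`` map taxon id -> count (dict or pandas Series); taxa must
    be tips of ``tree``. With ``abundance_weighted`` each community's taxa
    are weighted by relative abundance, otherwise uniformly.
    """
    x = pd.Series(x)
    y = pd.Series(y)
    x = x[x > 0]
    y = y[y > 0]
    if x.empty or y.empty:
        raise ValueError("betaMNTD undefined for an empty community")
    dm = patristic_distances(tree)
    pos = {t: i for i, t in enumerate(dm.ids)}
    missing = [t for t in list(x.index) + list(y.index) if t not in pos]
    if missing:
        raise KeyError(f"taxa not in tree: {missing[:10]}")
    D = dm.data
    ix = np.array([pos[t] for t in x.index])
    iy = np.array([pos[t] for t in y.index])
    fx = _weights_from_series(x, abundance_weighted)
    fy = _weights_from_series(y, abundance_weighted)
    return float(_bmntd_core(D, ix, fx, iy, fy))


def _weights_from_series(s: pd.Series, weighted: bool) -> np.ndarray:
    if weighted:
        w = s.to_numpy(dtype=float)
        return w / w.sum()
    return np.full(len(s), 1.0 / len(s))


def bnti(tree: TreeNode, x, y, config: NullConfig | None = None,
         pool_taxa: list[str] | None = None) -> float:
    """betaNTI for a single pair.

    The null shuffles taxon labels among the pool's tips (by default the
    union of the pair's taxa) ``n_null`` times; betaNTI is the z-score of
    the observed betaMNTD within that distribution. Returns NaN with a
    warning when the null has zero spread.
    """
    config = config or NullConfig()
    x = pd.Series(x)
    y = pd.Series(y)
    x = x[x > 0]
    y = y[y > 0]
    if pool_taxa is None:
        pool_taxa = sorted(set(x.index) | set(y.index))
    dm = patristic_distances(tree)
    pos = {t: i for i, t in enumerate(dm.ids)}
    pool_idx = np.array([pos[t] for t in pool_taxa])
    D = dm.data[np.ix_(pool_idx, pool_idx)]
    slot = {t: i for i, t in enumerate(pool_taxa)}
    ix = np.array([slot[t] for t in x.index])
    iy = np.array([slot[t] for t in y.index])
    fx = _weights_from_series(x, config.abundance_weighted)
    fy = _weights_from_series(y, config.abundance_weighted)
    obs = _bmntd_core(D, ix, fx, iy, fy)
    rng = np.random.default_rng(config.seed)
    nulls = np.empty(config.n_null)
    npool = len(pool_taxa)
    for r in range(config.n_null):
        perm = rng.permutation(npool)
        nulls[r] = _bmntd_core(D, perm[ix], fx, perm[iy], fy)
    sd = nulls.std(ddof=1)
    if sd == 0:
        logger.warning("betaNTI undefined: null distribution has zero spread")
        return float("nan")
    return float((obs - nulls.mean()) / sd)


def _group_bnti(D: np.ndarray, comm: np.ndarray, weighted: bool,
                n_null: int, rng: np.random.Generator,
                rows: list[int] | None = None):
    """Observed betaMNTD and betaNTI for sample pairs of one pool group.

    ``D`` is the patristic matrix over the group's pool taxa; ``comm`` is
    (n_samples, n_pool) counts. Pairs are formed among ``rows`` (default:
    all samples); the tip-shuffle null always spans the full pool. One tip
    permutation per null replicate is shared across pairs.
    """
    n_s, n_pool = comm.shape
    if rows is None:
        rows = list(range(n_s))
    supports = [np.flatnonzero(comm[s]) for s in rows]
    freqs = [_weights(comm[s], np.flatnonzero(comm[s]), weighted) for s in rows]
    pairs = list(combinations(range(len(rows)), 2))
    obs = np.array([
        _bmntd_core(D, supports[i], freqs[i], supports[j], freqs[j])
        for i, j in pairs
    ])
    nulls = np.empty((n_null, len(pairs)))
    for r in range(n_null):
        perm = rng.permutation(n_pool)
        shuffled = [perm[s] for s in supports]
        nulls[r] = [
            _bmntd_core(D, shuffled[i], freqs[i], shuffled[j], freqs[j])
            for i, j in pairs
        ]
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    if np.isnan(z).any():
        logger.warning("betaNTI undefined for %d pairs (zero null spread)",
                       int(np.isnan(z).sum()))
    return pairs, obs, z


# ---------------------------------------------------------------------------
# Raup–Crick with Bray–Curtis
# ---------------------------------------------------------------------------

def _assemble_null_sample(rng, pool_idx, occ_p, pool_rel, richness, total):
    members = rng.choice(pool_idx, size=richness, replace=False, p=occ_p)
    w = pool_rel[members]
    if w.sum() == 0:
        w = np.full(len(members), 1.0)
    w = w / w.sum()
    counts = np.zeros(len(pool_rel), dtype=np.int64)
    counts[members] = 1
    counts[members] += rng.multinomial(total - richness, w)
    return counts


def _group_rc(comm: np.ndarray, n_null: int, rng: np.random.Generator,
              rows: list[int] | None = None) -> np.ndarray:
    """RCbray for all pairs among ``rows`` of one pool group.

    The regional pool (occupancy, relative abundance) is estimated from
    every sample in ``comm``; null communities preserve each paired
    sample's richness and total count, with inclusion probability
    proportional to pool occupancy and abundances filled proportionally to
    pool relative abundance. One null assemblage per sample per replicate
    is shared across pairs. Ties use the half-weight (mid-p) convention.
    Pair order matches ``combinations(range(len(rows)), 2)``.
    """
    n_s, n_pool = comm.shape
    if rows is None:
        rows = list(range(n_s))
    occ = (comm > 0).sum(axis=0).astype(float)
    pool_idx = np.flatnonzero(occ)
    richness = (comm > 0).sum(axis=1)
    if len(pool_idx) < richness[rows].max():
        raise ValueError("pool has fewer taxa than the richest sample")
    occ_p = occ[pool_idx] / occ[pool_idx].sum()
    pool_rel = comm.sum(axis=0) / comm.sum()
    sub = comm[rows]
    obs = pdist(sub.astype(float), metric="braycurtis")
    below = np.zeros(len(obs))
    ties = np.zeros(len(obs))
    null_comm = np.empty((len(rows), n_pool))
    for _ in range(n_null):
        for k, s in enumerate(rows):
            null_comm[k] = _assemble_null_sample(
                rng, pool_idx, occ_p, pool_rel, richness[s], comm[s].sum()
            )
        null_bc = pdist(null_comm, metric="braycurtis")
        below += null_bc < obs - 1e-12
        ties += np.abs(null_bc - obs) <= 1e-12
    rc = 2.0 * (below + 0.5 * ties) / n_null - 1.0
    return rc


def _bc(x: np.ndarray, y: np.ndarray) -> float:
    s = x + y
    return float(np.abs(x - y).sum() / s.sum())


def raup_crick_bray(table: AbundanceTable, pair: tuple[str, str],
                    config: NullConfig | None = None) -> float:
    """RCbray for one sample pair, with the whole table as the regional pool."""
    config = config or NullConfig()
    rng = np.random.default_rng(config.seed)
    comm = table.counts.T
    i = table.sample_ids.index(pair[0])
    j = table.sample_ids.index(pair[1])
    rc = _group_rc(comm, config.n_null, rng, rows=[i, j])
    return float(rc[0])


# ---------------------------------------------------------------------------
# Classification and aggregation
# ---------------------------------------------------------------------------

def classify_assembly(bnti_value: float, rc_bray: float) -> str:
    """Assign the ecological assembly process for one pair.

    betaNTI beyond +/-2 (strict) indicates selection; otherwise RCbray
    beyond +/-0.95 (strict) indicates dispersal processes; anything else is
    drift. Boundary values (exactly +/-2, exactly +/-0.95) fall to the
    stochastic/drift side.
    """
    if not (np.isfinite(bnti_value) and np.isfinite(rc_bray)):
        raise ValueError("classify_assembly requires finite inputs")
    if bnti_value > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_bray > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_bray < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def assembly_analysis(
    table: AbundanceTable,
    tree: TreeNode,
    metadata: SampleMetadata,
    config: NullConfig | None = None,
    pair_filter: dict | None = None,
) -> pd.DataFrame:
    """Per-pair betaMNTD, betaNTI, RCbray and assembly process.

    Pool groups follow ``config.pool_scope`` (all samples of one lake by
    default, the whole table under ``pool_scope="global"``); every sample
    of a group contributes to its regional pool — its taxa to the
    tip-shuffle pool, its occupancy and abundance to the Raup–Crick null.
    ``pair_filter`` (e.g. ``{"fraction": "plastisphere"}``) restricts which
    samples are paired and classified without removing the rest from the
    pool, mirroring how field surveys treat water communities as the
    source pool for biofilm pairs. Pairs with an undefined betaNTI are
    excluded from classification with a warning.
    """
    config = config or NullConfig()
    meta = metadata.frame.reset_index(drop=True)
    meta = meta[meta["sample_id"].isin(table.sample_ids)]
    if config.pool_scope == "per_lake_kingdom":
        groups = [(lake, list(sub["sample_id"]))
                  for lake, sub in meta.groupby("lake", observed=True)]
    else:
        groups = [("global", list(meta["sample_id"]))]
    meta_idx = meta.set_index("sample_id")

    dm = patristic_distances(tree)
    pos = {t: i for i, t in enumerate(dm.ids)}
    tx = np.array([pos[t] for t in table.taxon_ids])
    D_full = dm.data[np.ix_(tx, tx)]  # aligned to table taxon order

    seeds = np.random.SeedSequence(config.seed).spawn(len(groups))
    rows = []
    for (gname, sids), ss in zip(groups, seeds):
        pair_sids = sids
        if pair_filter:
            pair_sids = [
                s for s in sids
                if all(meta_idx.loc[s, k] == v for k, v in pair_filter.items())
            ]
        if len(pair_sids) < 2:
            logger.warning("pool group %s has <2 pairable samples; skipped", gname)
            continue
        sub = table.select_samples(sids)
        keep = sub.counts.sum(axis=1) > 0
        comm = sub.counts[keep].T  # samples x pool taxa
        D = D_full[np.ix_(keep, keep)]
        row_idx = [sids.index(s) for s in pair_sids]
        rng = np.random.default_rng(ss)
        pairs, obs, z = _group_bnti(
            D, comm, config.abundance_weighted, config.n_null, rng,
            rows=row_idx,
        )
        # same complete pair ordering over row_idx as _group_bnti
        rc = _group_rc(comm, config.n_null, rng, rows=row_idx)
        for (i, j), o, zz, r in zip(pairs, obs, z, rc):
            process = classify_assembly(zz, r) if np.isfinite(zz) else None
            rows.append(dict(
                sample_i=pair_sids[i], sample_j=pair_sids[j], group=gname,
                bmntd_obs=o, bnti=zz, rc_bray=r, process=process,
            ))
    return pd.DataFrame(rows)


def process_fractions(
    results: pd.DataFrame,
    metadata: SampleMetadata,
    group_by: list[str] = ("lake",),
    stage_by: str | None = None,
) -> pd.DataFrame:
    """Fraction of pairs assigned to each assembly process per group.

    With ``stage_by`` (e.g. "day") only pairs whose two samples share the
    stage value contribute, yielding per-stage stacked fractions. Also
    reports the deterministic share (both selection processes), and the
    homogenizing (homogeneous selection + homogenizing dispersal) vs
    differentiating (heterogeneous selection + dispersal limitation)
    aggregate shares.
    """
    meta = metadata.frame
    df = results.dropna(subset=["process"]).copy()
    keys = []
    for col in group_by:
        vi = meta.loc[df["sample_i"], col].to_numpy()
        vj = meta.loc[df["sample_j"], col].to_numpy()
        same = vi == vj
        df = df[same]
        vi = vi[same]
        df[col] = vi
        keys.append(col)
    if stage_by is not None:
        vi = meta.loc[df["sample_i"], stage_by].to_numpy()
        vj = meta.loc[df["sample_j"], stage_by].to_numpy()
        same = vi == vj
        df = df[same]
        df[stage_by] = vi[same]
        keys.append(stage_by)
    rows = []
    grouped = df.groupby(keys, observed=True) if keys else [((), df)]
    for cell, sub in grouped:
        if sub.empty:
            continue
        frac = sub["process"].value_counts(normalize=True)
        rec = dict(zip(keys, cell if isinstance(cell, tuple) else (cell,)))
        for p in PROCESSES:
            rec[p] = float(frac.get(p, 0.0))
        rec["n_pairs"] = len(sub)
        rec["deterministic"] = rec["heterogeneous_selection"] + rec["homogeneous_selection"]
        rec["stochastic"] = 1.0 - rec["deterministic"]
        rec["homogenizing"] = rec["homogeneous_selection"] + rec["homogenizing_dispersal"]
        rec["differentiating"] = rec["heterogeneous_selection"] + rec["dispersal_limitation"]
        rows.append(rec)
    return pd.DataFrame(rows)
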