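"""Succession statistics: time-decay of community similarity, multi-term
sequential PERMANOVA, Mantel tests, and the convergence-trend statistic.

The PERMANOVA here is the adonis-style sequential (Type-I) partitioning of
a Gower-centred distance matrix among an ordered list of factors and
interactions (McArdle–Anderson), with significance by permutation of
sample labels — optionally restricted within strata. No Python library
offers the multi-term sequential variant, so it is implemented directly;
the one-way case is cross-checked against scikit-bio's PERMANOVA in the
test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations as iter_permutations
from math import factorial

import numpy as np
import pandas as pd
import skbio
from scipy import stats as sps

from .io_core import SampleMetadata

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Time decay of similarity
# ---------------------------------------------------------------------------

@dataclass
class TimeDecayFit:
    """Log–log (or lin–lin) regression of pairwise similarity on time lag."""

    group: str
    slope: float          # signed regression slope
    turnover_rate: float  # |slope|, the temporal turnover rate w
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    n_excluded: int
    transform: str        # "log10" or "linear"


def time_decay(
    similarity: skbio.DistanceMatrix,
    metadata: SampleMetadata,
    group_by: list[str] = ("lake",),
    transform: str = "log10",
) -> list[TimeDecayFit]:
    """Fit the time-decay relationship per group.

    ``similarity`` holds pairwise similarities (e.g. 1 - beta_SOR stored as
    a symmetric matrix); for every within-group pair the similarity is
    regressed on the colonization-time lag |day_i - day_j|. Under the
    default log10 transform, pairs with zero time lag or non-positive
    similarity are excluded (and counted); slope magnitude is the temporal
    turnover rate.
    """
    if transform not in ("log10", "linear"):
        raise ValueError("transform must be 'log10' or 'linear'")
    meta = metadata.frame
    ids = list(similarity.ids)
    day = meta.loc[ids, "day"].to_numpy(dtype=float)
    sim = similarity.data
    fits = []
    group_of = meta.loc[ids, list(group_by)].astype(str).agg("/".join, axis=1).to_numpy()
    for g in pd.unique(group_of):
        idx = np.flatnonzero(group_of == g)
        xs, ys, excluded = [], [], 0
        for i, j in combinations(idx, 2):
            dt = abs(day[i] - day[j])
            s = sim[i, j]
            if transform == "log10" and (dt <= 0 or s <= 0):
                excluded += 1
                continue
            xs.append(dt)
            ys.append(s)
        if len(xs) < 3:
            logger.warning("group %s has <3 usable pairs; no fit", g)
            continue
        x = np.asarray(xs)
        y = np.asarray(ys)
        if transform == "log10":
            x, y = np.log10(x), np.log10(y)
        if len(set(x)) < 2:
            raise ValueError(
                f"group {g}: all pairs share one time distance; no regression possible"
            )
        if np.allclose(y, y[0]):
            fits.append(TimeDecayFit(g, 0.0, 0.0, float(y[0]), 0.0, 1.0,
                                     len(xs), excluded, transform))
            continue
        res = sps.linregress(x, y)
        fits.append(TimeDecayFit(
            g, float(res.slope), float(abs(res.slope)), float(res.intercept),
            float(res.rvalue ** 2), float(res.pvalue), len(xs), excluded,
            transform,
        ))
    return fits


def time_decay_table(fits: list[TimeDecayFit]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in fits])


# ---------------------------------------------------------------------------
# PERMANOVA (sequential, multi-term)
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _term_design(meta: pd.DataFrame, term: str) -> pd.DataFrame:
    """Full dummy encoding of a factor or ':'-interaction of factors."""
    parts = term.split(":")
    combo = meta[parts[0]].astype(str)
    for p in parts[1:]:
        combo = combo + "␟" + meta[p].astype(str)
    if combo.nunique() < 2:
        raise ValueError(f"term '{term}' has a single level")
    return pd.get_dummies(combo, dtype=float)


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(r).max())))
    q = q[:, :rank]
    return q @ q.T


def permanova(
    dm: skbio.DistanceMatrix,
    metadata: SampleMetadata,
    terms: list[str],
    n_permutations: int = 9999,
    seed: int = 0,
    strata: str | None = None,
) -> pd.DataFrame:
    """Sequential (Type-I) multi-factor PERMANOVA of a distance matrix.

    ``terms`` is an ordered list of metadata factors and ``a:b``
    interactions; sums of squares are attributed sequentially in that
    order. P-values come from free permutation of sample labels (restricted
    within ``strata`` when given); when the full permutation group is no
    larger than ``n_permutations`` it is enumerated exactly.

    Returns a table with one row per term plus a residual row; R2 over all
    terms and the residual sums to one.
    """
    ids = list(dm.ids)
    meta = metadata.frame.loc[ids]
    n = len(ids)
    G = _gower_center(dm.data)
    ss_total = float(np.trace(G))

    designs = [_term_design(meta, t).to_numpy() for t in terms]
    ones = np.ones((n, 1))
    hats = [_hat(ones)]
    for k in range(len(terms)):
        x = np.hstack([ones] + designs[: k + 1])
        hats.append(_hat(x))
    dfs = [int(round(np.trace(hats[k + 1] - hats[k]))) for k in range(len(terms))]
    df_res = n - int(round(np.trace(hats[-1])))
    if df_res <= 0:
        raise ValueError("model is saturated; no residual degrees of freedom")
    resid_proj = np.eye(n) - hats[-1]

    def term_stats(Gp: np.ndarray):
        ss = np.array([
            float(np.einsum("ij,ji->", hats[k + 1] - hats[k], Gp))
            for k in range(len(terms))
        ])
        ss_res = float(np.einsum("ij,ji->", resid_proj, Gp))
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, ss_res, f

    ss_obs, ss_res_obs, f_obs = term_stats(G)

    rng = np.random.default_rng(seed)
    perms = _permutation_indices(n, n_permutations, rng,
                                 strata_labels=None if strata is None
                                 else meta[strata].to_numpy())
    exhaustive = perms is not None
    if exhaustive:
        count_ge = np.zeros(len(terms))
        total = 0
        for perm in perms:
            Gp = G[np.ix_(perm, perm)]
            _, _, f_p = term_stats(Gp)
            count_ge += f_p >= f_obs - 1e-12
            total += 1
        p_values = count_ge / total
    else:
        count_ge = np.zeros(len(terms))
        for _ in range(n_permutations):
            perm = _random_permutation(n, rng,
                                       None if strata is None
                                       else meta[strata].to_numpy())
            Gp = G[np.ix_(perm, perm)]
            _, _, f_p = term_stats(Gp)
            count_ge += f_p >= f_obs - 1e-12
        p_values = (count_ge + 1.0) / (n_permutations + 1.0)

    rows = []
    for t, ss, df_t, f, p in zip(terms, ss_obs, dfs, f_obs, p_values):
        rows.append(dict(term=t, df=df_t, SS=ss, R2=ss / ss_total, F=f, p=p))
    rows.append(dict(term="Residual", df=df_res, SS=ss_res_obs,
                     R2=ss_res_obs / ss_total, F=np.nan, p=np.nan))
    return pd.DataFrame(rows)


def _permutation_indices(n, n_permutations, rng, strata_labels):
    """Full enumeration when the permutation group is small, else None."""
    if strata_labels is None:
        if factorial(n) <= n_permutations:
            return [np.array(p) for p in iter_permutations(range(n))]
        return None
    sizes = pd.Series(strata_labels).value_counts()
    total = 1
    for s in sizes:
        total *= factorial(s)
        if total > n_permutations:
            return None
    # enumerate within-stratum permutations jointly
    groups = [np.flatnonzero(strata_labels == lab) for lab in sizes.index]
    perms_per_group = [list(iter_permutations(g)) for g in groups]
    out = []

    def rec(k, current):
        if k == len(groups):
            perm = np.arange(n)
            for g, assignment in zip(groups, current):
                perm[g] = assignment
            out.append(perm)
            return
        for assignment in perms_per_group[k]:
            rec(k + 1, current + [np.array(assignment)])

    rec(0, [])
    return out


def _random_permutation(n, rng, strata_labels):
    if strata_labels is None:
        return rng.permutation(n)
    perm = np.arange(n)
    for lab in pd.unique(strata_labels):
        idx = np.flatnonzero(strata_labels == lab)
        perm[idx] = idx[rng.permutation(len(idx))]
    return perm


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    method: str
    n_permutations: int
    n: int


def mantel(
    dm_a: skbio.DistanceMatrix,
    dm_b: skbio.DistanceMatrix,
    method: str = "pearson",
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> MantelResult:
    """Mantel test of matrix correlation.

    Correlates the off-diagonal entries of two distance matrices over the
    same samples; significance by jointly permuting the rows/columns of the
    second matrix. ``method`` is "pearson" or "spearman".
    """
    if set(dm_a.ids) != set(dm_b.ids):
        raise ValueError("distance matrices must share the same sample ids")
    dm_b = dm_b.filter(dm_a.ids)
    a = dm_a.data
    b = dm_b.data
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    corr = {"pearson": lambda u, v: sps.pearsonr(u, v)[0],
            "spearman": lambda u, v: sps.spearmanr(u, v)[0]}
    if method not in corr:
        raise ValueError("method must be 'pearson' or 'spearman'")
    f = corr[method]
    r_obs = float(f(a[iu], b[iu]))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_p = f(a[iu], b[np.ix_(perm, perm)][iu])
        if alternative == "two-sided":
            hit = abs(r_p) >= abs(r_obs) - 1e-12
        elif alternative == "greater":
            hit = r_p >= r_obs - 1e-12
        else:
            hit = r_p <= r_obs + 1e-12
        count += bool(hit)
    p = (count + 1.0) / (n_permutations + 1.0)
    return MantelResult(r_obs, p, method, n_permutations, n)


def env_distance(env: pd.DataFrame, variables: list[str],
                 metadata: SampleMetadata,
                 sample_ids: list[str]) -> skbio.DistanceMatrix:
    """Euclidean distance between samples in (z-scored) environment space,
    looked up via each sample's (lake, day)."""
    env_idx = env.set_index(["lake", "day"])
    z = (env_idx[variables] - env_idx[variables].mean()) / env_idx[variables].std()
    meta = metadata.frame
    points = np.array([
        z.loc[(meta.loc[s, "lake"], meta.loc[s, "day"])].to_numpy()
        for s in sample_ids
    ])
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return skbio.DistanceMatrix(d, ids=sample_ids)


# ---------------------------------------------------------------------------
# Convergence trend
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceFit:
    group: str
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    convergent: bool  # slope < 0
    per_day: pd.DataFrame  # columns: day, mean_dissimilarity, n_pairs


def convergence_trend(
    dm: skbio.DistanceMatrix,
    metadata: SampleMetadata,
    within: list[str] = ("lake",),
    across: str = "polymer",
) -> list[ConvergenceFit]:
    """Trend of between-substrate community dissimilarity over time.

    Per ``within`` group (a lake): the mean pairwise dissimilarity across
    levels of ``across`` (polymer types) at each day, then an OLS fit of
    that mean against day. A negative slope is the convergence call —
    communities on different polymers growing more alike with colonization
    time.
    """
    meta = metadata.frame
    ids = list(dm.ids)
    pos = {s: i for i, s in enumerate(ids)}
    data = dm.data
    group_of = meta.loc[ids, list(within)].astype(str).agg("/".join, axis=1)
    fits = []
    for g in pd.unique(group_of):
        sids = [s for s in ids if group_of[s] == g]
        sub = meta.loc[sids]
        per_day = []
        for day, day_sub in sub.groupby("day"):
            vals = []
            for si, sj in combinations(day_sub["sample_id"], 2):
                if meta.loc[si, across] != meta.loc[sj, across]:
                    vals.append(data[pos[si], pos[sj]])
            if not vals:
                logger.warning("group %s day %s: <2 %s levels; skipped",
                               g, day, across)
                continue
            per_day.append(dict(day=int(day), mean_dissimilarity=float(np.mean(vals)),
                                n_pairs=len(vals)))
        per_day_df = pd.DataFrame(per_day)
        if len(per_day_df) < 2:
            logger.warning("group %s has <2 usable days; no fit", g)
            continue
        x = per_day_df["day"].to_numpy(dtype=float)
        y = per_day_df["mean_dissimilarity"].to_numpy()
        if np.allclose(y, y[0]):
            fits.append(ConvergenceFit(g, 0.0, float(y[0]), 1.0, 0.0, False,
                                       per_day_df))
            continue
        res = sps.linregress(x, y)
        fits.append(ConvergenceFit(
            g, float(res.slope), float(res.intercept), float(res.pvalue),
            float(res.rvalue ** 2), bool(res.slope < 0), per_day_df,
        ))
    return fits


def convergence_table(fits: list[ConvergenceFit]) -> pd.DataFrame:
    return pd.DataFrame([
        {k: v for k, v in f.__dict__.items() if k != "per_day"} for f in fits
    ])
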