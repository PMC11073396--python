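"""Pairwise beta diversity: Bray–Curtis, Sørensen-family partitioning into
species turnover and nestedness (Baselga decomposition), and the beta_ratio
statistic summarised per group and succession stage.

The pairwise Sørensen dissimilarity beta_SOR = (b + c) / (2a + b + c), with
a = shared taxa and b, c the taxa unique to each community, decomposes as

    beta_SOR = beta_sim + beta_sne
    beta_sim = min(b, c) / (a + min(b, c))     (Simpson / turnover)
    beta_sne = beta_SOR - beta_sim             (nestedness-resultant)

and beta_ratio = beta_sim / beta_SOR > 0.5 flags turnover-dominated beta
diversity, < 0.5 nestedness-dominated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import braycurtis, pdist, squareform

from .io_core import AbundanceTable, SampleMetadata

logger = logging.getLogger(__name__)


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y) of two count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two empty communities")
    return float(braycurtis(x, y))


def bray_curtis_matrix(table: AbundanceTable) -> skbio.DistanceMatrix:
    """All-pairs Bray–Curtis over the table's samples."""
    data = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
    return skbio.DistanceMatrix(data, ids=table.sample_ids)


@dataclass(frozen=True)
class BetaPartition:
    """Turnover/nestedness partition of one sample pair."""

    sample_i: str
    sample_j: str
    beta_sor: float
    beta_sim: float
    beta_sne: float
    beta_ratio: float  # NaN when beta_sor == 0 (identical incidence)


def sorensen_partition(x, y, ids: tuple[str, str] = ("i", "j")) -> BetaPartition:
    """Baselga partition of the Sørensen dissimilarity for one pair.

    ``x`` and ``y`` are count or incidence vectors; presence is count > 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    px, py = x > 0, y > 0
    a = int(np.sum(px & py))
    b = int(np.sum(px & ~py))
    c = int(np.sum(~px & py))
    if a + b + c == 0:
        raise ValueError("both communities are empty")
    beta_sor = (b + c) / (2 * a + b + c)
    bmin = min(b, c)
    # a + bmin == 0 only when one community is empty: strict nesting, no turnover
    beta_sim = bmin / (a + bmin) if (a + bmin) > 0 else 0.0
    beta_sne = beta_sor - beta_sim
    beta_ratio = beta_sim / beta_sor if beta_sor > 0 else float("nan")
    return BetaPartition(ids[0], ids[1], beta_sor, beta_sim, beta_sne, beta_ratio)


def sorensen_partition_table(table: AbundanceTable) -> pd.DataFrame:
    """Partition every sample pair; one row per unordered pair."""
    inc = table.counts > 0
    rows = []
    for i, j in combinations(range(table.n_samples), 2):
        p = sorensen_partition(
            inc[:, i], inc[:, j], ids=(table.sample_ids[i], table.sample_ids[j])
        )
        rows.append(p.__dict__)
    return pd.DataFrame(rows)


def sorensen_matrix(table: AbundanceTable) -> skbio.DistanceMatrix:
    """All-pairs Sørensen (beta_SOR) dissimilarity (Dice on incidence)."""
    inc = (table.counts > 0).T.astype(bool)
    data = squareform(pdist(inc, metric="dice"))
    return skbio.DistanceMatrix(data, ids=table.sample_ids)


def beta_ratio_by_group(
    table: AbundanceTable,
    metadata: SampleMetadata,
    group_by: list[str] = ("lake",),
    stage_by: str = "day",
) -> pd.DataFrame:
    """Mean beta_ratio over within-cell pairs per group x stage, with a
    turnover/nestedness dominance call at the 0.5 boundary.

    Within a cell (e.g. one lake at one day) every unordered sample pair —
    for plastisphere data, pairs across polymers — contributes one
    beta_ratio; cells with fewer than two samples are skipped with a
    warning. Pairs with identical incidence (beta_sor = 0) carry an
    undefined ratio and are dropped from the mean.
    """
    meta = metadata.frame.reset_index(drop=True)
    keys = list(group_by) + [stage_by]
    inc = table.counts > 0
    col = {s: k for k, s in enumerate(table.sample_ids)}
    rows = []
    for cell, sub in meta.groupby(keys, observed=True):
        sids = [s for s in sub["sample_id"] if s in col]
        if len(sids) < 2:
            logger.warning("cell %s has <2 samples; skipped", cell)
            continue
        ratios = []
        for si, sj in combinations(sids, 2):
            p = sorensen_partition(inc[:, col[si]], inc[:, col[sj]], ids=(si, sj))
            if np.isfinite(p.beta_ratio):
                ratios.append(p.beta_ratio)
        if not ratios:
            logger.warning("cell %s has no defined beta_ratio pairs; skipped", cell)
            continue
        mean_ratio = float(np.mean(ratios))
        rec = dict(zip(keys, cell if isinstance(cell, tuple) else (cell,)))
        rec.update(
            mean_beta_ratio=mean_ratio,
            n_pairs=len(ratios),
            dominance="turnover" if mean_ratio > 0.5 else "nestedness",
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def rarefy(table: AbundanceTable, depth: int | None = None,
           seed: int = 0) -> AbundanceTable:
    """Seeded rarefaction (subsampling without replacement) to a common
    depth, by default the minimum sample total. Optional pipeline-level
    normalisation; distances are computed on raw counts unless requested."""
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if depth > totals.min():
        raise ValueError("rarefaction depth exceeds the smallest sample total")
    out = np.zeros_like(table.counts)
    for j in range(table.n_samples):
        counts = table.counts[:, j]
        pool = np.repeat(np.arange(table.n_taxa), counts)
        keep = rng.choice(pool, size=depth, replace=False)
        out[:, j] = np.bincount(keep, minlength=table.n_taxa)
    return AbundanceTable(list(table.taxon_ids), list(table.sample_ids), out).drop_empty()
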