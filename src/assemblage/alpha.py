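"""Per-sample alpha diversity: species richness and rooted Faith's PD,
with grouped trajectories over colonization time."""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_core import AbundanceTable, SampleMetadata


def richness(table: AbundanceTable, sample_id: str) -> int:
    """Number of taxa with nonzero count in the sample."""
    return int((table.sample_counts(sample_id) > 0).sum())


def faith_pd(tree: TreeNode, present_taxa) -> float:
    """Rooted Faith's phylogenetic diversity.

    Sum of branch lengths of the minimal subtree connecting ``present_taxa``
    and the root (the root connection is included, so PD of a single taxon
    equals its root-to-tip path length and PD is monotone under inclusion).
    """
    present = set(present_taxa)
    if not present:
        raise ValueError("present_taxa must be non-empty")
    tips = {t.name for t in tree.tips()}
    unknown = present - tips
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)[:10]}")
    total = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._pd_hit = node.name in present
        else:
            node._pd_hit = any(c._pd_hit for c in node.children)
        if node._pd_hit:
            total += node.length
    for node in tree.postorder(include_self=False):
        del node._pd_hit
    return total


def alpha_table(table: AbundanceTable, tree: TreeNode) -> pd.DataFrame:
    """Richness and Faith's PD for every sample."""
    taxa = np.asarray(table.taxon_ids)
    rows = []
    for sid in table.sample_ids:
        counts = table.sample_counts(sid)
        present = taxa[counts > 0]
        rows.append(
            dict(sample_id=sid, richness=int(len(present)),
                 faith_pd=faith_pd(tree, present))
        )
    return pd.DataFrame(rows)


def alpha_trajectories(
    alpha_results: pd.DataFrame,
    metadata: SampleMetadata,
    group_by: list[str] = ("lake", "fraction"),
    metrics: tuple[str, ...] = ("richness", "faith_pd"),
) -> pd.DataFrame:
    """Per-group per-day mean and sd of each alpha metric.

    Groups with a single sample report a missing (NaN) sd, never zero.
    """
    merged = alpha_results.merge(
        metadata.frame.reset_index(drop=True), on="sample_id", how="left"
    )
    keys = list(group_by) + ["day"]
    if merged.empty:
        cols = keys + [f"{m}_{s}" for m in metrics for s in ("mean", "sd")] + ["n"]
        return pd.DataFrame(columns=cols)
    agg = {f"{m}_{s}": (m, s) for m in metrics for s in ("mean", "std")}
    out = merged.groupby(keys, observed=True).agg(
        **{k.replace("_std", "_sd"): v for k, v in agg.items()},
        n=("sample_id", "size"),
    )
    return out.reset_index().sort_values(keys).reset_index(drop=True)
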