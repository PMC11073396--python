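"""Domain containers and readers/writers for the formats the pipeline touches.

The central object is the :class:`AbundanceTable` — an integer ASV-count
matrix (taxa x samples) — accompanied by per-sample metadata (lake, day,
polymer, fraction), a rooted phylogeny over the taxon pool, and an optional
environmental table keyed by (lake, day).

Trees are :class:`skbio.TreeNode` instances; pairwise dissimilarities use
:class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["sample_id", "lake", "day", "polymer", "fraction"]
ENV_VARIABLES = ["T", "Turb", "C", "DO", "ChlA", "TN", "TP", "TC", "TOC", "TIC", "ORP"]

PLASTISPHERE = "plastisphere"
WATER_SENTINEL = "water"


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class AbundanceTable:
    """Integer count matrix, taxa x samples.

    Counts are always raw integers; relative abundances are derived on
    demand and never stored, so rarefaction has a single source of truth.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_taxa, n_samples), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                bad = np.argwhere(self.counts != np.round(self.counts))[0]
                raise ValidationError(
                    f"non-integer count at taxon '{self.taxon_ids[bad[0]]}', "
                    f"sample '{self.sample_ids[bad[1]]}'"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon '{self.taxon_ids[bad[0]]}', "
                f"sample '{self.sample_ids[bad[1]]}'"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """Count vector (over all taxa) for one sample."""
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample '{sample_id}'") from None
        return self.counts[:, j]

    def relative_abundance(self) -> np.ndarray:
        """Column-normalised matrix of relative abundances."""
        totals = self.counts.sum(axis=0)
        return self.counts / totals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def drop_empty(self) -> "AbundanceTable":
        """Drop all-zero taxa rows and all-zero sample columns, with warnings."""
        row_tot = self.counts.sum(axis=1)
        col_tot = self.counts.sum(axis=0)
        empty_taxa = [t for t, s in zip(self.taxon_ids, row_tot) if s == 0]
        empty_samples = [s for s, t in zip(self.sample_ids, col_tot) if t == 0]
        if empty_taxa:
            logger.warning("dropping %d all-zero taxa: %s", len(empty_taxa), empty_taxa[:5])
        if empty_samples:
            logger.warning("dropping all-zero samples: %s", empty_samples)
        keep_r = row_tot > 0
        keep_c = col_tot > 0
        return AbundanceTable(
            [t for t, k in zip(self.taxon_ids, keep_r) if k],
            [s for s, k in zip(self.sample_ids, keep_c) if k],
            self.counts[np.ix_(keep_r, keep_c)],
        )


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} id '{i}'")
        seen.add(i)


@dataclass
class SampleMetadata:
    """Per-sample design factors: lake, day, polymer, fraction.

    fraction is "plastisphere" for pellet samples (polymer is then one of
    the incubated polymer types) or "WP"/"WF" for water samples (polymer is
    the sentinel "water").
    """

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame["sample_id"][self.frame["sample_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate sample id '{dup}' in metadata")
        if (self.frame["day"].astype(int) < 0).any():
            raise ValidationError("day must be >= 0")
        is_plast = self.frame["fraction"] == PLASTISPHERE
        is_water_poly = self.frame["polymer"] == WATER_SENTINEL
        if (is_plast & is_water_poly).any() or (~is_plast & ~is_water_poly).any():
            raise ValidationError(
                "fraction=plastisphere must coincide exactly with polymer != 'water'"
            )
        self.frame = self.frame.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[sample_ids].reset_index(drop=True))

    def plastisphere(self) -> "SampleMetadata":
        return SampleMetadata(
            self.frame[self.frame["fraction"] == PLASTISPHERE].reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path, orientation: str = "taxa_by_samples") -> AbundanceTable:
    """Read a TSV count table.

    Canonical orientation is taxa x samples (first column taxon ids, header
    row sample ids); ``orientation="samples_by_taxa"`` transposes on read.
    All-zero rows/columns are dropped with a logged warning; duplicate ids
    and non-integer or negative entries are hard errors.
    """
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise ValueError(f"unknown orientation '{orientation}'")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_by_taxa":
        df = df.T
    # pandas mangles duplicate column headers; detect from the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    first_col = pd.read_csv(path, sep="\t", usecols=[0]).iloc[:, 0].astype(str)
    if orientation == "taxa_by_samples":
        _check_unique(header, "sample")
        _check_unique(list(first_col), "taxon")
    else:
        _check_unique(header, "taxon")
        _check_unique(list(first_col), "sample")
    table = AbundanceTable(
        [str(t) for t in df.index], [str(s) for s in df.columns], df.to_numpy()
    )
    return table.drop_empty()


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    df["day"] = df["day"].astype(int)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.frame.reset_index(drop=True)[METADATA_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def read_env_table(path) -> pd.DataFrame:
    """Environmental variables keyed by (lake, day)."""
    df = pd.read_csv(path, sep="\t")
    if not {"lake", "day"}.issubset(df.columns):
        raise ValidationError("environment table must have 'lake' and 'day' columns")
    dup = df.duplicated(subset=["lake", "day"])
    if dup.any():
        raise ValidationError("duplicate (lake, day) record in environment table")
    return df


def write_env_table(env: pd.DataFrame, path) -> None:
    env.to_csv(path, sep="\t", index=False)


def read_tree(path_or_str) -> TreeNode:
    """Read a rooted newick tree; branch lengths are required on non-root edges."""
    if _looks_like_newick(path_or_str):
        tree = TreeNode.read(io.StringIO(str(path_or_str)))
    else:
        tree = TreeNode.read(str(path_or_str))
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                "tree has edges without branch lengths; lengths are required "
                "for phylogenetic diversity and betaMNTD"
            )
        if not np.isfinite(node.length) or node.length < 0:
            raise ValidationError(f"invalid branch length {node.length!r}")
    return tree


def _looks_like_newick(s) -> bool:
    return isinstance(s, str) and s.lstrip().startswith("(")


def cross_validate_tree(tree: TreeNode, table: AbundanceTable) -> TreeNode:
    """Prune tree to the table's taxa; error if a table taxon lacks a tip."""
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tips]
    if missing:
        raise ValidationError(f"table taxa missing from tree: {missing[:10]}")
    extra = tips - set(table.taxon_ids)
    if extra:
        logger.warning("pruning %d tree tips absent from table", len(extra))
        tree = tree.shear(table.taxon_ids)
        tree.prune()
    return tree


def patristic_distances(tree: TreeNode) -> skbio.DistanceMatrix:
    """Tip-to-tip path-length (patristic) distance matrix."""
    tips = list(tree.tips())
    if len(tips) == 1:
        return skbio.DistanceMatrix(np.zeros((1, 1)), ids=[tips[0].name])
    return tree.tip_tip_distances()
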