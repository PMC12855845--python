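"""Reading, writing and depth-normalising amplicon feature tables.

All downstream analyses consume one canonical container, :class:`FeatureTable`
(samples x taxa integer counts), plus a rooted tree (scikit-bio ``TreeNode``),
a sample -> group metadata Series and an id -> sequence mapping.  Orientation
of a feature-table file must be stated by the caller; silent transposition is
refused because it is a classic amplicon-pipeline bug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "FormatError",
    "read_feature_table",
    "write_feature_table",
    "read_tree",
    "read_fasta",
    "read_metadata",
    "rarefy",
    "relative_abundance",
    "filter_rare",
]


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


@dataclass
class FeatureTable:
    """Samples x taxa count matrix with unique, ordered labels.

    Parameters
    ----------
    counts:
        Integer DataFrame; index = sample ids, columns = taxon ids.
    taxonomy:
        Optional taxon id -> lineage string map.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise ValueError("feature table needs at least one sample and one taxon")
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate taxon ids")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric counts")
        if (arr < 0).any():
            raise FormatError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FeatureTable) and self.counts.equals(other.counts)


def read_feature_table(path, orientation: str) -> FeatureTable:
    """Read a TSV count table; ``orientation`` is ``"samples-as-rows"`` or
    ``"taxa-as-rows"`` and must be given explicitly."""
    if orientation not in ("samples-as-rows", "taxa-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # parsing failures become format errors
        raise FormatError(f"cannot parse feature table {path}: {exc}") from exc
    if orientation == "taxa-as-rows":
        df = df.T
    for cell in df.dtypes:
        if not np.issubdtype(cell, np.number):
            raise FormatError(f"non-numeric cell in {path}")
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write the canonical samples-as-rows TSV (round-trips byte-stably)."""
    out = table.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; tip labels are taken verbatim."""
    try:
        tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    except Exception as exc:
        raise FormatError(f"cannot parse newick {path}: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise FormatError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError("negative branch length in tree")
    return tree


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r}")
        seqs[rec.id] = seq
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return seqs


def read_metadata(path) -> pd.Series:
    """Read a two-or-more-column TSV ``sample_id<TAB>group`` into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("metadata needs at least sample_id and group columns")
    if df.iloc[:, 0].duplicated().any():
        raise FormatError("duplicate sample ids in metadata")
    meta = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    meta.index.name = "sample_id"
    return meta


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a logged warning.
    Uses multivariate-hypergeometric draws, so taxon proportions are unbiased
    in expectation; the seed is required, never implicit.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning(
            "dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    if len(keep) == 0:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    rows = []
    for s in keep:
        counts = table.counts.loc[s].to_numpy()
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    sub = pd.DataFrame(rows, index=list(keep), columns=table.taxon_ids)
    return FeatureTable(sub, taxonomy=table.taxonomy)


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Per-sample proportions; every row sums to 1."""
    totals = table.sample_totals
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return table.counts.div(totals, axis=0)


def filter_rare(
    table: FeatureTable,
    min_overall_rel_abund: float = 0.00005,
    per_sample: bool = False,
) -> FeatureTable:
    """Drop taxa whose share of the grand total is below the threshold.

    The default 0.00005 (0.005%) is applied to each taxon's summed counts
    over all samples divided by the grand total.  ``per_sample=True`` instead
    requires the taxon to reach the threshold within at least one sample.
    Samples are never dropped.
    """
    if not (0 <= min_overall_rel_abund < 1):
        raise ValueError("threshold must be in [0, 1)")
    if per_sample:
        rel = relative_abundance(table)
        keep = rel.max(axis=0) >= min_overall_rel_abund
    else:
        shares = table.counts.sum(axis=0) / table.counts.to_numpy().sum()
        keep = shares >= min_overall_rel_abund
    kept = table.counts.loc[:, keep[keep].index]
    if kept.shape[1] == 0:
        raise ValueError("abundance filter removed every taxon")
    return FeatureTable(kept, taxonomy=table.taxonomy)
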