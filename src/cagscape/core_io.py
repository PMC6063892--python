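"""Shared domain types and tabular I/O.

The universal currency of the pipeline is the :class:`AbundanceTable`, a
sample x OTU matrix of counts or relative abundances.  Taxonomy, sample
metadata and per-OTU genome content are plain :class:`pandas.DataFrame`
objects read from TSV; phylogenetic trees are :class:`skbio.TreeNode`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

COUNTS = "counts"
RELATIVE = "relative"

_REL_TOL = 1e-9


@dataclass
class AbundanceTable:
    """Sample x OTU abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are OTUs; all entries non-negative.
    mode : str
        ``"counts"`` or ``"relative"``.  In relative mode every row must
        sum to 1 (within tolerance) unless ``closed`` is False.
    closed : bool
        False marks a relative table whose columns are a subset of a closed
        composition (e.g. after the median-abundance filter), so rows sum to
        the retained fraction rather than 1.
    """

    data: pd.DataFrame
    mode: str = COUNTS
    closed: bool = True

    def __post_init__(self) -> None:
        if self.mode not in (COUNTS, RELATIVE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate OTU ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric abundance values")
        if not np.isfinite(values).all():
            raise ValueError("non-finite abundance values")
        if (values < 0).any():
            raise ValueError("negative abundance")
        if self.mode == RELATIVE and self.closed:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6, rtol=0):
                bad = self.data.index[np.abs(sums - 1.0) > 1e-6][0]
                raise ValueError(f"relative row {bad!r} does not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]


def read_abundance_table(path, orientation: str = "sample_rows") -> AbundanceTable:
    """Read a TSV abundance table into counts mode.

    ``orientation="otu_rows"`` transposes the file so that the returned
    table is always sample x OTU.
    """
    if orientation not in ("sample_rows", "otu_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "otu_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if df.isna().to_numpy().any():
        raise ValueError(f"missing or ragged cells in {path}")
    return AbundanceTable(df, mode=COUNTS)


def write_abundance_table(t: AbundanceTable, path) -> None:
    t.data.to_csv(path, sep="\t")


def to_relative(t: AbundanceTable) -> AbundanceTable:
    """Close each sample to relative abundances (rows sum to 1).

    Idempotent: a relative-mode table is returned unchanged.
    """
    if t.mode == RELATIVE:
        return t
    sums = t.values.sum(axis=1)
    if (sums <= 0).any():
        bad = t.data.index[sums <= 0][0]
        raise ValueError(f"all-zero sample {bad!r}")
    return AbundanceTable(t.data.div(sums, axis=0), mode=RELATIVE)


def read_taxonomy(path) -> pd.DataFrame:
    """Read an OTU taxonomy TSV (otu_id + ranked label columns).

    Missing ranks are stored explicitly as ``"unclassified"``.
    """
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    tax.index = tax.index.astype(str)
    if tax.index.has_duplicates:
        raise ValueError("duplicate OTU ids in taxonomy")
    return tax.fillna("unclassified").replace("", "unclassified")


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV; empty cells become missing (NaN)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    return meta


def read_tree(path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def aggregate_by_taxon(
    t: AbundanceTable, tax: pd.DataFrame, rank: str, label: str
) -> pd.Series:
    """Per-sample total relative abundance of OTUs whose *rank* equals *label*.

    Matching is case-sensitive and exact.  A label absent from the taxonomy
    yields an all-zero vector (not an error).
    """
    if t.mode != RELATIVE:
        raise ValueError("aggregate_by_taxon requires a relative-mode table")
    if rank not in tax.columns:
        raise ValueError(f"unknown rank {rank!r}; have {list(tax.columns)}")
    labels = tax[rank].reindex(t.otu_ids).fillna("unclassified")
    mask = (labels == label).to_numpy()
    return pd.Series(
        t.values[:, mask].sum(axis=1), index=t.data.index, name=label
    )


def filter_by_median_abundance(t: AbundanceTable, threshold: float) -> AbundanceTable:
    """Keep OTUs whose across-sample median relative abundance >= threshold.

    The threshold is a fraction (0.0001 = 0.01%).  Retained columns are NOT
    renormalized, so per-sample totals of the filtered table report how much
    of the community the retained OTUs capture.
    """
    if t.mode != RELATIVE:
        raise ValueError("filter_by_median_abundance requires a relative-mode table")
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold {threshold} outside [0, 1)")
    medians = np.median(t.values, axis=0)
    keep = medians >= threshold
    return AbundanceTable(
        t.data.loc[:, t.data.columns[keep]], mode=RELATIVE, closed=False
    )
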