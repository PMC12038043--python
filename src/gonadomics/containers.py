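"""Shared in-memory containers for the pipeline.

Conventions: genomic coordinates are 0-based half-open throughout (BED
convention); matrices are features-by-cells sparse CSR with string indexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import sparse

logger = logging.getLogger("gonadomics")

#: Columns every cell table must carry before QC gating.
CELL_TABLE_COLUMNS = (
    "cell_id", "pct_mito", "pct_ribo", "pct_hemo", "n_genes_detected",
    "frip", "n_frag_in_peaks", "pct_blacklist",
)


@dataclass
class FeatureMatrix:
    """Sparse counts, features (genes or peaks) x cells.

    ``normalized`` flags whether :attr:`X` still holds raw counts.
    """

    X: sparse.csr_matrix
    feature_ids: pd.Index
    cell_ids: pd.Index
    normalized: bool = False

    def __post_init__(self) -> None:
        self.X = sparse.csr_matrix(self.X)
        self.feature_ids = pd.Index(self.feature_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.X.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        if self.feature_ids.has_duplicates or self.cell_ids.has_duplicates:
            raise ValueError("feature and cell identifiers must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def subset_cells(self, cell_ids) -> "FeatureMatrix":
        idx = self.cell_ids.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            missing = pd.Index(cell_ids)[idx < 0]
            raise KeyError(f"unknown cells: {list(missing[:5])}")
        return FeatureMatrix(self.X[:, idx], self.feature_ids,
                             pd.Index(cell_ids), self.normalized)

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        idx = self.feature_ids.get_indexer(pd.Index(feature_ids))
        if (idx < 0).any():
            missing = pd.Index(feature_ids)[idx < 0]
            raise KeyError(f"unknown features: {list(missing[:5])}")
        return FeatureMatrix(self.X[idx, :], pd.Index(feature_ids),
                             self.cell_ids, self.normalized)


class IntervalSet:
    """Ordered genomic intervals (0-based half-open) with names.

    Stored as a DataFrame with columns chrom/start/end/name, sorted by
    (chrom, start, end); iteration and indexing follow that order.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"interval table needs columns {sorted(required)}")
        df = df.copy()
        if "name" not in df.columns:
            df["name"] = [f"peak_{i}" for i in range(len(df))]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            first = df[bad].iloc[0]
            raise ValueError(
                f"invalid interval on {first['chrom']}: "
                f"start {first['start']} >= end {first['end']}"
            )
        self.df = (
            df[["chrom", "start", "end", "name"]]
            .sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.df.equals(other.df)

    @property
    def names(self) -> pd.Index:
        return pd.Index(self.df["name"])

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def midpoints(self) -> np.ndarray:
        """Integer midpoints, floor((start + end) / 2)."""
        return ((self.df["start"] + self.df["end"]) // 2).to_numpy()

    def restrict_chroms(self, genome) -> "IntervalSet":
        allowed = set(genome)
        keep = self.df["chrom"].isin(allowed)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d intervals on non-canonical chromosomes",
                        dropped)
        return IntervalSet(self.df[keep])

    def subset(self, names) -> "IntervalSet":
        keep = self.df["name"].isin(set(names))
        return IntervalSet(self.df[keep])

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees over the half-open intervals."""
        out: dict[str, IntervalTree] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[chrom] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"], sub["name"])
            )
        return out

    def overlap_mask(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per interval: overlaps any interval of ``other`` by >= 1 bp."""
        trees = other.trees()
        mask = np.zeros(len(self.df), dtype=bool)
        for i, (chrom, start, end) in enumerate(
            zip(self.df["chrom"], self.df["start"], self.df["end"])
        ):
            tree = trees.get(chrom)
            if tree is not None and tree.overlaps(start, end):
                mask[i] = True
        return mask


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the per-cell QC table schema and invariants."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table is missing columns: {missing}")
    if cells["cell_id"].duplicated().any():
        dups = cells.loc[cells["cell_id"].duplicated(), "cell_id"]
        raise ValueError(f"duplicate cell ids: {list(dups[:5])}")
    for col in ("pct_mito", "pct_ribo", "pct_hemo", "frip", "pct_blacklist"):
        vals = cells[col]
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    for col in ("n_genes_detected", "n_frag_in_peaks"):
        if (cells[col] < 0).any():
            raise ValueError(f"{col} must be non-negative")
    return cells


@dataclass
class GeneModels:
    """Per-gene chrom, body [start, end), strand and derived TSS."""

    df: pd.DataFrame = field()

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand", "gene_id"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"gene model table needs columns {sorted(required)}")
        df = self.df.copy()
        dup = df["gene_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate gene ids: {sorted(df.loc[dup, 'gene_id'].unique())}"
            )
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError("strand must be '+' or '-'")
        if "tss" not in df.columns or df["tss"].isna().any():
            derived = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
            if "tss" in df.columns:
                df["tss"] = df["tss"].fillna(pd.Series(derived, index=df.index))
            else:
                df["tss"] = derived
        df["tss"] = df["tss"].astype(np.int64)
        self.df = df.sort_values(["chrom", "tss", "gene_id"],
                                 kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)
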