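"""Per-cell quality gates for the RNA and ATAC assays.

A nucleus survives only if it passes BOTH assays. Every comparison is
strict: a cell at exactly 10% mitochondrial counts, or exactly 250
fragments in peaks, fails. Metrics and thresholds:

RNA:  pct_mito < 0.10, pct_ribo < 0.10, pct_hemo < 0.005,
      n_genes_detected > 500
ATAC: frip > 0.20, 250 < n_frag_in_peaks < 25000, pct_blacklist < 0.05
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import Thresholds

logger = logging.getLogger("gonadomics")

RNA_METRICS = ("pct_mito", "pct_ribo", "pct_hemo", "n_genes_detected")
ATAC_METRICS = ("frip", "n_frag_in_peaks", "pct_blacklist")


def _require_metrics(cells: pd.DataFrame, metrics) -> None:
    for col in metrics:
        if col not in cells.columns:
            raise ValueError(f"cell table is missing metric {col!r}")
        if cells[col].isna().any():
            cell = cells.loc[cells[col].isna(), "cell_id"].iloc[0]
            raise ValueError(f"cell {cell!r} has missing metric {col!r}")


def rna_pass(cells: pd.DataFrame, t: Thresholds | None = None) -> pd.Series:
    """Boolean mask of cells passing all four RNA gates (strict)."""
    t = t or Thresholds()
    _require_metrics(cells, RNA_METRICS)
    mask = (
        (cells["pct_mito"] < t.rna_mito_max)
        & (cells["pct_ribo"] < t.rna_ribo_max)
        & (cells["pct_hemo"] < t.rna_hemo_max)
        & (cells["n_genes_detected"] > t.rna_min_genes)
    )
    mask.name = "rna_pass"
    return mask


def atac_pass(cells: pd.DataFrame, t: Thresholds | None = None) -> pd.Series:
    """Boolean mask of cells passing all three ATAC gates (strict)."""
    t = t or Thresholds()
    _require_metrics(cells, ATAC_METRICS)
    mask = (
        (cells["frip"] > t.atac_frip_min)
        & (cells["n_frag_in_peaks"] > t.atac_frag_min)
        & (cells["n_frag_in_peaks"] < t.atac_frag_max)
        & (cells["pct_blacklist"] < t.atac_blacklist_max)
    )
    mask.name = "atac_pass"
    return mask


def failure_report(cells: pd.DataFrame, t: Thresholds | None = None) -> pd.DataFrame:
    """Per-criterion failure counts (a cell may fail several)."""
    t = t or Thresholds()
    criteria = {
        "mito": cells["pct_mito"] >= t.rna_mito_max,
        "ribo": cells["pct_ribo"] >= t.rna_ribo_max,
        "hemo": cells["pct_hemo"] >= t.rna_hemo_max,
        "n_genes": cells["n_genes_detected"] <= t.rna_min_genes,
        "frip": cells["frip"] <= t.atac_frip_min,
        "frag_low": cells["n_frag_in_peaks"] <= t.atac_frag_min,
        "frag_high": cells["n_frag_in_peaks"] >= t.atac_frag_max,
        "blacklist": cells["pct_blacklist"] >= t.atac_blacklist_max,
    }
    return pd.DataFrame(
        {"criterion": list(criteria), "n_failed": [int(m.sum()) for m in criteria.values()]}
    )


def joint_filter(
    cells: pd.DataFrame, t: Thresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain cells passing both assays; return (retained, failure report)."""
    t = t or Thresholds()
    keep = rna_pass(cells, t) & atac_pass(cells, t)
    report = failure_report(cells, t)
    logger.info("QC retained %d / %d cells", int(keep.sum()), len(cells))
    return cells[keep].reset_index(drop=True), report
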