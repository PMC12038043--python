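"""Cross-dataset statistics: ChIP targets x DEGs, DA x ChIP overlap, and
peak-gene linkage.

Reported percentages follow the truncation convention of the source
contingency tables: percent = floor(1000 * n / d) / 10 (one decimal,
never rounded up), so 169/386 -> 43.7 and 328/684 -> 47.9.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .config import Thresholds
from .containers import FeatureMatrix, GeneModels, IntervalSet
from .differential import bh_adjust, log_normalize
from .similarity import depth_normalize

logger = logging.getLogger("gonadomics")


def truncate_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage truncated (not rounded) to ``decimals`` decimal places."""
    if denominator == 0:
        return math.nan
    scale = 10**decimals
    return math.floor(scale * 100.0 * numerator / denominator) / scale


def assign_targets(
    annotated: pd.DataFrame, promoter_only: bool = False
) -> tuple[set, pd.DataFrame]:
    """TF target genes: the gene most proximal to each (significant) peak.

    Returns (target gene set, per-peak mapping). ``promoter_only``
    restricts to peaks classified as promoter.
    """
    mapping = annotated.dropna(subset=["nearest_gene"])
    if promoter_only:
        mapping = mapping[mapping["context"] == "promoter"]
    mapping = mapping[["name", "nearest_gene", "context"]].reset_index(drop=True)
    return set(mapping["nearest_gene"]), mapping


def intersect_deg_targets(targets: set, deg_a: set, deg_b: set) -> pd.DataFrame:
    """Counts of the 7 Venn regions of (targets, deg_a, deg_b) plus coverage.

    Region labels use T/A/B membership flags; coverage rows give the
    fraction of each DEG set containing a target (truncated percent).
    """
    targets, deg_a, deg_b = set(targets), set(deg_a), set(deg_b)
    universe = targets | deg_a | deg_b
    regions = {"T": 0, "A": 0, "B": 0, "TA": 0, "TB": 0, "AB": 0, "TAB": 0}
    for gene in universe:
        key = ""
        if gene in targets:
            key += "T"
        if gene in deg_a:
            key += "A"
        if gene in deg_b:
            key += "B"
        regions[key] += 1
    rows = [{"region": k, "count": v} for k, v in regions.items()]
    for label, deg in (("A", deg_a), ("B", deg_b)):
        covered = len(deg & targets)
        rows.append(
            {
                "region": f"pct_{label}_with_target",
                "count": truncate_percent(covered, len(deg)) if deg else math.nan,
            }
        )
    return pd.DataFrame(rows)


def overlap_fraction(
    da_peaks: IntervalSet, chip: IntervalSet, label: str = ""
) -> dict:
    """Fraction of DA peaks containing (>= 1 bp overlap) a ChIP peak."""
    n = len(da_peaks)
    if n == 0:
        logger.warning("empty DA peak set for %r; percent undefined", label)
        return {"group": label, "n_da_peaks": 0, "n_overlapping": 0,
                "percent": math.nan}
    mask = da_peaks.overlap_mask(chip)
    k = int(mask.sum())
    return {"group": label, "n_da_peaks": n, "n_overlapping": k,
            "percent": truncate_percent(k, n)}


def link_peaks(
    atac: FeatureMatrix,
    rna: FeatureMatrix,
    peaks: IntervalSet,
    genes: GeneModels,
    atac_totals=None,
    window: int = 500_000,
    t: Thresholds | None = None,
) -> pd.DataFrame:
    """Peak-gene links by accessibility-expression correlation across cells.

    For every peak-gene pair with |peak midpoint - TSS| <= ``window`` on
    the same chromosome, the Pearson correlation of depth-normalized
    binarized accessibility against log-normalized expression is tested via
    the t-transform (n - 2 d.f.) and BH-corrected over all tested pairs.
    A link is a pair with adj_p < 0.05. Zero-variance features are skipped.
    """
    t = t or Thresholds()
    if not atac.cell_ids.equals(rna.cell_ids):
        raise ValueError("ATAC and RNA matrices must share the same cells")
    n = len(atac.cell_ids)
    if n < 3:
        raise ValueError("need >= 3 cells for correlation")

    binarized = FeatureMatrix((atac.X > 0).astype(float), atac.feature_ids,
                              atac.cell_ids, normalized=False)
    A = depth_normalize(binarized, atac_totals).X.toarray()
    E = log_normalize(rna).X.toarray()

    peak_rows = atac.feature_ids.get_indexer(peaks.names)
    if (peak_rows < 0).any():
        raise KeyError("interval names must match ATAC matrix features")
    gene_rows = {g: i for i, g in enumerate(rna.feature_ids)}

    mids = peaks.midpoints()
    rows = []
    skipped = 0
    for (chrom, name), mid, arow in zip(
        zip(peaks.df["chrom"], peaks.df["name"]), mids, peak_rows
    ):
        sub = genes.df[genes.df["chrom"] == chrom]
        near = sub[np.abs(sub["tss"] - mid) <= window]
        if len(near) == 0:
            continue
        x = A[arow]
        if x.std() == 0:
            skipped += len(near)
            continue
        for gene_id in near["gene_id"]:
            grow = gene_rows.get(gene_id)
            if grow is None:
                continue
            y = E[grow]
            if y.std() == 0:
                skipped += 1
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
            t_stat = r_clip * math.sqrt((n - 2) / (1 - r_clip**2))
            p = 2.0 * float(stats.t.sf(abs(t_stat), df=n - 2))
            rows.append((name, gene_id, r, p))
    if skipped:
        logger.info("skipped %d zero-variance peak-gene pairs", skipped)
    out = pd.DataFrame(rows, columns=["peak_id", "gene_id", "correlation", "p"])
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["linked"] = out["adj_p"] < t.adj_p_max
    return out


def linked_fraction(da_peak_names, links: pd.DataFrame, label: str = "") -> dict:
    """Percent of the DA peaks appearing in >= 1 significant link."""
    da_peak_names = list(da_peak_names)
    n = len(da_peak_names)
    if n == 0:
        return {"group": label, "n_da_peaks": 0, "n_overlapping": 0,
                "percent": math.nan}
    linked = set(links.loc[links["linked"], "peak_id"])
    k = sum(1 for p in da_peak_names if p in linked)
    return {"group": label, "n_da_peaks": n, "n_overlapping": k,
            "percent": truncate_percent(k, n)}
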