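"""ChIP peak post-processing and genomic-context classification.

Called peaks are resized to a fixed width (default 300 bp) around their
midpoints, peaks touching blacklist regions or non-canonical chromosomes
are dropped, and each surviving peak is classified by its midpoint's
position relative to the nearest annotated TSS:

promoter    signed distance in [-1000, 0] (gene-orientation upstream of,
            or exactly at, the TSS)
gene_body   midpoint inside the nearest gene's body [start, end)
upstream    signed distance in [-10000, -1000)
intergenic  everything else

Signed distance is strand-aware: negative means upstream of the TSS in
the gene's orientation. Classes are exclusive with precedence
promoter > gene_body > upstream > intergenic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import Thresholds
from .containers import GeneModels, IntervalSet

logger = logging.getLogger("gonadomics")

CONTEXT_CLASSES = ("promoter", "gene_body", "upstream", "intergenic")


def resize_peaks(
    peaks: IntervalSet,
    width: int,
    chrom_sizes: dict[str, int] | None = None,
) -> IntervalSet:
    """Fixed-width intervals centered on the original midpoints.

    Output is [mid - floor(w/2), mid + ceil(w/2)), clipped at chromosome
    bounds (with a logged count) when ``chrom_sizes`` is given.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    mid = peaks.midpoints()
    start = mid - width // 2
    end = mid + (width + 1) // 2
    df = peaks.df.copy()
    df["start"] = start
    df["end"] = end
    clipped = 0
    low = df["start"] < 0
    clipped += int(low.sum())
    df.loc[low, "start"] = 0
    if chrom_sizes is not None:
        limits = df["chrom"].map(chrom_sizes)
        high = df["end"] > limits
        clipped += int(high.sum())
        df.loc[high, "end"] = limits[high]
    if clipped:
        logger.info("clipped %d resized peaks at chromosome bounds", clipped)
    return IntervalSet(df)


def filter_peaks(
    peaks: IntervalSet, blacklist: IntervalSet | None, genome
) -> IntervalSet:
    """Drop peaks overlapping the blacklist (>= 1 bp) or off-genome chroms."""
    kept = peaks.restrict_chroms(genome) if genome is not None else peaks
    if blacklist is not None and len(blacklist):
        mask = kept.overlap_mask(blacklist)
        if mask.any():
            logger.info("excluded %d peaks overlapping blacklist regions",
                        int(mask.sum()))
        kept = IntervalSet(kept.df[~mask])
    return kept


def classify_context(
    peaks: IntervalSet,
    genes: GeneModels,
    t: Thresholds | None = None,
) -> pd.DataFrame:
    """Annotate every peak with nearest gene, signed TSS distance, context.

    Nearest gene minimizes |midpoint - TSS| on the same chromosome
    (equidistant ties break lexicographically by gene id, logged); a peak
    on a chromosome with no genes is intergenic.
    """
    t = t or Thresholds()
    by_chrom = {
        chrom: sub.reset_index(drop=True)
        for chrom, sub in genes.df.groupby("chrom", sort=False)
    }
    mids = peaks.midpoints()
    records = []
    n_ties = 0
    for (chrom, name), mid in zip(
        zip(peaks.df["chrom"], peaks.df["name"]), mids
    ):
        sub = by_chrom.get(chrom)
        if sub is None or len(sub) == 0:
            records.append((name, chrom, int(mid), None, np.nan, "intergenic"))
            continue
        dist = np.abs(sub["tss"].to_numpy() - mid)
        best = dist.min()
        candidates = sub[dist == best]
        if len(candidates) > 1:
            n_ties += 1
            candidates = candidates.sort_values("gene_id", kind="mergesort")
        gene = candidates.iloc[0]
        if gene["strand"] == "+":
            signed = int(mid - gene["tss"])
        else:
            signed = int(gene["tss"] - mid)
        if -t.promoter_upstream <= signed <= 0:
            context = "promoter"
        elif gene["start"] <= mid < gene["end"]:
            context = "gene_body"
        elif -t.upstream_window <= signed < -t.promoter_upstream:
            context = "upstream"
        else:
            context = "intergenic"
        records.append((name, chrom, int(mid), gene["gene_id"], signed, context))
    if n_ties:
        logger.info("broke %d equidistant nearest-gene ties by gene id", n_ties)
    return pd.DataFrame(
        records,
        columns=["name", "chrom", "midpoint", "nearest_gene",
                 "signed_distance_to_tss", "context"],
    )


def context_composition(annotated: pd.DataFrame) -> pd.Series:
    """Percent of peaks per context class, rounded to the nearest integer."""
    if len(annotated) == 0:
        raise ValueError("no annotated peaks")
    counts = annotated["context"].value_counts()
    pct = {
        cls: float(np.rint(100.0 * counts.get(cls, 0) / len(annotated)))
        for cls in CONTEXT_CLASSES
    }
    return pd.Series(pct, name="percent")
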