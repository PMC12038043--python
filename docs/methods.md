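# Methods

This note documents the models, parameter choices and numerical
conventions behind `gonadomics`, and what the synthetic-data tests do and
do not establish about real data.

## Coordinate and formatting conventions

All genomic coordinates are 0-based half-open (BED convention) in memory
and on disk; any 1-based dialect must be converted at the boundary. Two
intervals overlap when they share at least one base. Reported
percentages are truncated, not rounded, to one decimal
(`floor(1000·n/d)/10`): truncation is the only convention consistent
with printed pairs such as 169/386 → 43.7 and 328/684 → 47.9, where
round-half-up would give 43.8 and 48.0.

## Quality gating

Cells must pass both assays; every comparison is strict, following the
wording of the gates ("<10%", ">250"), so boundary cells fail:
mito < 0.10, ribo < 0.10, hemoglobin < 0.005 (all as fractions of RNA
counts), detected genes > 500; FRiP > 0.20, 250 < fragments-in-peaks
< 25,000, blacklist fraction < 0.05. Hemoglobin content is interpreted
as a fraction of counts (the alternative — fraction of detected genes —
is not distinguishable from the stated gates; this reading is the
conventional one). Doublet and ambient-RNA removal are not
re-implemented; the generator can emulate their effect by pre-dropping
labeled cells.

## Chromatin similarity

Per-cell ATAC signal is depth-normalized (counts ÷ per-cell fragment
total × median total — simple, monotone and transparent), the most
variable peaks are chosen by plain variance of the normalized signal
(deterministic tie-break by peak id) rather than a dispersion-model
selector: the downstream use (a distance ranking over cluster means) is
robust to the selector and a plain criterion is oracle-testable.
Clusters below `min_cluster_cells = 3` are excluded, mirroring the
removal of a two-cell cluster in this kind of study. The dendrogram uses
complete linkage (configurable: complete | average | single); the
linkage method and whether signals are binarized before averaging are
genuinely open choices, so both are parameters with these documented
defaults. Nearest-cluster ties break by cluster id order.

## Differential testing

RNA: counts per cell are scaled to 10,000 and log1p-transformed; genes
are compared by a two-sided Wilcoxon rank-sum test. Exact enumeration is
used only when both groups have ≤ 50 cells *and* the pooled sample is
tie-free; count data essentially always contain ties, where the exact
null is invalid, so the normal approximation with tie correction is the
effective default. The effect is the log2 ratio of mean normalized
expression with a 1/(n_a+n_b) pseudocount.

ATAC: peak signal is binarized per cell; the test is a likelihood-ratio
comparison (χ², 1 d.f.) of two logistic regressions of group membership
— intercept + standardized log fragment total, with and without the peak
indicator. Conditioning on the fragment covariate means a peak whose
apparent openness is driven purely by per-cell depth stays null while a
raw proportion test fires (verified by simulation). Peaks closed in
every cell of both groups are skipped. Effects are
log2((rate_a+ε)/(rate_b+ε)), ε = 1/(n_a+n_b).

Benjamini–Hochberg correction is applied per contrast across all tested
features; significance is strict adj p < 0.05. No minimum-fraction or
fold-change prefilters are applied by default (only the adjusted-p gate
is stated for the procedure being modeled); both are available as
options. No DA effect-size threshold is applied by default for the same
reason.

## ChIP peak annotation

Peaks are resized to `chip_peak_width = 300` bp around the integer
midpoint `⌊(start+end)/2⌋` and clipped at chromosome bounds (logged).
Peaks overlapping the blacklist by ≥ 1 bp or lying off the canonical
chromosome list are removed. Context classification keys on the resized
peak's midpoint, not any-overlap: peaks are midpoint-centered 300-mers,
and midpoint rules are tie-free. The nearest gene minimizes
|midpoint − TSS| on the same chromosome (equidistant ties break
lexicographically by gene id, logged); the signed distance is negative
upstream of the TSS in the gene's orientation. Classes are exclusive
with precedence promoter > gene body > upstream > intergenic: promoter
for signed distance in [−1000, 0] (a midpoint exactly at the TSS counts
as promoter), gene body for a midpoint inside the nearest gene's body,
upstream for [−10000, −1000). The upstream window is sometimes printed
elsewhere as "−10 kb to 1 kb"; that reading would overlap the promoter
definition, so the window is implemented as [−10 kb, −1 kb) and the
discrepancy is flagged here rather than silently reconciled.

## Integration

Target genes are the nearest gene per (significant) ChIP peak, with a
promoter-restricted variant. DA × ChIP overlap uses the ≥ 1 bp
predicate. Peak–gene links are tested for every pair with
|midpoint − TSS| ≤ 500 kb (the conventional search window,
configurable): Pearson correlation across cells of depth-normalized
binarized accessibility against log-normalized expression, p from the
t-transform of r with n − 2 d.f., BH over all tested pairs, link =
adj p < 0.05. The analytic t-transform was chosen over a GC-matched
background z-score because it is deterministic and checkable against
closed forms at desk scale; the linkage significance cutoff and window
are not externally fixed, so both are parameters with these defaults.
Zero-variance peaks or genes are skipped and logged.

## Motif analysis and TF ranking

PFMs (JASPAR text, bracketed or plain rows) become probability matrices
with a +0.5 pseudocount and log-odds against a uniform background. A
hit is any window on either strand scoring ≥ `threshold_frac = 0.8` of
the motif's maximum attainable score — simple and deterministic; a
p-value-calibrated threshold is out of scope. Enrichment of hits in a
foreground peak set versus a disjoint background is the upper-tail
hypergeometric probability of the 2×2 table, BH-corrected across motifs;
fold enrichment is the ratio of with-motif fractions (infinity sentinel
when the background has none). The background is GC-matched by sampling
candidates to the foreground's GC histogram (bin width 0.05, seeded),
falling back to all non-foreground peaks when a bin is empty (logged);
for the unrestricted run the candidate pool is all scanned peaks outside
the foreground (the natural default where no background is externally
specified).

Candidate TFs must pass both gates — motif adj p < 0.05 and DE
adj p < 0.05 upregulated on the queried side. "Combining" the two
criteria is operationalized as the rank-sum of the two adjusted
p-values (ties by motif adj p, then gene id): rank-sum is scale-free and
invariant to monotone transforms of either column; a product of
−log10 p alternative is available behind a config key. The
ChIP-restricted analysis reruns the same pipeline with the foreground
narrowed to DA peaks carrying a ChIP peak and the background set to the
remaining DA peaks on the same side; when every DA peak is covered the
background falls back to all other scanned peaks, making the run
coincide with the unrestricted one.

## Empirical projection

For each direction of the bulk DEG list (adj p < 0.05): per-cluster mean
log-normalized expression (clusters under 3 cells ignored; absent genes
dropped and logged), per-gene z-scores across clusters with the sample
(n−1) standard deviation — constant rows become all-zero and are flagged
rather than dropped. A cluster is "most affected" when the fraction of
DEGs with z > 1 strictly exceeds 0.20 (both comparisons strict, so a
fraction of exactly 20% or a z of exactly 1 does not count). The
affected-population statistic is evaluated on the cluster-average z
matrix, not per-cell values: the procedure being modeled scales
per-cluster averages, and the per-cell layer exists only for heatmap
export. Gene groups come from complete-linkage hierarchical clustering
of the z rows; the cut k is the largest k (k = 2, 3, …) whose smallest
group holds ≥ ⌈0.02 · n⌉ genes, else k = 1. Rows merging at height zero
(identical profiles) cap the largest meaningful k, so an all-identical
list yields a single group. With short gene lists (n < 100) the 2% floor
is ⌈0.02n⌉ = 1 and the rule degenerates to the largest distinguishable
k; this is the rule taken literally and matters only at desk scale.
Cell-cycle/mitochondrial regression for the cosmetic per-cell heatmap
export is not implemented (it requires external gene lists) — a
documented deviation that does not touch the affected-population
statistic.

## Synthetic data

The generator is a pure function of (design, seed) and emulates exactly
the structure the analysis assumes: RNA counts are negative binomial
with mean = base_expression[gene, cluster] × a log-normal cell size
factor (dispersion 2.0); accessibility is Bernoulli with the
peak-by-cluster open probability scaled by the cell's fragment-depth
factor (fragment totals log-uniform 1,000–15,000, factor clipped to
[0.5, 2]); QC metrics are scaled Beta draws inside the passing region,
with failing cells planted by explicit override so expected counts are
exact, never by tail chance. Geography is two synthetic chromosomes of
10 Mb — small enough for brute-force interval oracles — with evenly
spaced genes (random strand, 5–15 kb bodies) and 500 bp peaks on a
jittered grid.

The default design (6 clusters × 150 cells, 300 genes, 400 peaks)
carries a progenitor/derivative pair (c0, c3): the derivative's
open-probability column is a copy of the progenitor's perturbed by
ε = 0.02 noise, a shared 30-peak lineage block separates the pair from
the other clusters, and 30 + 40 designed DA peaks (open rates 0.8 vs
0.1) encode the pair's differential accessibility. Each remaining
cluster has 15 exclusive 4-fold marker genes and 30 exclusive
high-open marker peaks. ChIP peaks are placed with exact
largest-remainder context composition at the 35/34/26/5 mix, avoiding
ATAC peaks so the zero-overlap control is exact; DA-covering ChIP peaks
(43.7% of the progenitor side, 3.8% of the derivative side — the
study-level proportions) are appended beyond the context budget.
Peak–gene links are planted for 48.7%/47.9% of the two DA sides by
relocating those peaks a few kb from a marker gene of their own cluster,
so accessibility and expression co-vary through the cluster structure.
Bulk DEG tables plant designed up/down genes with tiny p-values against
U(0.5, 1) nulls, so BH at 0.05 flags exactly the designed set. About 5%
of cells carry planted QC failures in the full default bundle.

What the synthetic data does **not** emulate: fragment-level ATAC
structure, doublets and ambient RNA (their removal is out of scope),
batch effects, trans-chromosomal regulation, realistic motif syntax or
co-occurrence, and genome-scale peak/gene counts. Passing recovery
tests therefore demonstrates correctness of the computations under the
assumed generative structure — not robustness to the artifacts of real
libraries.

## Problem sizes

Tests and the acceptance script run at desk scale by design: null
simulations use 1,000 features over 2 × 200 cells; planted-DA recovery
uses 100 seeded replicates of 200 vs 200 cells; similarity recovery uses
20 seeds of a 4 × 80-cell design; the full bundle is 900 cells. These
sizes give binomial error bars tight enough for the 3-s.d. checks while
keeping the whole suite under a minute.
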