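"""Synthetic "testis multiome" generator with recorded ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: cluster-specific negative-binomial RNA counts, cluster-specific
Bernoulli peak accessibility scaled by per-cell fragment depth, per-cell
QC metrics with explicitly planted failures, a gene/peak geography on two
synthetic chromosomes, a ChIP peak set with exact genomic-context
composition and controlled overlap with the true differentially accessible
peaks, peak sequences with planted motif occurrences, and a bulk
differential-expression table. Every planted signal is recorded in truth
tables that downstream recovery tests score against; the pipeline itself
never reads them.

The default design carries a progenitor/derivative cluster pair ("c0" and
"c3"): the derivative's accessibility profile is a copy of the
progenitor's perturbed by a small epsilon plus the designed differential
peaks, so the pair is mutually nearest in chromatin space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import FeatureMatrix, GeneModels, IntervalSet
from .motifs import MotifModel, reverse_complement

logger = logging.getLogger("gonadomics")

#: values planted when a cell is designated to fail a QC criterion
_FAIL_VALUES = {
    "mito": ("pct_mito", 0.25),
    "ribo": ("pct_ribo", 0.25),
    "hemo": ("pct_hemo", 0.02),
    "n_genes": ("n_genes_detected", 200),
    "frip": ("frip", 0.10),
    "frag_low": ("n_frag_in_peaks", 100),
    "frag_high": ("n_frag_in_peaks", 40000),
    "blacklist": ("pct_blacklist", 0.20),
}


def largest_remainder(fractions, n: int) -> np.ndarray:
    """Integer counts summing to ``n`` proportional to ``fractions``.

    Largest-remainder rounding: floor everything, then hand the leftover
    units to the largest fractional parts (ties to earlier entries).
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.sum() <= 0:
        raise ValueError("fractions must sum to a positive value")
    quota = fractions / fractions.sum() * n
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n - counts.sum()
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return counts


@dataclass
class SimDesign:
    """Parameters of one synthetic multiome draw.

    ``base_expression`` (genes x clusters) and ``peak_open_prob``
    (peaks x clusters) may be supplied directly; otherwise they are
    generated with per-cluster markers and the progenitor/derivative pair
    structure described in the module docstring.
    """

    n_cells_per_cluster: tuple = (150,) * 6
    n_genes: int = 300
    n_peaks: int = 400
    genome_length_per_chrom: dict = field(
        default_factory=lambda: {"chrS1": 10_000_000, "chrS2": 10_000_000}
    )
    rna_dispersion: float = 2.0
    base_expression: np.ndarray | None = None
    peak_open_prob: np.ndarray | None = None
    context_mix: tuple = (0.35, 0.34, 0.26, 0.05)
    chip_overlap_frac: dict = field(default_factory=dict)
    link_frac: dict = field(default_factory=dict)
    n_chip_peaks: int = 200
    motif_plant_rate: float = 0.6
    qc_fail_rates: dict = field(default_factory=dict)
    gc_content: float = 0.5
    progenitor: str = "c0"
    derivative: str = "c3"
    epsilon: float = 0.02
    markers_per_cluster: int = 15
    marker_peaks_per_cluster: int = 30
    n_da_progenitor: int = 30
    n_da_derivative: int = 40
    peak_width: int = 500
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.n_cells_per_cluster)

    @property
    def cluster_names(self) -> list[str]:
        return [f"c{i}" for i in range(self.n_clusters)]

    def validate(self) -> None:
        if abs(sum(self.context_mix) - 1.0) > 1e-9:
            raise ValueError("context_mix must sum to 1")
        for p in self.context_mix:
            if not 0 <= p <= 1:
                raise ValueError("context_mix entries must lie in [0, 1]")
        if not 0 <= self.motif_plant_rate <= 1:
            raise ValueError("motif_plant_rate must lie in [0, 1]")
        if self.n_clusters < 1 or self.n_genes < 1 or self.n_peaks < 1:
            raise ValueError("cluster, gene and peak counts must be positive")
        if self.base_expression is not None and (
            self.base_expression.shape != (self.n_genes, self.n_clusters)
        ):
            raise ValueError(
                "base_expression shape inconsistent with design: expected "
                f"({self.n_genes}, {self.n_clusters})"
            )
        if self.peak_open_prob is not None and (
            self.peak_open_prob.shape != (self.n_peaks, self.n_clusters)
        ):
            raise ValueError(
                "peak_open_prob shape inconsistent with design: expected "
                f"({self.n_peaks}, {self.n_clusters})"
            )


@dataclass
class SimulatedMultiome:
    """One synthetic draw: data the pipeline sees plus the hidden truth."""

    rna: FeatureMatrix
    atac: FeatureMatrix
    cells: pd.DataFrame
    peaks: IntervalSet
    genes: GeneModels
    truth: dict[str, pd.DataFrame]
    design: SimDesign


# -- geography --------------------------------------------------------------

def _lay_out_genes(design: SimDesign, rng: np.random.Generator) -> GeneModels:
    chroms = list(design.genome_length_per_chrom)
    lengths = np.array([design.genome_length_per_chrom[c] for c in chroms])
    per_chrom = largest_remainder(lengths, design.n_genes)
    rows = []
    gid = 0
    for chrom, n_here, length in zip(chroms, per_chrom, lengths):
        if n_here == 0:
            continue
        spacing = length / (n_here + 1)
        for j in range(n_here):
            anchor = int((j + 1) * spacing)
            body = int(rng.integers(5_000, min(15_000, max(6_000, spacing // 3))))
            strand = "+" if rng.random() < 0.5 else "-"
            start = anchor
            end = min(anchor + body, length - 1)
            rows.append((chrom, start, end, strand, f"gene_{gid:04d}"))
            gid += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "gene_id"])
    return GeneModels(df)


def _lay_out_peaks(design: SimDesign, rng: np.random.Generator) -> IntervalSet:
    chroms = list(design.genome_length_per_chrom)
    lengths = np.array([design.genome_length_per_chrom[c] for c in chroms])
    per_chrom = largest_remainder(lengths, design.n_peaks)
    rows = []
    pid = 0
    w = design.peak_width
    for chrom, n_here, length in zip(chroms, per_chrom, lengths):
        if n_here == 0:
            continue
        spacing = length / (n_here + 1)
        jitter = int(min(spacing / 4, 10_000))
        for j in range(n_here):
            mid = int((j + 1) * spacing) + int(rng.integers(-jitter, jitter + 1))
            start = max(0, mid - w // 2)
            end = min(int(length), start + w)
            rows.append((chrom, start, end, f"peak_{pid:04d}"))
            pid += 1
    return IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    )


# -- expression / accessibility design --------------------------------------

def _default_base_expression(
    design: SimDesign, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Gene x cluster mean matrix with per-cluster 4-fold marker genes."""
    K, G = design.n_clusters, design.n_genes
    base = np.exp(rng.normal(np.log(0.5), 0.8, size=G)).clip(0.05, 20.0)
    M = np.tile(base[:, None], (1, K))
    m = min(design.markers_per_cluster, G // max(K, 1))
    markers = []
    for k in range(K):
        idx = np.arange(k * m, (k + 1) * m)
        M[idx, k] *= 4.0
        for g in idx:
            markers.append((f"gene_{g:04d}", design.cluster_names[k]))
    truth = pd.DataFrame(markers, columns=["gene_id", "cluster"])
    return M, truth


def _default_peak_open_prob(
    design: SimDesign, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Peak x cluster open-probability matrix with pair structure.

    Non-pair clusters get exclusive high-open marker peaks; the
    progenitor/derivative pair shares a lineage block, differs at the
    designed DA peaks (0.8 vs 0.1) and by epsilon noise elsewhere.
    """
    K, P = design.n_clusters, design.n_peaks
    names = design.cluster_names
    background = rng.uniform(0.05, 0.30, size=P)
    M = np.tile(background[:, None], (1, K))

    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        if cursor + n > P:
            raise ValueError("design needs more peaks than n_peaks provides")
        out = np.arange(cursor, cursor + n)
        cursor += n
        return out

    pair = [c for c in (design.progenitor, design.derivative) if c in names]
    i_pair = [names.index(c) for c in pair]
    others = [i for i in range(K) if i not in i_pair]

    mp = min(design.marker_peaks_per_cluster, max(1, P // (2 * max(K, 1))))
    for k in others:
        idx = take(mp)
        M[np.ix_(idx, [j for j in range(K) if j != k])] = 0.08
        M[idx, k] = 0.75

    da_rows = []
    if len(i_pair) == 2:
        ip, id_ = i_pair
        lineage = take(mp)
        M[lineage, :] = 0.08
        M[lineage, ip] = 0.75
        M[lineage, id_] = 0.75
        up_p = take(design.n_da_progenitor)
        M[up_p, :] = 0.08
        M[up_p, ip] = 0.80
        M[up_p, id_] = 0.10
        up_d = take(design.n_da_derivative)
        M[up_d, :] = 0.08
        M[up_d, id_] = 0.80
        M[up_d, ip] = 0.10
        for i in up_p:
            da_rows.append((f"peak_{i:04d}", f"up_in_{pair[0]}", 0.80, 0.10))
        for i in up_d:
            da_rows.append((f"peak_{i:04d}", f"up_in_{pair[1]}", 0.10, 0.80))
        # epsilon perturbation on everything the pair still shares
        shared = np.setdiff1d(np.arange(P), np.concatenate([up_p, up_d]))
        noise = rng.normal(0.0, design.epsilon, size=len(shared))
        M[shared, id_] = np.clip(M[shared, ip] + noise, 0.01, 0.99)
    truth = pd.DataFrame(
        da_rows,
        columns=["peak_id", "direction", "rate_progenitor", "rate_derivative"],
    )
    return M, truth


# -- QC metrics -------------------------------------------------------------

def _draw_qc_metrics(
    n_cells: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Passing-region metrics from scaled Beta / log-uniform draws."""
    return pd.DataFrame(
        {
            "pct_mito": 0.09 * rng.beta(2, 6, n_cells),
            "pct_ribo": 0.09 * rng.beta(2, 6, n_cells),
            "pct_hemo": 0.0045 * rng.beta(1.5, 6, n_cells),
            "n_genes_detected": rng.integers(800, 4000, n_cells),
            "frip": 0.25 + 0.45 * rng.beta(2, 2, n_cells),
            "n_frag_in_peaks": np.exp(
                rng.uniform(np.log(1000), np.log(15000), n_cells)
            ).astype(int),
            "pct_blacklist": 0.045 * rng.beta(1.5, 6, n_cells),
        }
    )


def _plant_qc_failures(
    cells: pd.DataFrame,
    qc_fail_rates: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Override disjoint cell sets so exactly the designed cells fail."""
    n = len(cells)
    counts = {}
    for criterion, rate in qc_fail_rates.items():
        if criterion not in _FAIL_VALUES:
            raise ValueError(f"unknown QC criterion {criterion!r}")
        counts[criterion] = int(rate) if rate >= 1 else int(round(rate * n))
    total = sum(counts.values())
    if total > n:
        raise ValueError("more planted QC failures than cells")
    chosen = rng.choice(n, size=total, replace=False)
    truth_rows = []
    offset = 0
    for criterion, k in counts.items():
        column, value = _FAIL_VALUES[criterion]
        idx = chosen[offset:offset + k]
        offset += k
        cells.loc[cells.index[idx], column] = value
        for i in idx:
            truth_rows.append((cells.loc[cells.index[i], "cell_id"], criterion))
    return pd.DataFrame(truth_rows, columns=["cell_id", "criterion"])


# -- the main generator -----------------------------------------------------

def simulate_multiome(design: SimDesign) -> SimulatedMultiome:
    """Draw a full synthetic multiome. Pure function of the design (+seed)."""
    design.validate()
    root = np.random.SeedSequence(design.seed)
    (s_geo, s_expr, s_rna, s_atac, s_qc) = [
        np.random.default_rng(s) for s in root.spawn(5)
    ]

    genes = _lay_out_genes(design, s_geo)
    peaks = _lay_out_peaks(design, s_geo)

    if design.base_expression is not None:
        base_expr = np.asarray(design.base_expression, dtype=float)
        marker_truth = pd.DataFrame(columns=["gene_id", "cluster"])
    else:
        base_expr, marker_truth = _default_base_expression(design, s_expr)
    if design.peak_open_prob is not None:
        open_prob = np.asarray(design.peak_open_prob, dtype=float)
        da_truth = pd.DataFrame(
            columns=["peak_id", "direction", "rate_progenitor",
                     "rate_derivative"]
        )
    else:
        open_prob, da_truth = _default_peak_open_prob(design, s_expr)

    link_truth = pd.DataFrame(columns=["peak_id", "gene_id", "direction"])
    if design.link_frac and len(da_truth) and len(marker_truth):
        peaks, link_truth = _plant_links(design, peaks, genes, da_truth,
                                         marker_truth)

    labels = np.repeat(design.cluster_names,
                       np.asarray(design.n_cells_per_cluster))
    n_cells = len(labels)
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    cluster_index = {c: i for i, c in enumerate(design.cluster_names)}
    col_cluster = np.array([cluster_index[c] for c in labels])

    # RNA: negative binomial, mean = base_expression[g, k] * cell size factor
    size_factors = np.exp(s_rna.normal(0.0, 0.3, size=n_cells))
    mu = base_expr[:, col_cluster] * size_factors[None, :]
    r = design.rna_dispersion
    rna_counts = s_rna.negative_binomial(r, r / (r + mu))
    rna = FeatureMatrix(
        sparse.csr_matrix(rna_counts),
        pd.Index([f"gene_{g:04d}" for g in range(design.n_genes)]),
        pd.Index(cell_ids),
    )

    # QC metrics first: ATAC depth scaling uses the fragment totals
    metrics = _draw_qc_metrics(n_cells, s_qc)
    cells = pd.DataFrame({"cell_id": cell_ids, "cluster_label": labels})
    cells = pd.concat([cells, metrics], axis=1)
    qc_truth = _plant_qc_failures(cells, design.qc_fail_rates, s_qc)

    frag = cells["n_frag_in_peaks"].to_numpy(dtype=float)
    depth_factor = np.clip(frag / np.median(frag), 0.5, 2.0)
    q = np.clip(open_prob[:, col_cluster] * depth_factor[None, :], 0.0, 0.99)
    atac_counts = (s_atac.random(q.shape) < q).astype(np.int8)
    # row i of open_prob is peak_<i> by construction; IntervalSet order is
    # positional and diverges from index order once links are planted
    atac = FeatureMatrix(
        sparse.csr_matrix(atac_counts),
        pd.Index([f"peak_{i:04d}" for i in range(design.n_peaks)]),
        pd.Index(cell_ids),
    )

    truth = {
        "qc_failures": qc_truth,
        "cluster_markers": marker_truth,
        "da_peaks": da_truth,
        "de_genes": _pair_de_truth(design, marker_truth),
        "link_plants": link_truth,
    }
    return SimulatedMultiome(rna=rna, atac=atac, cells=cells, peaks=peaks,
                             genes=genes, truth=truth, design=design)


def _plant_links(
    design: SimDesign,
    peaks: IntervalSet,
    genes: GeneModels,
    da_truth: pd.DataFrame,
    marker_truth: pd.DataFrame,
) -> tuple[IntervalSet, pd.DataFrame]:
    """Relocate a designed fraction of DA peaks next to pair marker genes.

    A relocated peak sits a few kb from the TSS of a marker gene of its
    own cluster, so its cluster-specific accessibility co-varies with the
    gene's cluster-specific expression across cells — a plantable
    peak-gene link. Relocation slots avoid collisions with other peaks.
    """
    df = peaks.df.set_index("name")
    trees = peaks.trees()
    gene_df = genes.df.set_index("gene_id")
    cluster_of = {f"up_in_{design.progenitor}": design.progenitor,
                  f"up_in_{design.derivative}": design.derivative}
    width = design.peak_width
    rows = []
    for direction, frac in design.link_frac.items():
        cluster = cluster_of.get(direction)
        if cluster is None:
            raise ValueError(f"unknown DA direction {direction!r}")
        anchors = marker_truth.loc[marker_truth["cluster"] == cluster,
                                   "gene_id"].tolist()
        if not anchors:
            continue
        targets = da_truth.loc[da_truth["direction"] == direction,
                               "peak_id"].tolist()
        n_link = int(np.floor(frac * len(targets) + 0.5))
        for j, peak in enumerate(targets[:n_link]):
            gene = gene_df.loc[anchors[j % len(anchors)]]
            chrom = gene["chrom"]
            length = design.genome_length_per_chrom[chrom]
            placed = False
            for slot in range(60):
                start = int(gene["tss"]) + 3000 + 1200 * (
                    slot + 60 * (j // len(anchors))
                )
                end = start + width
                if end >= length:
                    break
                tree = trees.get(chrom)
                if tree is not None and tree.overlaps(start, end):
                    continue
                old = df.loc[peak]
                trees[old["chrom"]].remove_overlap(int(old["start"]),
                                                   int(old["end"]))
                df.loc[peak, ["chrom", "start", "end"]] = [chrom, start, end]
                if chrom not in trees:
                    from intervaltree import IntervalTree

                    trees[chrom] = IntervalTree()
                trees[chrom].addi(start, end, peak)
                rows.append((peak, gene.name, direction))
                placed = True
                break
            if not placed:
                logger.warning("could not relocate %s near %s; link not "
                               "planted", peak, gene.name)
    new_peaks = IntervalSet(df.reset_index())
    truth = pd.DataFrame(rows, columns=["peak_id", "gene_id", "direction"])
    return new_peaks, truth


def _pair_de_truth(design: SimDesign, marker_truth: pd.DataFrame) -> pd.DataFrame:
    """Markers of the pair clusters double as the pair's true DE genes."""
    rows = []
    for cluster, direction in (
        (design.progenitor, f"up_in_{design.progenitor}"),
        (design.derivative, f"up_in_{design.derivative}"),
    ):
        sub = marker_truth[marker_truth["cluster"] == cluster]
        for g in sub["gene_id"]:
            rows.append((g, direction))
    return pd.DataFrame(rows, columns=["gene_id", "direction"])


# -- ChIP peaks -------------------------------------------------------------

def simulate_chip_peaks(
    design: SimDesign,
    genes: GeneModels,
    da_truth: pd.DataFrame | None = None,
    atac_peaks: IntervalSet | None = None,
    width: int = 300,
) -> tuple[IntervalSet, pd.DataFrame]:
    """Place ChIP peaks with exact genomic-context composition.

    Context counts follow largest-remainder rounding of
    ``context_mix x n_chip_peaks``. Placement anchors each peak's midpoint
    relative to a gene TSS so its true class is unambiguous; peaks are
    rejected if they would touch an ATAC peak (keeping the
    ``chip_overlap_frac = 0`` case exactly overlap-free). When
    ``chip_overlap_frac`` maps a DA direction (e.g. ``"up_in_c0"``) to a
    fraction, that fraction of the direction's true DA peaks additionally
    receives a covering ChIP peak, appended beyond the context budget.
    """
    design.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence(design.seed).spawn(6)[-1]
    )
    counts = largest_remainder(design.context_mix, design.n_chip_peaks)
    gene_df = genes.df
    chrom_len = design.genome_length_per_chrom
    avoid = atac_peaks.trees() if atac_peaks is not None else {}

    def collides(chrom: str, start: int, end: int) -> bool:
        tree = avoid.get(chrom)
        return tree is not None and tree.overlaps(start, end)

    rows = []
    truth_rows = []
    pid = 0
    classes = ("promoter", "gene_body", "upstream", "intergenic")
    for cls, k in zip(classes, counts):
        placed = 0
        attempts = 0
        while placed < k:
            attempts += 1
            if attempts > 200 * max(k, 1):
                raise ValueError(
                    f"could not place {k} {cls} peaks; increase "
                    "genome_length_per_chrom or reduce n_chip_peaks"
                )
            gene = gene_df.iloc[int(rng.integers(len(gene_df)))]
            tss, strand = int(gene["tss"]), gene["strand"]
            sign = 1 if strand == "+" else -1
            if cls == "promoter":
                mid = tss - sign * int(rng.integers(0, 900))
            elif cls == "gene_body":
                body_len = int(gene["end"] - gene["start"])
                if body_len < 3000:
                    continue
                off = int(rng.integers(1500, body_len - 500))
                mid = tss + sign * off
                if not (gene["start"] <= mid < gene["end"]):
                    continue
            elif cls == "upstream":
                mid = tss - sign * int(rng.integers(1500, 9500))
            else:  # intergenic: midway between gene anchors, far from any TSS
                chrom = gene["chrom"]
                sub = gene_df[gene_df["chrom"] == chrom]
                mid = int(rng.integers(200, chrom_len[chrom] - 200))
                if np.abs(sub["tss"] - mid).min() <= 25_000:
                    continue
                inside = ((sub["start"] <= mid) & (mid < sub["end"])).any()
                if inside:
                    continue
            chrom = gene["chrom"]
            start = mid - width // 2
            end = mid + (width + 1) // 2
            if start < 0 or end > chrom_len[chrom]:
                continue
            if collides(chrom, start, end):
                continue
            rows.append((chrom, start, end, f"chip_{pid:04d}"))
            truth_rows.append((f"chip_{pid:04d}", cls, gene["gene_id"], ""))
            pid += 1
            placed += 1

    # DA-covering peaks, beyond the context budget
    if design.chip_overlap_frac and da_truth is not None and \
            atac_peaks is not None and len(da_truth):
        peak_df = atac_peaks.df.set_index("name")
        for direction, frac in design.chip_overlap_frac.items():
            targets = da_truth.loc[da_truth["direction"] == direction,
                                   "peak_id"].tolist()
            n_cover = int(np.floor(frac * len(targets) + 0.5))
            for name in targets[:n_cover]:
                row = peak_df.loc[name]
                mid = int((row["start"] + row["end"]) // 2)
                start = mid - width // 2
                end = mid + (width + 1) // 2
                rows.append((row["chrom"], start, end, f"chip_{pid:04d}"))
                truth_rows.append((f"chip_{pid:04d}", "da_cover", "", name))
                pid += 1

    chip = IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["name", "context", "anchor_gene", "covered_da_peak"],
    )
    return chip, truth


# -- peak sequences with planted motifs -------------------------------------

def simulate_peak_sequences(
    peaks: IntervalSet,
    motif_list: list[MotifModel],
    plants: pd.DataFrame | None = None,
    gc_content: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random sequences per peak, with motif consensus planted as designed.

    ``plants`` columns: peak, motif_id, offset (-1 = random), strand.
    Returns (name -> sequence, realized plant truth).
    """
    rng = rng or np.random.default_rng(0)
    p_gc = gc_content / 2.0
    probs = np.array([0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc])  # A C G T
    bases = np.array(list("ACGT"))
    lengths = dict(zip(peaks.names, peaks.lengths()))
    sequences = {
        name: "".join(rng.choice(bases, size=int(length), p=probs))
        for name, length in lengths.items()
    }
    by_id = {m.motif_id: m for m in motif_list}
    truth_rows = []
    if plants is not None:
        for _, row in plants.iterrows():
            motif = by_id[row["motif_id"]]
            seq = sequences[row["peak"]]
            core = motif.consensus
            if len(core) > len(seq):
                raise ValueError(
                    f"motif {motif.motif_id} consensus longer than peak "
                    f"{row['peak']}"
                )
            offset = int(row.get("offset", -1))
            if offset < 0:
                offset = int(rng.integers(0, len(seq) - len(core) + 1))
            strand = row.get("strand", "+")
            insert = core if strand == "+" else reverse_complement(core)
            sequences[row["peak"]] = (
                seq[:offset] + insert + seq[offset + len(core):]
            )
            truth_rows.append((row["peak"], motif.motif_id, offset, strand))
    truth = pd.DataFrame(
        truth_rows, columns=["peak", "motif_id", "offset", "strand"]
    )
    return sequences, truth


def plan_motif_plants(
    fg_peaks,
    motif_list: list[MotifModel],
    plant_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign each motif to ``plant_rate`` of the foreground peaks."""
    fg_peaks = list(fg_peaks)
    rows = []
    for motif in motif_list:
        k = int(round(plant_rate * len(fg_peaks)))
        chosen = rng.choice(fg_peaks, size=k, replace=False) if k else []
        for peak in chosen:
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((peak, motif.motif_id, -1, strand))
    return pd.DataFrame(rows, columns=["peak", "motif_id", "offset", "strand"])


# -- bulk DE table ----------------------------------------------------------

def simulate_bulk_de(
    gene_ids,
    up_genes,
    down_genes,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """A bulk knockout-vs-control differential table with planted calls.

    Designed genes get tiny p-values and +/- 4-fold effects; nulls draw p
    from U(0.5, 1) so BH at 0.05 flags exactly the designed set.
    Direction ``up_in_a`` = upregulated in the knockout.
    """
    from .differential import bh_adjust

    rng = rng or np.random.default_rng(0)
    gene_ids = list(gene_ids)
    up, down = set(up_genes), set(down_genes)
    if up & down:
        raise ValueError("a gene cannot be both up- and down-regulated")
    rows = []
    for g in gene_ids:
        if g in up:
            lfc = rng.normal(2.0, 0.3)
            p = 10.0 ** (-rng.uniform(8, 20))
        elif g in down:
            lfc = -rng.normal(2.0, 0.3)
            p = 10.0 ** (-rng.uniform(8, 20))
        else:
            lfc = rng.normal(0.0, 0.1)
            p = rng.uniform(0.5, 1.0)
        rows.append((g, lfc, p))
    out = pd.DataFrame(rows, columns=["feature_id", "effect", "p"])
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["effect"] >= 0, "up_in_a", "up_in_b")
    out.loc[out["feature_id"].isin(up), "direction"] = "up_in_a"
    out.loc[out["feature_id"].isin(down), "direction"] = "up_in_b"
    out["significant"] = out["adj_p"] < 0.05
    return out


# -- depth-confounded fixture ----------------------------------------------

def simulate_depth_confounded(
    n_a: int,
    n_b: int,
    rng: np.random.Generator,
    depth_shift: float = 1.0,
    slope: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A peak whose openness is driven purely by fragment depth.

    Group a's depths are shifted up; P(open | depth) is the same logistic
    function of log depth in both groups, so a depth-aware test should
    stay null while a raw proportion test fires. Returns (x, labels, depth).
    """
    log_depth = np.concatenate([
        rng.normal(8.0 + depth_shift, 0.4, n_a),
        rng.normal(8.0, 0.4, n_b),
    ])
    z = (log_depth - log_depth.mean()) / log_depth.std()
    p_open = 1.0 / (1.0 + np.exp(-(-0.5 + slope * z)))
    x = (rng.random(n_a + n_b) < p_open).astype(float)
    labels = np.array(["a"] * n_a + ["b"] * n_b)
    depth = np.exp(log_depth)
    return x, labels, depth
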