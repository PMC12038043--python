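"""Peak resizing, blacklist/genome filtering, genomic-context classification."""

import numpy as np
import pandas as pd
import pytest

from gonadomics import (
    SimDesign,
    classify_context,
    context_composition,
    filter_peaks,
    resize_peaks,
    simulate_chip_peaks,
    simulate_multiome,
)
from gonadomics.containers import GeneModels, IntervalSet


def iv(rows):
    return IntervalSet(pd.DataFrame(rows,
                                    columns=["chrom", "start", "end", "name"]))


def genes(rows):
    return GeneModels(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene_id"]))


def test_resize_hand_cases():
    out = resize_peaks(iv([("chr1", 100, 500, "p")]), 300)
    assert out.df.iloc[0][["start", "end"]].tolist() == [150, 450]
    clipped = resize_peaks(iv([("chr1", 0, 2, "p")]), 300)
    assert clipped.df.iloc[0][["start", "end"]].tolist() == [0, 151]


def test_resize_random_peaks_oracle(rng):
    rows = []
    for i in range(500):
        start = int(rng.integers(1000, 10**6))
        end = start + int(rng.integers(50, 2000))
        rows.append(("chr1", start, end, f"p{i}"))
    peaks = iv(rows)
    out = resize_peaks(peaks, 300)
    assert (out.lengths() == 300).all()
    # midpoints preserved, matched by peak name (sort order may change)
    before = pd.Series(peaks.midpoints(), index=peaks.names)
    after = pd.Series(out.midpoints(), index=out.names)
    assert after.loc[before.index].equals(before)


def test_filter_half_open_overlap_semantics():
    peaks = iv([("chr1", 100, 400, "a"), ("chr1", 100, 400, "b")])
    touching = iv([("chr1", 399, 600, "bl")])
    abutting = iv([("chr1", 400, 600, "bl")])
    assert len(filter_peaks(peaks, touching, None)) == 0
    assert len(filter_peaks(peaks, abutting, None)) == 2


def test_filter_matches_all_pairs_oracle(rng):
    prows, brows = [], []
    for i in range(200):
        s = int(rng.integers(0, 10**5))
        prows.append(("chr1", s, s + int(rng.integers(10, 400)), f"p{i}"))
    for i in range(30):
        s = int(rng.integers(0, 10**5))
        brows.append(("chr1", s, s + int(rng.integers(10, 2000)), f"b{i}"))
    peaks, bl = iv(prows), iv(brows)
    kept = filter_peaks(peaks, bl, None)
    survivors = set()
    for _, p in peaks.df.iterrows():
        hit = any(p["start"] < b["end"] and b["start"] < p["end"]
                  for _, b in bl.df.iterrows())
        if not hit:
            survivors.add(p["name"])
    assert set(kept.df["name"]) == survivors


def test_filter_genome_restriction():
    peaks = iv([("chr1", 0, 10, "a"), ("chrU", 0, 10, "b")])
    assert set(filter_peaks(peaks, None, ("chr1",)).df["name"]) == {"a"}


PLUS_GENE = [("chr1", 10000, 20000, "+", "GeneA")]


@pytest.mark.parametrize(
    "mid,expected_context,expected_signed",
    [
        (9600, "promoter", -400),
        (10000, "promoter", 0),          # exactly at the TSS
        (15000, "gene_body", 5000),
        (3000, "upstream", -7000),
        (9000, "promoter", -1000),       # -1 kb edge is still promoter
        (8999, "upstream", -1001),
        (200000, "intergenic", 190000),
    ],
)
def test_classify_plus_strand(mid, expected_context, expected_signed):
    peaks = iv([("chr1", mid - 150, mid + 150, "p")])
    out = classify_context(peaks, genes(PLUS_GENE))
    row = out.iloc[0]
    assert row["context"] == expected_context
    assert row["signed_distance_to_tss"] == expected_signed
    assert row["nearest_gene"] == "GeneA"


def test_classify_minus_strand_orientation():
    g = genes([("chr1", 1000, 5000, "-", "GeneB")])  # TSS = 4999
    out = classify_context(iv([("chr1", 5250, 5550, "p")]), g)  # mid 5400
    row = out.iloc[0]
    assert row["context"] == "promoter"
    assert row["signed_distance_to_tss"] == -401
    body = classify_context(iv([("chr1", 1850, 2150, "p")]), g).iloc[0]
    assert body["context"] == "gene_body"
    upstream = classify_context(iv([("chr1", 11850, 12150, "p")]), g).iloc[0]
    assert upstream["context"] == "upstream"
    assert upstream["signed_distance_to_tss"] == -7001


def test_classify_no_gene_chromosome_is_intergenic():
    out = classify_context(iv([("chrEmpty", 100, 400, "p")]),
                           genes(PLUS_GENE))
    assert out.iloc[0]["context"] == "intergenic"
    assert out.iloc[0]["nearest_gene"] is None


def test_classify_equidistant_tie_breaks_by_gene_id():
    g = genes([("chr1", 1000, 3000, "+", "Zeta"),
               ("chr1", 9000, 11000, "+", "Alpha")])
    # midpoint 5000: equidistant (4000) from both TSSs
    out = classify_context(iv([("chr1", 4850, 5150, "p")]), g)
    assert out.iloc[0]["nearest_gene"] == "Alpha"


def test_composition_trivial_cases():
    g = genes(PLUS_GENE)
    promoters = iv([("chr1", 9500, 9800, f"p{i}") for i in range(4)])
    comp = context_composition(classify_context(promoters, g))
    assert comp.tolist() == [100.0, 0.0, 0.0, 0.0]
    single = context_composition(
        classify_context(iv([("chr1", 14850, 15150, "p")]), g))
    assert comp.sum() == 100
    assert single["gene_body"] == 100.0


def test_composition_exact_recovery_from_planted_mix(sim):
    design = SimDesign(seed=3, n_chip_peaks=200, chip_overlap_frac={})
    chip, truth = simulate_chip_peaks(design, sim.genes,
                                      sim.truth["da_peaks"], sim.peaks)
    annotated = classify_context(chip, sim.genes)
    merged = annotated.merge(truth, on="name")
    assert (merged["context_x"] == merged["context_y"]).all()
    comp = context_composition(annotated)
    assert comp.tolist() == [35.0, 34.0, 26.0, 5.0]


def test_classification_mirror_invariance(sim):
    design = SimDesign(seed=9, n_chip_peaks=60, chip_overlap_frac={})
    chip, _ = simulate_chip_peaks(design, sim.genes, None, sim.peaks)
    fwd = classify_context(chip, sim.genes)

    L = {c: l for c, l in sim.design.genome_length_per_chrom.items()}
    mirrored_peaks = chip.df.copy()
    mirrored_peaks["start"], mirrored_peaks["end"] = (
        mirrored_peaks.apply(lambda r: L[r["chrom"]] - r["end"], axis=1),
        mirrored_peaks.apply(lambda r: L[r["chrom"]] - r["start"], axis=1),
    )
    gm = sim.genes.df.copy()
    gm["start"], gm["end"] = (
        gm.apply(lambda r: L[r["chrom"]] - r["end"], axis=1),
        gm.apply(lambda r: L[r["chrom"]] - r["start"], axis=1),
    )
    gm["strand"] = gm["strand"].map({"+": "-", "-": "+"})
    gm = gm.drop(columns="tss")
    rev = classify_context(IntervalSet(mirrored_peaks), GeneModels(gm))
    left = fwd.set_index("name")["context"]
    right = rev.set_index("name")["context"]
    mismatch = (left != right.loc[left.index]).sum()
    # midpoint flooring can shift a boundary case by 1 bp at most
    assert mismatch <= 0.02 * len(left)
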