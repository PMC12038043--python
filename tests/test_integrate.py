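"""Cross-dataset statistics: truncation rule, Venn, overlaps, peak-gene links."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from gonadomics import (
    assign_targets,
    intersect_deg_targets,
    link_peaks,
    linked_fraction,
    overlap_fraction,
    truncate_percent,
)
from gonadomics.containers import FeatureMatrix, GeneModels, IntervalSet


def test_truncate_percent_is_floor_not_round():
    assert truncate_percent(328, 684) == 47.9   # rounds to 48.0 if rounded
    assert truncate_percent(1, 3) == 33.3
    assert truncate_percent(0, 10) == 0.0
    assert truncate_percent(10, 10) == 100.0
    assert math.isnan(truncate_percent(1, 0))


def test_assign_targets_trivial_and_promoter_restricted():
    annotated = pd.DataFrame({
        "name": ["p1", "p2", "p3"],
        "nearest_gene": ["GeneA", "GeneA", "GeneA"],
        "context": ["promoter", "gene_body", "upstream"],
    })
    targets, mapping = assign_targets(annotated)
    assert targets == {"GeneA"}
    assert len(mapping) == 3
    targets_p, mapping_p = assign_targets(annotated, promoter_only=True)
    assert len(mapping_p) == 1
    empty, _ = assign_targets(annotated.iloc[:0])
    assert empty == set()


def test_venn_disjoint_and_coverage():
    out = intersect_deg_targets({"t1", "t2"}, {"a1", "a2", "a3"},
                                {"b1", "b2", "b3", "b4"})
    counts = out.set_index("region")["count"]
    assert counts["T"] == 2 and counts["A"] == 3 and counts["B"] == 4
    assert counts[["TA", "TB", "AB", "TAB"]].sum() == 0
    assert counts["pct_A_with_target"] == 0.0

    sup = intersect_deg_targets({"a1", "a2", "x"}, {"a1", "a2"}, set())
    assert sup.set_index("region")["count"]["pct_A_with_target"] == 100.0


def test_venn_matches_membership_oracle(rng):
    universe = [f"g{i}" for i in range(200)]
    T = set(rng.choice(universe, 60, replace=False))
    A = set(rng.choice(universe, 80, replace=False))
    B = set(rng.choice(universe, 50, replace=False))
    counts = intersect_deg_targets(T, A, B).set_index("region")["count"]
    for key in ("T", "A", "B", "TA", "TB", "AB", "TAB"):
        expect = sum(
            1 for g in universe
            if ("T" in key) == (g in T)
            and ("A" in key) == (g in A)
            and ("B" in key) == (g in B)
            and g in (T | A | B)
        )
        assert counts[key] == expect


def iv(rows):
    return IntervalSet(pd.DataFrame(rows,
                                    columns=["chrom", "start", "end", "name"]))


def test_overlap_fraction_counts_and_truncation():
    da = iv([("chr1", i * 1000, i * 1000 + 500, f"d{i}") for i in range(3)])
    chip = iv([("chr1", 499, 700, "c0"), ("chr1", 5000, 5100, "c1")])
    rep = overlap_fraction(da, chip, "side")
    assert rep["n_da_peaks"] == 3 and rep["n_overlapping"] == 1
    assert rep["percent"] == 33.3
    none = overlap_fraction(da, iv([("chr2", 0, 10, "x")]), "side")
    assert none["percent"] == 0.0
    empty = overlap_fraction(iv([]).subset([]), chip) if False else \
        overlap_fraction(IntervalSet(pd.DataFrame(
            columns=["chrom", "start", "end", "name"])), chip)
    assert math.isnan(empty["percent"])


def test_overlap_predicate_symmetric(rng):
    rows_a, rows_b = [], []
    for i in range(60):
        s = int(rng.integers(0, 50_000))
        rows_a.append(("chr1", s, s + int(rng.integers(50, 600)), f"a{i}"))
        s = int(rng.integers(0, 50_000))
        rows_b.append(("chr1", s, s + int(rng.integers(50, 600)), f"b{i}"))
    A, B = iv(rows_a), iv(rows_b)
    pairs_ab = {
        (ra["name"], rb["name"])
        for _, ra in A.df.iterrows() for _, rb in B.df.iterrows()
        if ra["start"] < rb["end"] and rb["start"] < ra["end"]
    }
    assert A.overlap_mask(B).sum() == len({a for a, _ in pairs_ab})
    assert B.overlap_mask(A).sum() == len({b for _, b in pairs_ab})


def _link_fixture(n_cells, rng, copy_gene=True):
    """One peak adjacent to one gene; optionally expression == accessibility."""
    acc = (rng.random(n_cells) < 0.5).astype(float)
    expr = acc.copy() if copy_gene else rng.poisson(3, n_cells).astype(float)
    atac = FeatureMatrix(sparse.csr_matrix(acc[None, :]), ["p0"],
                         [f"c{j}" for j in range(n_cells)])
    rna = FeatureMatrix(sparse.csr_matrix(expr[None, :]), ["g0"],
                        [f"c{j}" for j in range(n_cells)])
    rna.normalized = True
    peaks = iv([("chr1", 10_000, 10_500, "p0")])
    genes = GeneModels(pd.DataFrame(
        [("chr1", 12_000, 20_000, "+", "g0")],
        columns=["chrom", "start", "end", "strand", "gene_id"]))
    return atac, rna, peaks, genes


def test_link_planted_identical_vectors(rng):
    atac, rna, peaks, genes = _link_fixture(100, rng)
    links = link_peaks(atac, rna, peaks, genes,
                       atac_totals=np.full(100, 1000.0))
    assert len(links) == 1
    assert links.iloc[0]["correlation"] == pytest.approx(1.0)
    assert bool(links.iloc[0]["linked"])


def test_link_negation_flips_correlation(rng):
    atac, rna, peaks, genes = _link_fixture(100, rng)
    links = link_peaks(atac, rna, peaks, genes,
                       atac_totals=np.full(100, 1000.0))
    neg = FeatureMatrix(sparse.csr_matrix(-rna.X.toarray()), ["g0"],
                        rna.cell_ids, normalized=True)
    links_neg = link_peaks(atac, neg, peaks, genes,
                           atac_totals=np.full(100, 1000.0))
    assert links_neg.iloc[0]["correlation"] == pytest.approx(
        -links.iloc[0]["correlation"])


def test_link_independent_pair_mostly_null(rng):
    hits = 0
    for _ in range(40):
        atac, rna, peaks, genes = _link_fixture(400, rng, copy_gene=False)
        links = link_peaks(atac, rna, peaks, genes,
                           atac_totals=np.full(400, 1000.0))
        hits += int(links.iloc[0]["p"] < 0.05)
    assert hits <= 6  # ~5% nominal; generous binomial slack


def test_link_window_restricts_pairs(rng):
    atac, rna, peaks, genes = _link_fixture(50, rng)
    far_genes = GeneModels(
        genes.df.assign(start=10**7, end=10**7 + 1000).drop(columns="tss"))
    links = link_peaks(atac, rna, peaks, far_genes,
                       atac_totals=np.full(50, 1000.0), window=500_000)
    assert len(links) == 0


def test_link_cell_permutation_invariance(rng):
    atac, rna, peaks, genes = _link_fixture(80, rng)
    base = link_peaks(atac, rna, peaks, genes,
                      atac_totals=np.full(80, 1000.0))
    perm = rng.permutation(80)
    atac2 = FeatureMatrix(atac.X[:, perm], atac.feature_ids,
                          atac.cell_ids[perm])
    rna2 = FeatureMatrix(rna.X[:, perm], rna.feature_ids, rna.cell_ids[perm],
                         normalized=True)
    out = link_peaks(atac2, rna2, peaks, genes,
                     atac_totals=np.full(80, 1000.0))
    assert out.iloc[0]["correlation"] == pytest.approx(
        base.iloc[0]["correlation"])


def test_linked_fraction_reporting():
    links = pd.DataFrame({"peak_id": ["p1", "p2"], "gene_id": ["g", "g"],
                          "correlation": [0.5, 0.4], "p": [0.001, 0.002],
                          "adj_p": [0.01, 0.02], "linked": [True, True]})
    rep = linked_fraction(["p1", "p2"], links, "side")
    assert rep["percent"] == 100.0
    rep2 = linked_fraction(["p1", "p2", "p3"], links)
    assert rep2["n_overlapping"] == 2 and rep2["percent"] == 66.6


def test_planted_link_fraction_recovered(bundle):
    """Links planted for ~48.7% of progenitor DA peaks are recovered."""
    sim = bundle.sim
    links = link_peaks(sim.atac, sim.rna, sim.peaks, sim.genes,
                       sim.cells["n_frag_in_peaks"].to_numpy(float))
    da = sim.truth["da_peaks"]
    names = da.loc[da["direction"] == "up_in_c0", "peak_id"]
    rep = linked_fraction(names, links, "c0")
    planted = len(sim.truth["link_plants"].query("direction == 'up_in_c0'"))
    f = planted / len(names)
    sd = np.sqrt(f * (1 - f) / len(names))
    assert abs(rep["percent"] / 100 - f) < 3 * sd + 0.1
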