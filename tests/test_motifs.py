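"""PWM scanning, hypergeometric enrichment, combined TF ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from gonadomics import (
    MotifModel,
    enrich_motifs,
    gc_matched_background,
    rank_candidates,
    rank_on_chip_subset,
    read_jaspar,
    scan_motif,
    scan_motifs,
    write_jaspar,
)
from gonadomics.motifs import gc_fraction, reverse_complement


def strong_motif(consensus="TGACCT", motif_id="M1", tf="TfA"):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pfm = np.ones((4, len(consensus)))
    for j, b in enumerate(consensus):
        pfm[idx[b], j] = 40.0
    return MotifModel(motif_id, tf, pfm)


def test_jaspar_roundtrip(tmp_path):
    motifs = [strong_motif("TGACCT", "MA0001.1", "TfA"),
              strong_motif("AACCGGTT", "MA0002.1", "TfB")]
    write_jaspar(motifs, tmp_path / "m.jaspar")
    back = read_jaspar(tmp_path / "m.jaspar")
    assert [m.motif_id for m in back] == ["MA0001.1", "MA0002.1"]
    assert back[0].consensus == "TGACCT"
    assert np.allclose(back[0].pfm, motifs[0].pfm)


def test_jaspar_plain_dialect(tmp_path):
    (tmp_path / "plain.jaspar").write_text(
        ">MA0099.1 TfC\n"
        "4 17 0 0 1\n"
        "16 0 20 0 0\n"
        "0 0 0 20 0\n"
        "0 3 0 0 19\n"
    )
    m = read_jaspar(tmp_path / "plain.jaspar")[0]
    assert m.length == 5
    assert m.consensus == "CACGT"


def test_scan_finds_planted_consensus(rng):
    motif = strong_motif()
    bg = "".join(rng.choice(list("ACGT"), 60))
    seq = bg[:10] + "TGACCT" + bg[16:]
    out = scan_motif({"s": seq}, motif, 1.0)
    assert bool(out.loc["s", "hit"])
    assert out.loc["s", "best_pos"] == 10
    assert out.loc["s", "strand"] == "+"


def test_scan_reverse_strand_mirrored_offset():
    motif = strong_motif("TGACCA")
    flat = "C" * 40
    planted = reverse_complement("TGACCA")  # TGGTCA
    seq = flat[:12] + planted + flat[18:]
    out = scan_motif({"s": seq}, motif, 1.0)
    assert bool(out.loc["s", "hit"])
    assert out.loc["s", "strand"] == "-"
    assert out.loc["s", "best_pos"] == 12


def test_scan_matches_exhaustive_window_oracle(rng):
    motif = strong_motif("ACGTAC")
    lod = motif.log_odds()
    cutoff = 0.8 * motif.max_score
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 50)) for i in range(200)}
    out = scan_motif(seqs, motif, 0.8)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def brute_hit(seq):
        best = -np.inf
        for s in (seq, reverse_complement(seq)):
            for j in range(len(s) - 5):
                score = sum(lod[idx[s[j + k]], k] for k in range(6))
                best = max(best, score)
        return best >= cutoff

    expect = {name: brute_hit(seq) for name, seq in seqs.items()}
    assert {n: bool(h) for n, h in out["hit"].items()} == expect


def test_scan_short_sequence_no_hit():
    motif = strong_motif("ACGTACGT")
    out = scan_motif({"tiny": "ACG"}, motif, 0.8)
    assert not out.loc["tiny", "hit"]


def hit_table(fg_hits, n_fg, bg_hits, n_bg):
    rows = ([True] * fg_hits + [False] * (n_fg - fg_hits)
            + [True] * bg_hits + [False] * (n_bg - bg_hits))
    idx = [f"f{i}" for i in range(n_fg)] + [f"b{i}" for i in range(n_bg)]
    return (pd.DataFrame({"M": rows}, index=pd.Index(idx, name="peak")),
            [f"f{i}" for i in range(n_fg)], [f"b{i}" for i in range(n_bg)])


def test_enrichment_all_success_closed_form():
    hits, fg, bg = hit_table(10, 10, 0, 100)
    row = enrich_motifs(fg, bg, hits).iloc[0]
    assert row["p"] == pytest.approx(1.0 / math.comb(110, 10), rel=1e-9)
    assert row["fold_enrichment"] == math.inf


def test_enrichment_identical_fractions_is_null():
    hits, fg, bg = hit_table(5, 10, 50, 100)
    row = enrich_motifs(fg, bg, hits).iloc[0]
    assert row["fold_enrichment"] == pytest.approx(1.0)
    assert row["p"] >= 0.5


def test_enrichment_matches_enumeration_oracle():
    hits, fg, bg = hit_table(8, 10, 20, 100)
    row = enrich_motifs(fg, bg, hits).iloc[0]
    M, K, n = 110, 28, 10
    expect = sum(
        math.comb(K, k) * math.comb(M - K, n - k) / math.comb(M, n)
        for k in range(8, min(K, n) + 1)
    )
    assert row["p"] == pytest.approx(expect, rel=1e-12)


def test_enrichment_requires_disjoint_sets():
    hits, fg, bg = hit_table(2, 4, 2, 4)
    with pytest.raises(ValueError):
        enrich_motifs(fg, fg, hits)


def test_gc_matched_background_histogram(rng):
    seqs = {}
    for i in range(50):
        seqs[f"f{i}"] = "G" * 60 + "A" * 40  # GC 0.6
    for i in range(300):
        gc = rng.choice([20, 40, 60, 80])
        seqs[f"c{i}"] = "G" * gc + "A" * (100 - gc)
    gc = gc_fraction(seqs)
    fg = [f"f{i}" for i in range(50)]
    bg = gc_matched_background(fg, [k for k in seqs if k.startswith("c")],
                               gc, rng)
    assert len(bg) == 50
    assert np.allclose(gc.loc[bg], 0.6)


def de_table(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "adj_p", "direction"])
    df["significant"] = df["adj_p"] < 0.05
    return df


def enr_table(rows):
    return pd.DataFrame(
        rows, columns=["motif_id", "tf_gene_id", "adj_p"])


def test_rank_single_and_dominant_candidate():
    de = de_table([("TfA", 0.001, "up_in_a"), ("TfB", 0.002, "up_in_a")])
    enr = enr_table([("M1", "TfA", 0.01)])
    out = rank_candidates(enr, de, "a")
    assert out["tf_gene_id"].tolist() == ["TfA"]
    assert out["combined_rank"].tolist() == [1]

    enr2 = enr_table([("M1", "TfA", 0.001), ("M2", "TfB", 0.01)])
    de2 = de_table([("TfA", 0.0001, "up_in_a"), ("TfB", 0.01, "up_in_a")])
    out2 = rank_candidates(enr2, de2, "a")
    assert out2.iloc[0]["tf_gene_id"] == "TfA"  # best on both criteria


def test_rank_requires_both_significance_gates():
    enr = enr_table([("M1", "TfA", 0.2), ("M2", "TfB", 0.01)])
    de = de_table([("TfA", 0.001, "up_in_a"), ("TfB", 0.001, "up_in_b")])
    assert len(rank_candidates(enr, de, "a")) == 0   # TfA fails motif gate,
    assert len(rank_candidates(enr, de, "b")) == 1   # TfB is up on side b


def test_rank_matches_rank_sum_oracle(rng):
    tfs = [f"Tf{i}" for i in range(10)]
    motif_p = rng.uniform(1e-6, 0.04, 10)
    de_p = rng.uniform(1e-6, 0.04, 10)
    enr = enr_table([(f"M{i}", tf, motif_p[i]) for i, tf in enumerate(tfs)])
    de = de_table([(tf, de_p[i], "up_in_a") for i, tf in enumerate(tfs)])
    out = rank_candidates(enr, de, "a")

    r1 = pd.Series(motif_p, index=tfs).rank(method="min")
    r2 = pd.Series(de_p, index=tfs).rank(method="min")
    order = sorted(tfs, key=lambda t: (r1[t] + r2[t], motif_p[tfs.index(t)], t))
    assert out["tf_gene_id"].tolist() == order


def test_rank_invariant_to_monotone_p_transform(rng):
    tfs = [f"Tf{i}" for i in range(8)]
    motif_p = rng.uniform(1e-6, 0.04, 8)
    de_p = rng.uniform(1e-6, 0.04, 8)
    enr = enr_table([(f"M{i}", tf, motif_p[i]) for i, tf in enumerate(tfs)])
    de = de_table([(tf, de_p[i], "up_in_a") for i, tf in enumerate(tfs)])
    base = rank_candidates(enr, de, "a")["tf_gene_id"].tolist()
    # squash all p-values monotonically (keeps < 0.05 gates intact)
    enr2 = enr.assign(adj_p=enr["adj_p"] / 10)
    de2 = de_table([(tf, de_p[i] / 10, "up_in_a")
                    for i, tf in enumerate(tfs)])
    assert rank_candidates(enr2, de2, "a")["tf_gene_id"].tolist() == base


def test_chip_restricted_motif_improves_rank(sim, rng):
    """A motif planted only in ChIP-covered DA peaks gains rank when the
    foreground is restricted to those peaks."""
    from gonadomics.simulate import simulate_peak_sequences
    da = sim.truth["da_peaks"]
    fg_names = da.loc[da["direction"] == "up_in_c0", "peak_id"].tolist()
    covered, uncovered = fg_names[:15], fg_names[15:]
    chip = sim.peaks.subset(covered)

    m_cov = strong_motif("ACGTACGTAC", "Mcov", "TfCov")
    m_all = strong_motif("TTGGCCAATT", "Mall", "TfAll")
    plants = pd.DataFrame(
        [(p, "Mcov", -1, "+") for p in covered]
        + [(p, "Mall", -1, "+") for p in fg_names],
        columns=["peak", "motif_id", "offset", "strand"])
    seqs, _ = simulate_peak_sequences(sim.peaks, [m_cov, m_all], plants,
                                      rng=rng)
    de = de_table([("TfCov", 0.001, "up_in_a"), ("TfAll", 0.001, "up_in_a")])

    da_set = sim.peaks.subset(fg_names)
    restricted = rank_on_chip_subset(da_set, chip, seqs, [m_cov, m_all], de,
                                     side="a")
    assert "TfCov" in restricted["tf_gene_id"].tolist()
    assert restricted.iloc[0]["tf_gene_id"] == "TfCov"


def test_chip_restricted_empty_overlap_is_empty(sim):
    da = sim.truth["da_peaks"]
    fg_names = da.loc[da["direction"] == "up_in_c0", "peak_id"].tolist()
    da_set = sim.peaks.subset(fg_names)
    far_chip = sim.peaks.subset(
        da.loc[da["direction"] == "up_in_c3", "peak_id"])
    out = rank_on_chip_subset(da_set, far_chip, {}, [], de_table([]), "a")
    assert len(out) == 0
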