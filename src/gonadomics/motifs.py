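"""PWM scanning, motif enrichment in DA peaks, and TF candidate ranking.

A motif hit is any window, on either strand, whose log-odds score (position
probabilities vs a uniform background) reaches ``threshold_frac`` of the
motif's maximum attainable score (default 0.8). Enrichment of hits in a
foreground peak set against a GC-matched background is tested one-sided by
the hypergeometric distribution and BH-corrected over motifs. Candidate
transcription factors must be both differentially expressed (up on the
queried side) and motif-enriched; they are ordered by the rank-sum of the
two adjusted p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds
from .differential import bh_adjust

logger = logging.getLogger("gonadomics")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class MotifModel:
    """A position frequency matrix and its derived log-odds form."""

    motif_id: str
    tf_gene_id: str
    pfm: np.ndarray  # 4 x L, rows A,C,G,T (counts or probabilities)

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4 or self.pfm.shape[1] < 4:
            raise ValueError("PFM must be 4 x L with L >= 4")

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    def probabilities(self, pseudocount: float = 0.5) -> np.ndarray:
        p = self.pfm + pseudocount
        return p / p.sum(axis=0, keepdims=True)

    def log_odds(self) -> np.ndarray:
        """log2(p / 0.25) per base and position."""
        return np.log2(self.probabilities() / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pfm.argmax(axis=0))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_jaspar(path) -> list[MotifModel]:
    """Read a JASPAR PFM text file (bracketed or plain count rows)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        pfm = np.array([m.counts[b] for b in BASES], dtype=float)
        out.append(MotifModel(m.matrix_id or m.name, m.name or m.matrix_id, pfm))
    return out


def write_jaspar(motif_list: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        for m in motif_list:
            fh.write(f">{m.motif_id}\t{m.tf_gene_id}\n")
            for base, row in zip(BASES, m.pfm):
                vals = " ".join(f"{int(v)}" if float(v).is_integer()
                                else f"{v:.2f}" for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 0) for b in seq.upper()], dtype=np.intp)


def _window_scores(seq: str, lod: np.ndarray) -> np.ndarray:
    L = lod.shape[1]
    if len(seq) < L:
        return np.empty(0)
    idx = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return lod[windows, np.arange(L)].sum(axis=1)


def scan_motif(
    sequences: dict[str, str],
    motif: MotifModel,
    threshold_frac: float = 0.8,
) -> pd.DataFrame:
    """Scan every sequence for the motif on both strands.

    Returns one row per sequence: hit flag, best score, best position
    (forward-strand offset of the window start) and strand. Sequences
    shorter than the motif get no hit (logged).
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must lie in (0, 1]")
    lod = motif.log_odds()
    L = motif.length
    cutoff = threshold_frac * motif.max_score
    rows = []
    n_short = 0
    for name, seq in sequences.items():
        if len(seq) < L:
            n_short += 1
            rows.append((name, False, math.nan, -1, "."))
            continue
        fwd = _window_scores(seq, lod)
        rev = _window_scores(reverse_complement(seq), lod)
        # map reverse-strand window j to forward coordinates
        best_fwd = int(np.argmax(fwd))
        best_rev = int(np.argmax(rev))
        if rev[best_rev] > fwd[best_fwd]:
            best_score = float(rev[best_rev])
            best_pos = len(seq) - L - best_rev
            strand = "-"
        else:
            best_score = float(fwd[best_fwd])
            best_pos = best_fwd
            strand = "+"
        rows.append((name, bool(best_score >= cutoff), best_score,
                     best_pos, strand))
    if n_short:
        logger.info("%d sequences shorter than motif %s; no hit possible",
                    n_short, motif.motif_id)
    return pd.DataFrame(
        rows, columns=["peak", "hit", "best_score", "best_pos", "strand"]
    ).set_index("peak")


def scan_motifs(
    sequences: dict[str, str],
    motif_list: list[MotifModel],
    threshold_frac: float = 0.8,
) -> pd.DataFrame:
    """Hit table, peaks x motifs (boolean)."""
    cols = {
        m.motif_id: scan_motif(sequences, m, threshold_frac)["hit"]
        for m in motif_list
    }
    return pd.DataFrame(cols, index=pd.Index(sequences.keys(), name="peak"))


def gc_fraction(sequences: dict[str, str]) -> pd.Series:
    return pd.Series(
        {n: (s.upper().count("G") + s.upper().count("C")) / max(len(s), 1)
         for n, s in sequences.items()},
        name="gc",
    )


def gc_matched_background(
    fg_peaks,
    candidates,
    gc: pd.Series,
    rng: np.random.Generator,
    bin_width: float = 0.05,
) -> list:
    """Sample a background matching the foreground's GC-bin histogram.

    Falls back to all non-foreground candidates when a needed bin has no
    candidates (logged).
    """
    fg_peaks = list(fg_peaks)
    candidates = [c for c in candidates if c not in set(fg_peaks)]
    bins = np.arange(0, 1 + bin_width, bin_width)
    fg_bins = np.digitize(gc.loc[fg_peaks].to_numpy(), bins)
    cand_bins = pd.Series(np.digitize(gc.loc[candidates].to_numpy(), bins),
                          index=pd.Index(candidates))
    need = pd.Series(fg_bins).value_counts()
    chosen: list = []
    for b, k in need.items():
        pool = cand_bins.index[cand_bins == b].tolist()
        if not pool:
            logger.info("GC bin %d empty in background pool; "
                        "falling back to all non-foreground peaks", int(b))
            return sorted(candidates)
        if len(pool) <= k:
            chosen.extend(pool)
        else:
            chosen.extend(rng.choice(pool, size=int(k), replace=False))
    return sorted(chosen)


def enrich_motifs(
    fg_peaks,
    bg_peaks,
    hits: pd.DataFrame,
    motif_tf_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric motif enrichment of foreground vs background.

    ``hits`` is the peaks x motifs boolean table from :func:`scan_motifs`.
    For each motif, p is the upper tail of drawing ``n_fg_with`` successes
    in ``n_fg`` draws from the pooled fg+bg urn; fold is the ratio of
    with-motif fractions (infinity when the background has none).
    """
    fg_peaks, bg_peaks = list(fg_peaks), list(bg_peaks)
    if set(fg_peaks) & set(bg_peaks):
        raise ValueError("foreground and background must be disjoint")
    tf_for = _tf_lookup(hits.columns, motif_tf_map)
    rows = []
    n_fg, n_bg = len(fg_peaks), len(bg_peaks)
    for motif_id in hits.columns:
        col = hits[motif_id]
        k = int(col.loc[fg_peaks].sum())
        kb = int(col.loc[bg_peaks].sum())
        M, K = n_fg + n_bg, k + kb
        p = float(stats.hypergeom.sf(k - 1, M, K, n_fg))
        if n_bg == 0 or kb == 0:
            fold = math.inf if k > 0 else math.nan
        else:
            fold = (k / n_fg) / (kb / n_bg) if n_fg else math.nan
        for tf in tf_for[motif_id]:
            rows.append((motif_id, tf, k, n_fg, kb, n_bg, fold, p))
    out = pd.DataFrame(
        rows,
        columns=["motif_id", "tf_gene_id", "n_fg_with", "n_fg",
                 "n_bg_with", "n_bg", "fold_enrichment", "p"],
    )
    # BH over distinct motifs, then broadcast to expanded TF rows
    per_motif = out.drop_duplicates("motif_id").set_index("motif_id")["p"]
    adj = pd.Series(bh_adjust(per_motif.to_numpy()), index=per_motif.index)
    out["adj_p"] = out["motif_id"].map(adj)
    return out


def default_motif_tf_map(motif_list: list[MotifModel]) -> pd.DataFrame:
    """The motif-to-TF mapping carried by the motif models themselves."""
    return pd.DataFrame(
        [(m.motif_id, m.tf_gene_id) for m in motif_list],
        columns=["motif_id", "tf_gene_id"],
    )


def _tf_lookup(motif_ids, motif_tf_map: pd.DataFrame | None) -> dict:
    """motif id -> list of TF gene ids (possibly several per motif)."""
    if motif_tf_map is None:
        return {m: [m] for m in motif_ids}
    grouped = motif_tf_map.groupby("motif_id")["tf_gene_id"].apply(list)
    out = {}
    for m in motif_ids:
        if m in grouped.index:
            out[m] = grouped[m]
        else:
            logger.info("motif %s has no TF mapping; excluded from ranking", m)
            out[m] = []
    return out


def rank_candidates(
    enrichment: pd.DataFrame,
    de: pd.DataFrame,
    side: str = "a",
    t: Thresholds | None = None,
) -> pd.DataFrame:
    """Rank TFs by combined differential expression and motif enrichment.

    Eligible TFs have motif adj_p < 0.05 AND are significantly
    upregulated on the queried side (``side`` in {"a", "b"}). The combined
    rank orders the sum of the two ascending adj_p ranks; ties break by
    motif adj_p, then gene id.
    """
    t = t or Thresholds()
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    de_sig = de[(de["adj_p"] < t.adj_p_max)
                & (de["direction"] == f"up_in_{side}")]
    de_p = de_sig.set_index("feature_id")["adj_p"]

    rows = enrichment[enrichment["adj_p"] < t.adj_p_max]
    rows = rows[rows["tf_gene_id"].isin(de_p.index)]
    if len(rows) == 0:
        return pd.DataFrame(
            columns=["tf_gene_id", "de_adj_p", "motif_adj_p", "combined_rank"]
        )
    # one row per TF: its best (smallest) motif adj_p
    best = (rows.sort_values(["adj_p", "motif_id"])
                .drop_duplicates("tf_gene_id")
                .set_index("tf_gene_id")["adj_p"])
    table = pd.DataFrame({
        "tf_gene_id": best.index,
        "de_adj_p": de_p.loc[best.index].to_numpy(),
        "motif_adj_p": best.to_numpy(),
    })
    r_motif = table["motif_adj_p"].rank(method="min")
    r_de = table["de_adj_p"].rank(method="min")
    table["rank_sum"] = r_motif + r_de
    table = table.sort_values(["rank_sum", "motif_adj_p", "tf_gene_id"],
                              kind="mergesort").reset_index(drop=True)
    table["combined_rank"] = np.arange(1, len(table) + 1)
    return table.drop(columns="rank_sum")


def rank_da_side(
    fg_names,
    sequences: dict[str, str],
    motif_list: list[MotifModel],
    de: pd.DataFrame,
    side: str = "a",
    motif_tf_map: pd.DataFrame | None = None,
    threshold_frac: float = 0.8,
    t: Thresholds | None = None,
    gc_match: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Unrestricted TF ranking: DA peaks of one side vs all other peaks.

    ``sequences`` spans the peak universe; the background is every scanned
    peak outside the foreground, optionally GC-matched (seeded ``rng``).
    """
    if motif_tf_map is None:
        motif_tf_map = default_motif_tf_map(motif_list)
    fg = list(fg_names)
    hits = scan_motifs(sequences, motif_list, threshold_frac)
    bg = [n for n in sequences if n not in set(fg)]
    if gc_match and bg:
        gc = gc_fraction(sequences)
        rng = rng or np.random.default_rng(0)
        bg = gc_matched_background(fg, bg, gc, rng)
    enr = enrich_motifs(fg, bg, hits, motif_tf_map)
    return rank_candidates(enr, de, side=side, t=t)


def rank_on_chip_subset(
    da_peaks,
    chip,
    sequences: dict[str, str],
    motif_list: list[MotifModel],
    de: pd.DataFrame,
    side: str = "a",
    motif_tf_map: pd.DataFrame | None = None,
    threshold_frac: float = 0.8,
    t: Thresholds | None = None,
) -> pd.DataFrame:
    """TF ranking with foreground restricted to DA peaks carrying a ChIP peak.

    ``da_peaks`` is the IntervalSet of the side's DA peaks; the background
    is the remaining DA peaks on the same side. When every DA peak carries
    a ChIP peak, the background falls back to all other scanned peaks, so
    the run coincides with the unrestricted one. Empty restricted
    foregrounds yield an empty ranking.
    """
    if motif_tf_map is None:
        motif_tf_map = default_motif_tf_map(motif_list)
    overlap = da_peaks.overlap_mask(chip)
    names = list(da_peaks.names)
    fg = [n for n, o in zip(names, overlap) if o]
    if not fg:
        logger.info("no DA peaks overlap ChIP peaks; empty ranking")
        return pd.DataFrame(
            columns=["tf_gene_id", "de_adj_p", "motif_adj_p", "combined_rank"]
        )
    bg = [n for n in names if n not in set(fg)]
    if not bg:
        bg = [n for n in sequences if n not in set(fg)]
    hits = scan_motifs(sequences, motif_list, threshold_frac)
    enr = enrich_motifs(fg, bg, hits, motif_tf_map)
    return rank_candidates(enr, de, side=side, t=t)
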