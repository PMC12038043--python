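"""Readers and writers for the standard on-disk formats.

MatrixMarket triplets (features x cells, with sidecar feature/barcode TSVs),
BED3+ interval files, the 6-column gene-model TSV, per-cell QC tables, and
generic tab-separated stage outputs. All coordinates on disk are BED-style
0-based half-open, matching the in-memory convention.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import FeatureMatrix, GeneModels, IntervalSet, validate_cell_table

logger = logging.getLogger("gonadomics")


# -- matrices ---------------------------------------------------------------

def read_matrix(directory: str | Path) -> FeatureMatrix:
    """Read an MTX triplet directory: matrix.mtx + features.tsv + barcodes.tsv.

    The matrix is features-by-cells; the returned object is flagged raw.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    feat_path = directory / "features.tsv"
    bc_path = directory / "barcodes.tsv"
    for p in (mtx_path, feat_path, bc_path):
        if not p.exists():
            raise FileNotFoundError(f"missing matrix component: {p}")
    X = sparse.csr_matrix(spio.mmread(mtx_path))
    features = pd.read_csv(feat_path, sep="\t", header=None)[0]
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0]
    if X.shape[0] != len(features):
        raise ValueError(
            f"{feat_path} lists {len(features)} features but "
            f"{mtx_path} declares {X.shape[0]} rows"
        )
    if X.shape[1] != len(barcodes):
        raise ValueError(
            f"{bc_path} lists {len(barcodes)} barcodes but "
            f"{mtx_path} declares {X.shape[1]} columns"
        )
    return FeatureMatrix(X, pd.Index(features), pd.Index(barcodes),
                         normalized=False)


def write_matrix(matrix: FeatureMatrix, directory: str | Path) -> None:
    """Write the MTX triplet dialect :func:`read_matrix` consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sparse.coo_matrix(matrix.X)
    # canonical entry order keeps round-trips bit-identical
    order = np.lexsort((coo.row, coo.col))
    canonical = sparse.coo_matrix(
        (coo.data[order], (coo.row[order], coo.col[order])), shape=coo.shape
    )
    spio.mmwrite(directory / "matrix.mtx", canonical)
    pd.Series(matrix.feature_ids).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(matrix.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


# -- intervals --------------------------------------------------------------

def read_intervals(path: str | Path, genome=None) -> IntervalSet:
    """Read a BED3+ file; optionally drop non-``genome`` chromosomes.

    Lines with start >= end raise; intervals on chromosomes outside
    ``genome`` are dropped with a logged count. Missing names become
    ``peak_<i>`` in input order.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = parts[3] if len(parts) > 3 else f"peak_{len(rows)}"
            rows.append((chrom, start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    intervals = IntervalSet(df)
    if genome is not None:
        intervals = intervals.restrict_chroms(genome)
    return intervals


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    intervals.df.to_csv(path, sep="\t", header=False, index=False)


# -- gene models ------------------------------------------------------------

def read_gene_models(path: str | Path) -> GeneModels:
    """Read the gene-model TSV (chrom start end strand gene_id [tss]).

    TSS defaults to ``start`` for + genes and ``end - 1`` for - genes.
    """
    df = pd.read_csv(path, sep="\t")
    return GeneModels(df)


def write_gene_models(genes: GeneModels, path: str | Path) -> None:
    genes.df.to_csv(path, sep="\t", index=False)


# -- tables -----------------------------------------------------------------

def read_cell_table(path: str | Path) -> pd.DataFrame:
    cells = pd.read_csv(path, sep="\t")
    return validate_cell_table(cells)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a stage output as TSV with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- sequences --------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
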