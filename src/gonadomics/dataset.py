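"""Build, write and re-read a complete synthetic study directory.

One bundle holds everything a pipeline run consumes: the multiome matrices
and per-cell table, peak/gene/blacklist geography, ChIP peaks, peak
sequences with a small synthetic motif collection, the motif-to-TF map and
the bulk differential table — plus the truth tables (written under
``truth/`` for scoring, never read by any stage).

The default bundle mirrors the study's structure: a progenitor cluster
(c0) and a fetal-Leydig-like derivative (c3) with close chromatin
profiles; ChIP peaks at the 35/34/26/5 promoter/gene-body/upstream/
intergenic mix; 43.7% of the progenitor-side differential peaks and 3.8%
of the derivative-side ones covered by a ChIP peak; progenitor-side
motifs planted in progenitor-side differential peaks; and a bulk
knockout table whose downregulated genes are progenitor/contractile
markers and upregulated genes are germ-cell-like markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import RunConfig, Thresholds, save_config
from .containers import GeneModels, IntervalSet
from .motifs import BASES, MotifModel
from .simulate import (
    SimDesign,
    SimulatedMultiome,
    plan_motif_plants,
    simulate_bulk_de,
    simulate_chip_peaks,
    simulate_multiome,
    simulate_peak_sequences,
)

logger = logging.getLogger("gonadomics")


@dataclass
class StudyBundle:
    sim: SimulatedMultiome
    chip: IntervalSet
    blacklist: IntervalSet
    sequences: dict[str, str]
    motif_list: list[MotifModel]
    motif_tf_map: pd.DataFrame
    bulk_de: pd.DataFrame
    config: RunConfig


def synthetic_motifs(rng: np.random.Generator, tf_genes, length: int = 8
                     ) -> tuple[list[MotifModel], pd.DataFrame]:
    """Near-deterministic synthetic PWMs, one per TF gene."""
    motif_list = []
    rows = []
    for i, tf in enumerate(tf_genes):
        consensus = rng.integers(0, 4, size=length)
        pfm = np.full((4, length), 1.0)
        pfm[consensus, np.arange(length)] = 20.0
        motif_id = f"MS{i + 1:04d}.1"
        motif_list.append(MotifModel(motif_id, tf, pfm))
        rows.append((motif_id, tf))
    return motif_list, pd.DataFrame(rows, columns=["motif_id", "tf_gene_id"])


def default_design(seed: int) -> SimDesign:
    """The default study conditions for a full synthetic run.

    ChIP coverage and peak-gene link fractions follow the observed
    study-level proportions; roughly 5% of cells carry a planted QC
    failure spread over the gate criteria.
    """
    return SimDesign(
        seed=seed,
        chip_overlap_frac={"up_in_c0": 0.437, "up_in_c3": 0.038},
        link_frac={"up_in_c0": 0.487, "up_in_c3": 0.479},
        qc_fail_rates={
            "mito": 0.01, "ribo": 0.005, "hemo": 0.005, "n_genes": 0.01,
            "frip": 0.01, "frag_low": 0.005, "frag_high": 0.005,
            "blacklist": 0.005,
        },
    )


def build_bundle(seed: int, design: SimDesign | None = None) -> StudyBundle:
    """Draw the full synthetic study for one seed."""
    design = design or default_design(seed)
    sim = simulate_multiome(design)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(9)[-1])

    chip, chip_truth = simulate_chip_peaks(
        design, sim.genes, sim.truth["da_peaks"], sim.peaks
    )
    sim.truth["chip_peaks"] = chip_truth

    # a few blacklist regions; the last two deliberately cover a ChIP peak
    bl_rows = []
    chroms = list(design.genome_length_per_chrom)
    for i in range(2):
        pos = int(rng.integers(1000, design.genome_length_per_chrom[chroms[i % len(chroms)]] - 5000))
        bl_rows.append((chroms[i % len(chroms)], pos, pos + 2000, f"blacklist_{i}"))
    for j, (_, row) in enumerate(chip.df.tail(2).iterrows()):
        bl_rows.append((row["chrom"], int(row["start"]) - 50,
                        int(row["end"]) + 50, f"blacklist_{2 + j}"))
    blacklist = IntervalSet(
        pd.DataFrame(bl_rows, columns=["chrom", "start", "end", "name"])
    )

    markers = sim.truth["cluster_markers"]
    c0_markers = markers.loc[markers["cluster"] == "c0", "gene_id"].tolist()
    c3_markers = markers.loc[markers["cluster"] == "c3", "gene_id"].tolist()
    tf_genes = c0_markers[:2] + c3_markers[:2]
    motif_list, motif_tf_map = synthetic_motifs(rng, tf_genes)

    da = sim.truth["da_peaks"]
    plants = pd.concat(
        [
            plan_motif_plants(
                da.loc[da["direction"] == "up_in_c0", "peak_id"],
                motif_list[:2], design.motif_plant_rate, rng,
            ),
            plan_motif_plants(
                da.loc[da["direction"] == "up_in_c3", "peak_id"],
                motif_list[2:], design.motif_plant_rate, rng,
            ),
        ],
        ignore_index=True,
    )
    sequences, plant_truth = simulate_peak_sequences(
        sim.peaks, motif_list, plants, gc_content=design.gc_content, rng=rng
    )
    sim.truth["motif_plants"] = plant_truth

    down = markers.loc[markers["cluster"].isin(["c0", "c1"]), "gene_id"]
    up = markers.loc[markers["cluster"].isin(["c4", "c5"]), "gene_id"]
    bulk_de = simulate_bulk_de(list(sim.rna.feature_ids), up, down, rng)
    sim.truth["bulk_de_genes"] = pd.DataFrame(
        {"gene_id": pd.concat([up, down]),
         "direction": ["up"] * len(up) + ["down"] * len(down)}
    )

    config = RunConfig(
        thresholds=Thresholds(),
        seed=seed,
        genome=tuple(design.genome_length_per_chrom),
    )
    return StudyBundle(sim=sim, chip=chip, blacklist=blacklist,
                       sequences=sequences, motif_list=motif_list,
                       motif_tf_map=motif_tf_map, bulk_de=bulk_de,
                       config=config)


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_matrix(bundle.sim.rna, outdir / "rna")
    io.write_matrix(bundle.sim.atac, outdir / "atac")
    io.write_table(bundle.sim.cells, outdir / "cells.tsv")
    io.write_intervals(bundle.sim.peaks, outdir / "atac_peaks.bed")
    io.write_gene_models(bundle.sim.genes, outdir / "genes.tsv")
    io.write_intervals(bundle.blacklist, outdir / "blacklist.bed")
    io.write_intervals(bundle.chip, outdir / "chip_peaks.bed")
    io.write_fasta(bundle.sequences, outdir / "peak_sequences.fasta")
    from .motifs import write_jaspar

    write_jaspar(bundle.motif_list, outdir / "motifs.jaspar")
    io.write_table(bundle.motif_tf_map, outdir / "motif_tf_map.tsv")
    io.write_table(bundle.bulk_de, outdir / "bulk_de.tsv")
    save_config(bundle.config, outdir / "config.yaml")
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, table in bundle.sim.truth.items():
        io.write_table(table, truth_dir / f"{name}.tsv")


def read_bundle(outdir: str | Path) -> StudyBundle:
    """Re-read a written study directory (truth tables included)."""
    from .config import load_config
    from .motifs import read_jaspar

    outdir = Path(outdir)
    config = load_config(outdir / "config.yaml")
    rna = io.read_matrix(outdir / "rna")
    atac = io.read_matrix(outdir / "atac")
    cells = io.read_cell_table(outdir / "cells.tsv")
    peaks = io.read_intervals(outdir / "atac_peaks.bed")
    genes = io.read_gene_models(outdir / "genes.tsv")
    blacklist = io.read_intervals(outdir / "blacklist.bed")
    chip = io.read_intervals(outdir / "chip_peaks.bed")
    sequences = io.read_fasta(outdir / "peak_sequences.fasta")
    motif_list = read_jaspar(outdir / "motifs.jaspar")
    motif_tf_map = io.read_table(outdir / "motif_tf_map.tsv")
    bulk_de = io.read_table(outdir / "bulk_de.tsv")
    truth = {}
    truth_dir = outdir / "truth"
    if truth_dir.exists():
        for path in sorted(truth_dir.glob("*.tsv")):
            truth[path.stem] = io.read_table(path)
    design = default_design(config.seed)
    sim = SimulatedMultiome(rna=rna, atac=atac, cells=cells, peaks=peaks,
                            genes=genes, truth=truth, design=design)
    return StudyBundle(sim=sim, chip=chip, blacklist=blacklist,
                       sequences=sequences, motif_list=motif_list,
                       motif_tf_map=motif_tf_map, bulk_de=bulk_de,
                       config=config)
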