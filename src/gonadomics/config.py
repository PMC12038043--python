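"""Run configuration: every analysis threshold in one validated structure.

The defaults encode the study's stated gates: per-cell RNA quality
(<10% mitochondrial, <10% ribosomal, <0.5% hemoglobin counts, >500 genes),
per-cell ATAC quality (>20% fraction of reads in peaks, 250-25,000 fragments
in peaks, <5% blacklist fraction), the 2,000 most variable peaks used for
cluster chromatin similarity, 300 bp ChIP peak resizing, the -1 kb promoter
and -10 kb upstream windows, the 0.05 adjusted-p significance gate, and the
"affected population" projection rule (>20% of DEGs at z > 1).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("gonadomics")

#: Canonical mouse chromosome names (autosomes 1-19 plus X and Y).
CANONICAL_MOUSE_CHROMS: tuple[str, ...] = tuple(
    f"chr{i}" for i in range(1, 20)
) + ("chrX", "chrY")


@dataclass
class Thresholds:
    """All tunable analysis constants, with the study defaults.

    Fractions are proportions in [0, 1]; windows and widths are base pairs.
    """

    rna_mito_max: float = 0.10
    rna_ribo_max: float = 0.10
    rna_hemo_max: float = 0.005
    rna_min_genes: int = 500
    atac_frip_min: float = 0.20
    atac_frag_min: int = 250
    atac_frag_max: int = 25000
    atac_blacklist_max: float = 0.05
    n_variable_peaks: int = 2000
    chip_peak_width: int = 300
    promoter_upstream: int = 1000
    upstream_window: int = 10000
    adj_p_max: float = 0.05
    chip_fdr_max: float = 1e-5
    projection_z_cut: float = 1.0
    projection_deg_frac: float = 0.20
    projection_min_group_frac: float = 0.02
    min_cluster_cells: int = 3

    def __post_init__(self) -> None:
        fracs = {
            "rna_mito_max": self.rna_mito_max,
            "rna_ribo_max": self.rna_ribo_max,
            "rna_hemo_max": self.rna_hemo_max,
            "atac_frip_min": self.atac_frip_min,
            "atac_blacklist_max": self.atac_blacklist_max,
            "projection_deg_frac": self.projection_deg_frac,
            "projection_min_group_frac": self.projection_min_group_frac,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        counts = {
            "rna_min_genes": self.rna_min_genes,
            "atac_frag_min": self.atac_frag_min,
            "atac_frag_max": self.atac_frag_max,
            "n_variable_peaks": self.n_variable_peaks,
            "chip_peak_width": self.chip_peak_width,
            "promoter_upstream": self.promoter_upstream,
            "upstream_window": self.upstream_window,
            "min_cluster_cells": self.min_cluster_cells,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not self.atac_frag_min < self.atac_frag_max:
            raise ValueError("atac_frag_min must be < atac_frag_max")
        if not self.promoter_upstream < self.upstream_window:
            raise ValueError("promoter_upstream must be < upstream_window")
        for name in ("adj_p_max", "chip_fdr_max"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be a probability in (0, 1]")


@dataclass
class RunConfig:
    """A full pipeline configuration: thresholds, seed, paths, genome."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    genome: tuple[str, ...] = CANONICAL_MOUSE_CHROMS

    def digest(self) -> str:
        """Stable hex digest of the configuration, for run logs."""
        import hashlib

        payload = repr(
            (dataclasses.astuple(self.thresholds), self.seed,
             sorted(self.paths.items()), tuple(self.genome))
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a flat ``key: value`` configuration file (YAML subset).

    Unknown keys raise; every :class:`Thresholds` field is overridable.
    ``genome`` may be given as a comma-separated string or a list.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} is not a key: value mapping")
    threshold_fields = {f.name: f.type for f in dataclasses.fields(Thresholds)}
    t_kwargs: dict[str, object] = {}
    seed = 0
    paths: dict[str, str] = {}
    genome: tuple[str, ...] = CANONICAL_MOUSE_CHROMS
    for key, value in raw.items():
        if key in threshold_fields:
            t_kwargs[key] = value
        elif key == "seed":
            seed = int(value)
        elif key == "paths":
            paths = dict(value)
        elif key == "genome":
            if isinstance(value, str):
                genome = tuple(s.strip() for s in value.split(","))
            else:
                genome = tuple(value)
        else:
            raise ValueError(f"unknown configuration key: {key!r}")
    return RunConfig(thresholds=Thresholds(**t_kwargs), seed=seed,
                     paths=paths, genome=genome)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration in the flat dialect :func:`load_config` reads."""
    data: dict[str, object] = dataclasses.asdict(config.thresholds)
    data["seed"] = config.seed
    if config.paths:
        data["paths"] = dict(config.paths)
    data["genome"] = ",".join(config.genome)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
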