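"""Pipeline configuration: every threshold the analysis uses, in one place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class Thresholds:
    """Analysis thresholds.

    Defaults follow the published procedure: eRNAs within 1 kb of both an
    ATAC and an H3K4me1 peak at any time point; eRNAs within 1 kb of each
    other merged into one enhancer; differential units at |log2FC| > 1 and
    FDR < 0.05; correlation-based pairing within 1 Mb (or a shared TAD) at
    Spearman rho > 0.4; genes with 2-20 paired enhancers and the top 75% of
    Spearman correlations fitted; synergistic when the relative BIC
    (BIC_additive - BIC_exponential) exceeds 2; superenhancer stitching of
    peaks within 1 kb of enhancers at a 12.5 kb gap.
    """

    merge_dist: int = 1000            # bp, eRNA -> enhancer merging
    erna_proximity: int = 1000        # bp, eRNA to ATAC/H3K4me1 peak
    window_bp: int = 1_000_000        # bp, window pairing scope
    stitch_dist: int = 12_500         # bp, superenhancer stitching gap
    stitch_proximity: int = 1000      # bp, peak-to-enhancer proximity for stitching
    lfc: float = 1.0                  # |log2FC| threshold (strict)
    fdr: float = 0.05                 # FDR threshold (strict)
    rho_min: float = 0.4              # Spearman threshold for correlated pairing
    relbic: float = 2.0               # relative-BIC threshold for synergy
    enhancer_min: int = 2             # genes fitted if paired with 2-20 enhancers
    enhancer_max: int = 20
    correlation_keep_frac: float = 0.75  # top fraction of per-gene Spearman rho kept
    pseudocount: float = 1.0          # for log2 fold changes
    activity_floor: float = 1.0       # per-kb synthesis defining "transcribed"
    max_logistic_rounds: int = 1      # exclusion-refit rounds when logistic wins
    gencode_overlap_frac: float = 0.60
    discard_overlap_frac: float = 0.20
    overlap_relative_to: str = "reference"  # or "tu"
    ua_upstream_bp: int = 1000        # TSS window for uaRNA/convRNA
    ua_downstream_bp: int = 500
    dsrna_near_bp: int = 1000         # unconditional downstream-RNA window
    dsrna_far_bp: int = 10_000        # decaying-signal downstream-RNA window
    dsrna_decay_rho: float = -0.5     # max Spearman(bin, signal) to call decay
    log_offset: float = 1.0           # s0 in the logarithmic control model
    enhancer_anchor: str = "midpoint"  # or "five_prime" for window pairing
    concordance_null: Optional[float] = None  # None -> from class marginals

    def __post_init__(self):
        for name in ("merge_dist", "erna_proximity", "window_bp", "stitch_dist",
                     "stitch_proximity", "lfc", "fdr", "rho_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name!r} must be positive")
        if not 0 < self.correlation_keep_frac <= 1:
            raise ConfigError("correlation_keep_frac must be in (0, 1]")
        if self.enhancer_min < 1 or self.enhancer_max < self.enhancer_min:
            raise ConfigError("invalid enhancer count range")
        if self.overlap_relative_to not in ("reference", "tu"):
            raise ConfigError("overlap_relative_to must be 'reference' or 'tu'")
        if self.enhancer_anchor not in ("midpoint", "five_prime"):
            raise ConfigError("enhancer_anchor must be 'midpoint' or 'five_prime'")


@dataclass
class PipelineConfig:
    """Paths plus thresholds for an end-to-end run."""

    out_dir: str = "encoop_out"
    tus: Optional[str] = None          # BED6 of transcription units
    reference: Optional[str] = None    # GTF of annotated genes
    counts: Optional[str] = None       # TSV count table
    peaks_atac: list = field(default_factory=list)      # BED per time point
    peaks_h3k4me1: list = field(default_factory=list)
    tads: Optional[str] = None         # BED of TADs
    de_table: Optional[str] = None     # TSV unit_id/contrast/log2fc/fdr
    pairing_methods: list = field(default_factory=lambda: ["neighboring"])
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        bad = set(self.pairing_methods) - {"neighboring", "window", "tad"}
        if bad:
            raise ConfigError(f"unknown pairing methods: {sorted(bad)}")
        if "tad" in self.pairing_methods and not self.tads:
            raise ConfigError("pairing method 'tad' requested but no TAD file given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def manifest(self) -> dict:
        """Machine-readable run manifest: config hash, seed, thresholds."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "thresholds": dataclasses.asdict(self.thresholds),
        }

    def require(self, *names) -> None:
        for name in names:
            value = getattr(self, name)
            if not value:
                raise ConfigError(f"config field {name!r} is required for this stage")
            paths = value if isinstance(value, list) else [value]
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"path does not exist: {p}")
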