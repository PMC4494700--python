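"""Pipeline configuration.

Every numeric rule of the genotyping method lives here so that no stage
hard-codes a threshold.  Defaults reproduce the primary analysis mode:
exact tag matching, post-hoc mixture rules enabled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class PipelineConfig:
    """All tunable parameters of the genotyping pipeline.

    Attributes
    ----------
    tag_length:
        Length (bp) of the specificity tag extracted immediately downstream
        of the primer in the read.
    te_primer_max_mm:
        Maximum mismatches tolerated when matching the family-specific
        (TE-internal) primer at the start of read 2 of a G reaction.
    motif_max_mm:
        Maximum Hamming distance for detecting the reverse complement of the
        family diagnostic motif inside an E-reaction read.
    motif_fraction_threshold:
        Strict lower bound on the fraction of specific reads carrying the
        motif for the short-insertion override to fire.
    min_reads_all_absent:
        Rule A: if every sample has fewer than this many specific reads the
        amplicon is called absent in all samples.
    cluster_merge_distance:
        Rule B: two mixture components closer than this (log10 units) are
        merged into a single component.
    qc_low_mean_max / qc_high_mean_min:
        Cluster-mean QC thresholds (log10 read counts).
    qc_sd_max:
        Cluster standard-deviation QC threshold (log10 units).
    qc_unique_frac_min / qc_sample_frac_max:
        An amplicon fails tag-uniqueness QC when more than
        ``qc_sample_frac_max`` of the samples each have a uniquely-aligned
        tag fraction below ``qc_unique_frac_min``.
    quality_flag_threshold:
        Calls with log10-odds quality below this are flagged low quality
        (flagged, never removed).
    prior_shrinkage / prior_scale:
        Mean-shrinkage weight and variance-prior scale of the MAP-EM
        Gaussian mixture.
    prior_only:
        Disable post-hoc rules A and B, relying on the variance prior alone.
    tag_slack_bp / tag_max_mm:
        Relaxed tag matching: allowed start-position slack around the target
        and allowed mismatches.  Defaults (0, 0) replicate exact matching.
    max_amplicon_spread:
        Maximum allowed spread of expected product lengths within one
        multiplex library group (bp).
    quality_cap:
        Sentinel quality score used when the alternative-cluster posterior
        underflows or the fit is degenerate.
    scan_read2_for_motif:
        Also scan read 2 for the diagnostic motif (off by default; read 1 is
        long enough to reach the junction).
    min_phase_depth / min_phase_fraction:
        Monoploid caller thresholds: minimum pileup depth and majority-base
        fraction for a base call used in phasing.
    """

    tag_length: int = 50
    te_primer_max_mm: int = 1
    motif_max_mm: int = 6
    motif_fraction_threshold: float = 0.80
    min_reads_all_absent: int = 10
    cluster_merge_distance: float = 0.5
    qc_low_mean_max: float = 3.0
    qc_high_mean_min: float = 3.0
    qc_sd_max: float = 0.5
    qc_unique_frac_min: float = 0.80
    qc_sample_frac_max: float = 0.80
    quality_flag_threshold: float = 7.0
    prior_shrinkage: float = 0.1
    prior_scale: float = 1.0
    prior_only: bool = False
    tag_slack_bp: int = 0
    tag_max_mm: int = 0
    max_amplicon_spread: int = 200
    quality_cap: float = 15.0
    scan_read2_for_motif: bool = False
    min_phase_depth: int = 10
    min_phase_fraction: float = 0.9
    em_max_iter: int = 500
    em_tol: float = 1e-8

    def __post_init__(self) -> None:
        for name in (
            "motif_fraction_threshold",
            "qc_unique_frac_min",
            "qc_sample_frac_max",
            "min_phase_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        for name in (
            "tag_length",
            "min_reads_all_absent",
            "max_amplicon_spread",
            "min_phase_depth",
            "em_max_iter",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("te_primer_max_mm", "motif_max_mm", "tag_slack_bp", "tag_max_mm"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("prior_shrinkage", "prior_scale", "cluster_merge_distance", "em_tol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a plain ``key = value`` config file ('#' comments allowed)."""
        values: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ConfigError(f"{path}:{lineno}: unknown config field {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                if val.lower() not in {"true", "false", "0", "1"}:
                    raise ConfigError(f"{path}:{lineno}: {key} expects a boolean")
                values[key] = val.lower() in {"true", "1"}
            elif isinstance(current, int):
                values[key] = int(val)
            else:
                values[key] = float(val)
        return cls.from_dict(values)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
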