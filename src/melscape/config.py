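"""Pipeline configuration: dataclass, YAML loading, validation.

Every threshold the pipeline applies is surfaced here; the defaults are the
study's operating values (1% population allele fraction, 10-sample minimum
group size, 10 Mb focal-amplification bound, 25-fold coverage and 20%
purity sample QC floors).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import yaml


class ConfigError(ValueError):
    """Raised for malformed or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "melscape_out"
    # stage toggles
    run_simulate: bool = True
    run_filter: bool = True
    run_cn: bool = True
    run_drivers: bool = True
    run_stats: bool = True
    # thresholds (defaults = the study's printed operating values)
    pop_af_threshold: float = 0.01
    min_group_count: int = 10
    amplification_max_mb: float = 10.0
    qc_min_coverage: float = 25.0
    qc_min_purity: float = 0.20
    # cohort-generator overrides (passed to synthetic.CohortConfig)
    cohort: dict[str, Any] = field(default_factory=dict)
    # external inputs (used when run_simulate is False)
    mutations_path: Optional[str] = None
    segments_path: Optional[str] = None
    sample_sheet_path: Optional[str] = None
    germline_path: Optional[str] = None
    junctions_path: Optional[str] = None
    signatures_path: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("pop_af_threshold", "amplification_max_mb", "qc_min_coverage",
                     "qc_min_purity"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_group_count < 1:
            raise ConfigError("min_group_count must be >= 1")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if not isinstance(self.cohort, dict):
            raise ConfigError("cohort must be a mapping of CohortConfig overrides")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def to_dict(self) -> dict:
        return asdict(self)
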