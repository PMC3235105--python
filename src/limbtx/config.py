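"""Pipeline configuration: file paths, calling thresholds and the seed.

All printed thresholds of the analysis live here with their defaults:
fold-change 2 at BH-adjusted p < 0.001 for the DE call, fold >= 2 at
adjusted p <= 0.05 for enrichment with clusters of more than 40 members,
and the low-expression floor of 5 log2 units. A config round-trips through
a flat YAML file; CLI flags override individual keys.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .core import ConfigError


@dataclass(frozen=True)
class PipelineConfig:
    matrix: str | None = None
    sheet: str | None = None
    annotation: str | None = None
    phenotype_list: str | None = None
    out_dir: str = "limbtx_out"
    fc_threshold: float = 2.0
    p_threshold: float = 0.001
    enrichment_fold_min: float = 2.0
    enrichment_adjp_max: float = 0.05
    min_cluster_size: int = 41
    low_expression_threshold: float = 5.0
    d0_override: float | None = None
    s0_sq_override: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ConfigError(f"fc_threshold must exceed 1, got {self.fc_threshold}")
        if not 0 < self.p_threshold <= 1:
            raise ConfigError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if self.enrichment_fold_min <= 0:
            raise ConfigError("enrichment_fold_min must be positive")
        if not 0 < self.enrichment_adjp_max <= 1:
            raise ConfigError("enrichment_adjp_max must be in (0, 1]")
        if self.min_cluster_size < 1:
            raise ConfigError("min_cluster_size must be >= 1")
        if (self.d0_override is None) != (self.s0_sq_override is None):
            raise ConfigError("d0_override and s0_sq_override must be set together")

    def with_(self, **changes) -> "PipelineConfig":
        return replace(self, **changes)

    def require(self, *fields: str) -> None:
        for name in fields:
            if getattr(self, name) is None:
                raise ConfigError(f"config field {name!r} is required for this stage")
            path = Path(getattr(self, name))
            if not path.exists():
                raise ConfigError(f"{name} file not found: {path}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)
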