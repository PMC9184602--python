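"""Pipeline configuration.

All length thresholds are in base pairs, beta thresholds on the [0, 1]
methylation scale, and the HRD cutpoint on the HRDsum count scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant."""


@dataclass
class PipelineConfig:
    """Tunable constants of the HRD pipeline.

    Defaults are the published operating points: LOH regions must exceed
    15 Mb, LST junction segments must reach 10 Mb after 3 Mb smoothing,
    tumors are HRD-positive at HRDsum >= 42, and BRCA1 promoter
    hypermethylation is called strong at beta >= 0.6 and moderate at
    beta >= 0.2.
    """

    loh_min_length: int = 15_000_000
    lst_min_segment: int = 10_000_000
    lst_smoothing: int = 3_000_000
    tai_min_length: int = 0
    hrd_cutpoint: float = 42.0
    methylation_strong: float = 0.6
    methylation_moderate: float = 0.2
    gene_list: str = "long"
    prevalence_filter: float = 0.05
    fdr: float = 0.10
    include_moderate_hm_in_combined: bool = True
    # LOH dialect switches (operational rules differ between published tools)
    loh_count_homdel: bool = True
    include_sex_chromosomes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loh_min_length", "lst_min_segment", "lst_smoothing"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.tai_min_length < 0:
            raise ConfigError("tai_min_length must be >= 0")
        if not (0 <= self.methylation_moderate < self.methylation_strong <= 1):
            raise ConfigError(
                "methylation thresholds must satisfy 0 <= moderate < strong <= 1, "
                f"got moderate={self.methylation_moderate}, strong={self.methylation_strong}"
            )
        if not (0 < self.prevalence_filter < 1):
            raise ConfigError("prevalence_filter must be in (0, 1)")
        if not (0 < self.fdr < 1):
            raise ConfigError("fdr must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
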