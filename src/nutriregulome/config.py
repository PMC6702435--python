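"""Pipeline configuration: the fixed analysis constants in one place.

Defaults are the analysis constants used throughout: MR ceiling 5,
second-tier neighbour depth 2, minimum module size 4, marker support of
2 fully consistent studies, 50% ambiguity rule, 10% general-regulator
fraction, motif enrichment stringency 1e-3, and a correlation reporting
band of 0.24.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    mr_max: float = 5.0
    tier_depth: int = 2
    min_module_size: int = 4
    min_studies: int = 2
    min_fraction_consistent: float = 1.0
    ambiguity_fraction: float = 0.5
    general_fraction: float = 0.10
    motif_alpha: float = 1e-3
    correlation_band: float = 0.24
    clustering_linkage: str = "average"
    clustering_metric: str = "euclidean"
    deg_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        checks = [
            ("mr_max", self.mr_max >= 1),
            ("tier_depth", self.tier_depth >= 0),
            ("min_module_size", self.min_module_size >= 1),
            ("min_studies", self.min_studies >= 1),
            ("min_fraction_consistent", 0.0 < self.min_fraction_consistent <= 1.0),
            ("ambiguity_fraction", 0.0 <= self.ambiguity_fraction <= 1.0),
            ("general_fraction", 0.0 < self.general_fraction <= 1.0),
            ("motif_alpha", 0.0 < self.motif_alpha <= 1.0),
            ("correlation_band", self.correlation_band >= 0.0),
            ("deg_alpha", 0.0 < self.deg_alpha < 1.0),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"{name}: value {getattr(self, name)!r} outside its domain")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
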