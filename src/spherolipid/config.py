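"""Pipeline configuration: YAML-backed, validated, unknown keys rejected."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class IdentificationSettings:
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.02


@dataclass(frozen=True)
class CompositionSettings:
    scope: str = "total"  # denominator for species composition


@dataclass(frozen=True)
class StatsSettings:
    alpha: float = 0.05
    fdr: float = 0.10
    max_components: int = 3
    folds: Optional[int] = None  # None = leave-one-out
    vip_threshold: float = 1.0


@dataclass(frozen=True)
class PathwaySettings:
    map_path: Optional[str] = None
    alpha: float = 0.05
    n_permutations: int = 1000


@dataclass(frozen=True)
class InputPaths:
    peak_table: Optional[str] = None
    sample_table: Optional[str] = None
    msms: Optional[str] = None
    fame: Optional[str] = None
    expression: Optional[str] = None


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on besides the input data."""

    seed: int = 0
    out_dir: str = "spherolipid_out"
    preset: Optional[str] = "paper"  # "paper" | "null" | None (file inputs)
    inputs: InputPaths = field(default_factory=InputPaths)
    identification: IdentificationSettings = field(default_factory=IdentificationSettings)
    composition: CompositionSettings = field(default_factory=CompositionSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)
    pathway: PathwaySettings = field(default_factory=PathwaySettings)

    def __post_init__(self) -> None:
        if self.preset not in ("paper", "null", None):
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.composition.scope not in ("total", "within-class"):
            raise ConfigError(f"unknown composition scope {self.composition.scope!r}")
        if not (0 < self.stats.alpha < 1 and 0 < self.stats.fdr < 1):
            raise ConfigError("alpha and fdr must lie in (0, 1)")
        if self.identification.precursor_tol_ppm <= 0:
            raise ConfigError("precursor_tol_ppm must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


_SECTION_TYPES = {
    "inputs": InputPaths,
    "identification": IdentificationSettings,
    "composition": CompositionSettings,
    "stats": StatsSettings,
    "pathway": PathwaySettings,
}


def _build_section(cls, data: Mapping[str, Any], name: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {name!r}")
    return cls(**data)


def config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    allowed = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, Mapping):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a YAML mapping")
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
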