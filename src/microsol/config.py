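"""Pipeline configuration: one structured file, every default auditable.

The quantification literature this package follows leaves most processing
parameters unstated, so every free parameter lives in one YAML file with a
logged default, and unknown keys are rejected loudly instead of being
ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .preprocess import PreprocessParams
from .segment3d import SegmentationParams

__all__ = ["MorphometryOptions", "DensityOptions", "PipelineConfig", "ConfigError", "load_config"]


class ConfigError(Exception):
    """Raised for unparseable config files, unknown keys or invalid values."""


@dataclass(frozen=True)
class MorphometryOptions:
    exclude_border: bool = True
    aggregate: str = "pooled"  # or "by_lesion"

    def __post_init__(self) -> None:
        if self.aggregate not in ("pooled", "by_lesion"):
            raise ValueError(f"aggregate must be 'pooled' or 'by_lesion', got {self.aggregate!r}")


@dataclass(frozen=True)
class DensityOptions:
    # "pooled-otsu" shares one Otsu threshold across all images of the
    # experiment; a number fixes the threshold manually.
    threshold: float | str = "pooled-otsu"
    otsu_bins: int = 256

    def __post_init__(self) -> None:
        if isinstance(self.threshold, str) and self.threshold not in ("pooled-otsu", "per-image-otsu"):
            raise ValueError(f"unknown threshold policy {self.threshold!r}")


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segment: SegmentationParams = field(default_factory=SegmentationParams)
    morphometry: MorphometryOptions = field(default_factory=MorphometryOptions)
    density: DensityOptions = field(default_factory=DensityOptions)
    dx: float = 780.0 / 512
    dy: float = 780.0 / 512
    dz: float = 2.5
    rng_seed: int = 0

    def describe(self) -> dict[str, Any]:
        """Flat mapping of every effective parameter, for run logs."""
        return dataclasses.asdict(self)


def _build(cls, data: dict[str, Any], context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in {context}: {exc}") from exc


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; a missing path yields all defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in (
        ("preprocess", PreprocessParams),
        ("segment", SegmentationParams),
        ("morphometry", MorphometryOptions),
        ("density", DensityOptions),
    ):
        if name in raw:
            section = raw[name]
            if not isinstance(section, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            kwargs[name] = _build(cls, section, f"section {name!r}")
    for scalar in ("dx", "dy", "dz", "rng_seed"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config: {exc}") from exc
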