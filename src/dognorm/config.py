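"""Run configuration: a run is a pure, seedless function of its config."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .encoder import ModelUnit, NORMALIZATION_RATIOS, SURROUND_RATIOS


class ConfigError(ValueError):
    """The run configuration is invalid."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a sweep needs; fully serializable, deterministic."""

    resolution: int = 16                   # pixels per sigma_c
    padding: float = 5.0                   # grid half-width = padding * max sigma
    surround_ratios: tuple = SURROUND_RATIOS
    norm_ratios: tuple = NORMALIZATION_RATIOS
    contrast_step_pct: float = 1.0
    crf_background: float = 50.0
    n_luminance_targets: int = 60
    cone_adapt_intensities: tuple = (10.0, 100.0)
    aggregator: str = "mean"
    out_dir: str = "dognorm_out"

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ConfigError("resolution must be a positive integer (px per sigma_c)")
        if self.aggregator not in ("mean", "median"):
            raise ConfigError("aggregator must be 'mean' or 'median'")
        if self.n_luminance_targets < 10:
            raise ConfigError("n_luminance_targets must be >= 10 for L50 interpolation")
        if self.contrast_step_pct <= 0:
            raise ConfigError("contrast_step_pct must be positive")
        object.__setattr__(self, "surround_ratios", tuple(self.surround_ratios))
        object.__setattr__(self, "norm_ratios", tuple(self.norm_ratios))
        object.__setattr__(self, "cone_adapt_intensities", tuple(self.cone_adapt_intensities))

    def units(self) -> list[ModelUnit]:
        return [
            ModelUnit(sigma_s=ss, sigma_n=sn)
            for ss in self.surround_ratios
            for sn in self.norm_ratios
        ]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("surround_ratios", "norm_ratios", "cone_adapt_intensities"):
            d[key] = [float(v) for v in d[key]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(raw)

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)
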