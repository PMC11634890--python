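"""Pipeline configuration with YAML serialization.

Defaults follow the method's published operating point: N = 100 contour
points, band half-length L = 30, smoothing decay cap λ₀ = 0.9, fusion weight
α = 0.9, neighbour window 10 profiles to the left and 5 to the right.
Unknown keys in a config file are rejected, guarding against typos in
hyperparameter names.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from ._errors import ValidationError

__all__ = ["PipelineConfig", "CONFIG_VERSION"]

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    n_points: int = 100
    L: int = 30
    half_window: int | None = None  # None -> L
    m_left: int = 10
    m_right: int = 5
    lambda0: float = 0.9
    alpha: float = 0.9
    curvature_threshold: float = math.pi / 4
    k_step: int = 1
    mu: float = 0.95
    pixel_spacing: float = 1.0
    version: int = CONFIG_VERSION

    def validate(self) -> "PipelineConfig":
        if self.n_points < 3:
            raise ValidationError("n_points must be >= 3")
        if self.L < 1:
            raise ValidationError(f"L must be >= 1, got {self.L}")
        if self.half_window is not None and self.half_window < 1:
            raise ValidationError("half_window must be >= 1")
        if self.m_left < 0 or self.m_right < 0:
            raise ValidationError("neighbour window sizes must be >= 0")
        if self.m_left + self.m_right >= self.n_points:
            raise ValidationError("neighbour window must be smaller than n_points")
        if not (0 < self.lambda0 < 1):
            raise ValidationError("lambda0 must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if not self.curvature_threshold > 0:
            raise ValidationError("curvature_threshold must be positive")
        if self.k_step < 1:
            raise ValidationError("k_step must be >= 1")
        if not (0 < self.mu < 1):
            raise ValidationError("mu must be in (0, 1)")
        if not self.pixel_spacing > 0:
            raise ValidationError("pixel_spacing must be positive")
        if self.version != CONFIG_VERSION:
            raise ValidationError(
                f"unsupported config version {self.version} (expected {CONFIG_VERSION})"
            )
        return self

    @property
    def effective_half_window(self) -> int:
        return self.L if self.half_window is None else self.half_window

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()
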