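"""Measurement configuration: schema, validation and loading.

The YAML config mirrors what the measurement software asks its operator for:
camera intrinsics plus, optionally, the camera placement distance and the
water depth in the bucket.  The camera height above the surface is derived
as ``h = camera_placement - water_depth``.  When the refraction section is
omitted the pipeline runs in ignore-refraction mode.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .camera import CameraModel
from .errors import ConfigError
from .refraction import RefractionModel
from .segmentation import SegConfig

__all__ = ["MeasureConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CameraSection(_Strict):
    fx: float = Field(gt=0)
    fy: float = Field(gt=0)
    cx: float
    cy: float
    baseline_mm: float = Field(gt=0)
    width: int = Field(gt=0)
    height: int = Field(gt=0)

    def to_model(self) -> CameraModel:
        return CameraModel(
            focal_length_px_x=self.fx,
            focal_length_px_y=self.fy,
            principal_point=(self.cx, self.cy),
            baseline_mm=self.baseline_mm,
            resolution=(self.width, self.height),
        )


class RefractionSection(_Strict):
    camera_placement_mm: float = Field(gt=0)
    water_depth_mm: float = Field(gt=0)
    n_air: float = 1.0
    n_water: float = 1.333

    @model_validator(mode="after")
    def _check_height(self) -> "RefractionSection":
        if self.camera_placement_mm <= self.water_depth_mm:
            raise ValueError(
                "camera placement must exceed the water depth "
                "(camera height above the surface would not be positive)"
            )
        return self

    @property
    def camera_height_mm(self) -> float:
        return self.camera_placement_mm - self.water_depth_mm

    def to_model(self) -> RefractionModel:
        return RefractionModel(
            camera_height_mm=self.camera_height_mm, n_air=self.n_air, n_water=self.n_water
        )


class SegmentationSection(_Strict):
    gmm_components: int = 5
    gamma: float = 50.0
    n_iterations: int = 5
    stretch_low_pct: float = 1.0
    stretch_high_pct: float = 99.0
    brightness_offset: float = 0.0
    rng_seed: int = 0

    def to_model(self) -> SegConfig:
        return SegConfig(**self.model_dump())


class SkeletonSection(_Strict):
    max_deletions: Optional[int] = None


class MeasurementSection(_Strict):
    theta_threshold_deg: float = 5.0


class MeasureConfig(_Strict):
    camera: CameraSection
    refraction: Optional[RefractionSection] = None
    segmentation: SegmentationSection = SegmentationSection()
    skeleton: SkeletonSection = SkeletonSection()
    measurement: MeasurementSection = MeasurementSection()

    def camera_model(self) -> CameraModel:
        return self.camera.to_model()

    def refraction_model(self) -> Optional[RefractionModel]:
        return self.refraction.to_model() if self.refraction else None


def load_config(path: str | Path) -> MeasureConfig:
    """Parse and validate a YAML measurement config."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return MeasureConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
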