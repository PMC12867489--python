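"""Configuration schema, YAML/JSON loading, and shipped presets.

Configuration files use lab-friendly units (mm, nm, um, deg); they are
validated against a strict schema (unknown keys rejected) and converted to SI
once at parse time.  Two presets ship with the package:

* ``confocal_785`` -- 785 nm confocal point-source spectrometer: 3.3700000 mm
  fused-silica VIPA (R = 100%/92%, y-tilt 2 deg) cascaded with a 3.3700025 mm
  etalon (R = 94% both faces, x-tilt 0.1 deg).
* ``linescan_532`` -- 532 nm line-scanning spectrometer with a 110 um line
  source and the same VIPA/etalon cavity parameters.
"""

from __future__ import annotations

import importlib.resources
import pathlib
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .optics import CavitySpec, OpticalGeometry
from .sources import SourceSpec, SpectralLine

__all__ = [
    "CavityConfig",
    "GeometryConfig",
    "SourceConfig",
    "RunConfig",
    "load_run_config",
    "load_preset",
    "preset_names",
]

MM = 1e-3
UM = 1e-6
NM = 1e-9


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CavityConfig(_StrictModel):
    thickness_mm: float = Field(gt=0)
    index: float = Field(ge=1)
    r_front: float = Field(ge=0, le=1)
    r_back: float = Field(ge=0, le=1)
    tilt_y_deg: float = 0.0
    tilt_x_deg: float = 0.0
    sigma_nm: float = Field(default=0.0, ge=0)

    def to_spec(self) -> CavitySpec:
        return CavitySpec(
            thickness_m=self.thickness_mm * MM,
            index=self.index,
            reflectance_front=self.r_front,
            reflectance_back=self.r_back,
            tilt_y_rad=np.deg2rad(self.tilt_y_deg),
            tilt_x_rad=np.deg2rad(self.tilt_x_deg),
            thickness_sigma_m=self.sigma_nm * NM,
        )


class GeometryConfig(_StrictModel):
    wavelength_nm: float = Field(gt=0)
    f_collimator_mm: float = Field(gt=0)
    f_imaging_mm: float = Field(gt=0)
    pixel_um: float = Field(gt=0)
    pixel_x_um: float | None = Field(default=None, gt=0)
    sensor: tuple[int, int]
    axis_pixel: tuple[float, float] | None = None

    def to_geometry(self) -> OpticalGeometry:
        return OpticalGeometry(
            wavelength_m=self.wavelength_nm * NM,
            collimator_focal_m=self.f_collimator_mm * MM,
            imaging_focal_m=self.f_imaging_mm * MM,
            pixel_pitch_m=self.pixel_um * UM,
            sensor_shape=tuple(self.sensor),
            axis_pixel=tuple(self.axis_pixel) if self.axis_pixel else None,
            pixel_pitch_x_m=self.pixel_x_um * UM if self.pixel_x_um else None,
        )


class SpectralLineConfig(_StrictModel):
    offset_ghz: float
    amplitude: float = Field(ge=0)


class SourceConfig(_StrictModel):
    kind: Literal["point", "line"]
    gaussian_diameter_um: float | None = Field(default=None, gt=0)
    line_length_um: float | None = Field(default=None, gt=0)
    spectrum: list[SpectralLineConfig] = Field(min_length=1)

    @model_validator(mode="after")
    def _check_size(self):
        if self.kind == "point" and self.gaussian_diameter_um is None:
            raise ValueError("point source requires gaussian_diameter_um")
        if self.kind == "line" and self.line_length_um is None:
            raise ValueError("line source requires line_length_um")
        return self

    def to_source(self) -> SourceSpec:
        spectrum = tuple(
            SpectralLine(line.offset_ghz, line.amplitude) for line in self.spectrum
        )
        if self.kind == "point":
            return SourceSpec.point(self.gaussian_diameter_um * UM, spectrum)
        return SourceSpec.line(self.line_length_um * UM, spectrum)


class RunConfig(_StrictModel):
    """Validated spectrometer run configuration."""

    geometry: GeometryConfig
    cavities: list[CavityConfig] = Field(min_length=1)
    source: SourceConfig
    seed: int = 0

    def build(self) -> tuple[SourceSpec, list[CavitySpec], OpticalGeometry]:
        return (
            self.source.to_source(),
            [c.to_spec() for c in self.cavities],
            self.geometry.to_geometry(),
        )

    def resolved(self) -> dict:
        """Plain-dict echo of every resolved parameter (for provenance logs)."""
        return self.model_dump()


def load_run_config(path) -> RunConfig:
    text = pathlib.Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def preset_names() -> list[str]:
    root = importlib.resources.files("vipacascade") / "presets"
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> RunConfig:
    """Load a shipped preset by name (e.g. ``confocal_785``)."""
    resource = importlib.resources.files("vipacascade") / "presets" / f"{name}.yaml"
    if not resource.is_file():
        raise FileNotFoundError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        )
    return RunConfig.model_validate(yaml.safe_load(resource.read_text()))
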