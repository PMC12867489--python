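"""Source models and sensor-image formation.

The spectrometer image is the product of two independent maps: the cascade
transfer function (per spectral component) and the normalized system response
without the Fabry-Perot elements.  The source -- a small Gaussian point for
confocal collection or a uniform line for line scanning -- is re-imaged along
x with the focal-length-ratio magnification and spread as a flat envelope
along y, the dispersion axis.  Each spectral line of the source is rendered
through the cascade at its own (Brillouin-shifted) wavelength and the
components are summed.

Images here are noiseless ideal intensities; camera noise lives in
:mod:`vipacascade.synth`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import constants

from .optics import (
    CavitySpec,
    OpticalGeometry,
    airy_transmission,
    finesse,
    _cos_grid,
    _internal_cos,
)

__all__ = [
    "SpectralLine",
    "SourceSpec",
    "SensorImage",
    "frequency_shift_wavelength",
    "system_response",
    "render_image",
    "check_sampling",
    "fringe_fwhm_pixels",
]

C = constants.c
GHZ = 1.0e9


@dataclass(frozen=True)
class SpectralLine:
    """One monochromatic component: frequency offset from the pump (GHz)
    and relative intensity.  Offset 0 is the Rayleigh (elastic) line; the
    Stokes / anti-Stokes Brillouin doublet sits at -/+ the Brillouin shift."""

    offset_ghz: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class SourceSpec:
    """Confocal point source or line-scan source with a spectrum.

    ``gaussian_diameter_m`` is the 1/e^2 intensity diameter of the point
    source (at the source plane, before magnification); ``line_length_m`` the
    uniform line extent along the non-dispersion axis.  Exactly the size field
    matching ``kind`` must be set.
    """

    kind: str
    spectrum: tuple[SpectralLine, ...]
    gaussian_diameter_m: float | None = None
    line_length_m: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "line"):
            raise ValueError("kind must be 'point' or 'line'")
        object.__setattr__(self, "spectrum", tuple(self.spectrum))
        if not self.spectrum:
            raise ValueError("spectrum must be nonempty")
        if self.kind == "point":
            if self.gaussian_diameter_m is None or not self.gaussian_diameter_m > 0:
                raise ValueError("point source requires gaussian_diameter_m > 0")
            if self.line_length_m is not None:
                raise ValueError("point source must not set line_length_m")
        else:
            if self.line_length_m is None or not self.line_length_m > 0:
                raise ValueError("line source requires line_length_m > 0")
            if self.gaussian_diameter_m is not None:
                raise ValueError("line source must not set gaussian_diameter_m")

    @classmethod
    def point(
        cls, gaussian_diameter_m: float, spectrum: Sequence[SpectralLine]
    ) -> "SourceSpec":
        return cls("point", tuple(spectrum), gaussian_diameter_m=gaussian_diameter_m)

    @classmethod
    def line(cls, line_length_m: float, spectrum: Sequence[SpectralLine]) -> "SourceSpec":
        return cls("line", tuple(spectrum), line_length_m=line_length_m)

    def with_spectrum(self, spectrum: Sequence[SpectralLine]) -> "SourceSpec":
        return dataclasses.replace(self, spectrum=tuple(spectrum))


@dataclass
class SensorImage:
    """2-D nonnegative intensity grid with exposure and saturation metadata."""

    intensity: np.ndarray
    exposure_s: float = 1.0
    saturation_level: float = np.inf

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D grid")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")
        if not self.exposure_s > 0:
            raise ValueError("exposure_s must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


def frequency_shift_wavelength(wavelength_m: float, offset_ghz: float) -> float:
    """Vacuum wavelength of light offset by ``offset_ghz`` from the pump.

    lambda' = c / (c/lambda + delta_nu); positive (anti-Stokes) offsets give a
    shorter wavelength.
    """
    nu = C / wavelength_m + offset_ghz * GHZ
    return C / nu


def system_response(source: SourceSpec, geometry: OpticalGeometry) -> np.ndarray:
    """Normalized sensor response of the system without the FP elements.

    Separable: the magnified source profile along x (columns) times a flat
    unit envelope along y (rows).  Unit maximum.  If the magnified source
    exceeds the sensor a warning is emitted and the profile is truncated.
    """
    x = geometry.col_offsets_m()
    mag = geometry.magnification
    if source.kind == "point":
        diameter = source.gaussian_diameter_m * mag
        extent = 2.0 * diameter  # +/- 2 x 1/e^2 radius
        profile = np.exp(-8.0 * (x / diameter) ** 2)
    else:
        length = source.line_length_m * mag
        extent = length
        half = length / 2.0
        pitch = geometry.pitch_x
        # fractional pixel coverage at the flat-top edges
        profile = np.clip((half - np.abs(x)) / pitch + 0.5, 0.0, 1.0)
    span = x.max() - x.min()
    if extent > span:
        warnings.warn(
            "magnified source exceeds the sensor along x; envelope truncated",
            stacklevel=2,
        )
    envelope = np.ones(geometry.sensor_shape[0])[:, None] * profile[None, :]
    peak = envelope.max()
    if peak <= 0:
        raise ValueError("source envelope is identically zero on the sensor")
    return envelope / peak


def fringe_fwhm_pixels(
    cavity: CavitySpec, geometry: OpticalGeometry, wavelength_m: float | None = None
) -> float:
    """Smallest fringe FWHM (in row pixels) of a cavity across the sensor.

    The local fringe period along the dispersion axis is 2*pi over the phase
    change per pixel; dividing by the finesse gives the fringe FWHM.  The
    phase gradient grows with field angle, so the minimum is taken over the
    sensor's worst (largest-angle) edge.
    """
    lam = geometry.wavelength_m if wavelength_m is None else wavelength_m
    rows = geometry.sensor_shape[0]
    ax_col = geometry.axis[1]
    fwhms = []
    for row in (0.0, rows - 1.0):
        cos_a = _internal_cos(
            geometry.row_offsets_m(row), geometry.col_offsets_m(ax_col), geometry, cavity
        )
        cos_b = _internal_cos(
            geometry.row_offsets_m(row + (1.0 if row == 0 else -1.0)),
            geometry.col_offsets_m(ax_col),
            geometry,
            cavity,
        )
        dphi = abs(
            4.0 * np.pi * cavity.index * cavity.thickness_m / lam * (cos_a - cos_b)
        )
        if dphi == 0:
            fwhms.append(np.inf)
        else:
            period_px = 2.0 * np.pi / dphi
            fwhms.append(period_px / finesse(cavity.effective_reflectance))
    return float(min(fwhms))


def check_sampling(
    cavities: Sequence[CavitySpec],
    geometry: OpticalGeometry,
    min_samples_per_fwhm: float = 8.0,
) -> None:
    """Require >= ``min_samples_per_fwhm`` row pixels per instrument FWHM."""
    for cav in cavities:
        if cav.effective_reflectance == 0.0:
            continue
        fwhm_px = fringe_fwhm_pixels(cav, geometry)
        if fwhm_px < min_samples_per_fwhm:
            raise ValueError(
                f"sensor undersamples the fringes: {fwhm_px:.2f} px per FWHM "
                f"(need >= {min_samples_per_fwhm}); reduce pixel_pitch_m"
            )


def render_image(
    source: SourceSpec,
    cavities: Sequence[CavitySpec],
    geometry: OpticalGeometry,
    exposure_s: float = 1.0,
    saturation_level: float = np.inf,
) -> SensorImage:
    """Ideal sensor image of a source through the cascade.

    For each spectral line the cascade transfer map is evaluated at the
    shifted wavelength, multiplied by the system envelope, scaled by the line
    amplitude, and summed.  An empty cascade returns the bare envelope times
    the summed amplitudes.
    """
    cavities = list(cavities)
    check_sampling(cavities, geometry)
    envelope = system_response(source, geometry)
    total = np.zeros(geometry.sensor_shape)
    if cavities:
        cos_grids = [_cos_grid(cav, geometry) for cav in cavities]
    for line in source.spectrum:
        lam = frequency_shift_wavelength(geometry.wavelength_m, line.offset_ghz)
        if cavities:
            transfer = np.ones(geometry.sensor_shape)
            for cav, cos_grid in zip(cavities, cos_grids):
                transfer *= airy_transmission(
                    cos_grid, cav.effective_reflectance, cav.thickness_m, cav.index, lam
                )
        else:
            transfer = 1.0
        total += line.amplitude * np.asarray(transfer)
    return SensorImage(
        total * envelope, exposure_s=exposure_s, saturation_level=saturation_level
    )
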