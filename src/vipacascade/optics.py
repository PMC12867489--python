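"""Closed-form Fabry-Perot cavity physics.

A virtually imaged phased array (VIPA) and the etalons cascaded behind it are
all plane-parallel Fabry-Perot cavities.  For a lossless cavity of thickness
``d``, refractive index ``n`` and (equal) mirror reflectance ``R``, the
transmitted intensity at vacuum wavelength ``lambda`` and *internal* refraction
angle ``theta`` is the Airy function

    T = (1 - R)^2 / (1 + R^2 - 2 R cos(4 pi n d cos(theta) / lambda)),

which reaches unity at resonance and (1-R)^2/(1+R)^2 at anti-resonance.  The
round-trip phase uses the internal (Snell-corrected) angle: for a solid cavity
the physical path folds inside the medium, so ``sin(theta_int) =
sin(theta_ext)/n``.  At the <= 2 deg tilts of interest the distinction is a
sub-ppm phase correction, but it is exactly this correction that makes a small
thickness offset (a few nm) equivalent to a small x-tilt of the etalon.

This module provides the per-pixel transfer maps of single cavities and of
cascades (pixelwise products), the standard spectrometer figures of merit
(free spectral range, finesse, Airy contrast and mean transmission), and the
thickness-nonuniformity average that models real etalon surface defects.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import hermite_e
from scipy import constants

__all__ = [
    "CavitySpec",
    "OpticalGeometry",
    "TransferMap",
    "airy_transmission",
    "airy_contrast",
    "airy_contrast_db",
    "airy_mean_transmission",
    "mean_transmission",
    "effective_reflectance",
    "free_spectral_range",
    "finesse",
    "pixel_to_internal_cos",
    "cavity_transfer_map",
    "cascade_transfer_map",
    "cascade_transmission_at",
    "nonuniform_transfer",
    "matched_etalon_thickness",
    "peak_transmission_nonuniform",
]

C = constants.c  # vacuum speed of light, m/s
GHZ = 1.0e9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CavitySpec:
    """One Fabry-Perot element (VIPA or etalon).

    Parameters
    ----------
    thickness_m : float
        Cavity (plate) thickness ``d`` in metres.
    index : float
        Refractive index ``n`` of the cavity medium (>= 1).
    reflectance_front, reflectance_back : float
        Intensity reflectances of the two mirrors, each in [0, 1].  A VIPA's
        fully reflective entrance mirror may be exactly 1; the pair is reduced
        to the equal-mirror reflectance sqrt(R_front * R_back) for the Airy
        response (both may not be 1 simultaneously).
    tilt_y_rad, tilt_x_rad : float
        Tilt of the cavity normal about the two sensor axes, radians.  The
        y-tilt sets the working incidence angle (dispersion); a small x-tilt
        inclines the fringes of a cascaded etalon relative to the VIPA's.
    thickness_sigma_m : float
        Standard deviation of the thickness nonuniformity across the aperture
        (m, >= 0); see :func:`nonuniform_transfer`.
    """

    thickness_m: float
    index: float
    reflectance_front: float
    reflectance_back: float
    tilt_y_rad: float = 0.0
    tilt_x_rad: float = 0.0
    thickness_sigma_m: float = 0.0

    def __post_init__(self) -> None:
        if not self.thickness_m > 0:
            raise ValueError("thickness_m must be positive")
        if not self.index >= 1.0:
            raise ValueError("index must be >= 1")
        for name in ("reflectance_front", "reflectance_back"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.reflectance_front * self.reflectance_back >= 1.0:
            raise ValueError("lossless limit R_front * R_back = 1 is undefined")
        if self.thickness_sigma_m < 0:
            raise ValueError("thickness_sigma_m must be >= 0")

    @property
    def effective_reflectance(self) -> float:
        """Equal-mirror reflectance sqrt(R_front * R_back)."""
        return effective_reflectance(self.reflectance_front, self.reflectance_back)

    @property
    def finesse(self) -> float:
        return finesse(self.effective_reflectance)

    def fsr_ghz(self, cos_theta_internal: float = 1.0) -> float:
        return free_spectral_range(
            self.thickness_m, self.index, cos_theta_internal
        )

    def replace(self, **changes) -> "CavitySpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class OpticalGeometry:
    """Imaging geometry mapping sensor pixels to incidence angles.

    The source is re-imaged onto the sensor along x (magnification
    ``imaging_focal_m / collimator_focal_m``) and spread uniformly along y,
    the dispersion axis (image rows).  A pixel offset from the optical axis
    corresponds to a field angle ``offset / imaging_focal_m`` (first order),
    to which the cavity tilts are added per axis.

    ``pixel_pitch_m`` is the row (dispersion-axis) pitch; ``pixel_pitch_x_m``
    optionally sets a different column pitch (fringes vary on a ~10 um scale
    along y but only on a ~100 um scale along x, so anisotropic sampling keeps
    grids small).
    """

    wavelength_m: float
    collimator_focal_m: float
    imaging_focal_m: float
    pixel_pitch_m: float
    sensor_shape: tuple[int, int]
    axis_pixel: tuple[float, float] | None = None
    pixel_pitch_x_m: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "wavelength_m",
            "collimator_focal_m",
            "imaging_focal_m",
            "pixel_pitch_m",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        rows, cols = self.sensor_shape
        if rows < 1 or cols < 1:
            raise ValueError("sensor_shape must be positive")
        if self.pixel_pitch_x_m is not None and not self.pixel_pitch_x_m > 0:
            raise ValueError("pixel_pitch_x_m must be positive")
        ar, ac = self.axis
        if not (0 <= ar <= rows - 1 and 0 <= ac <= cols - 1):
            raise ValueError("axis_pixel must lie inside the sensor")

    @property
    def axis(self) -> tuple[float, float]:
        if self.axis_pixel is not None:
            return self.axis_pixel
        rows, cols = self.sensor_shape
        return ((rows - 1) / 2.0, (cols - 1) / 2.0)

    @property
    def pitch_x(self) -> float:
        return (
            self.pixel_pitch_x_m
            if self.pixel_pitch_x_m is not None
            else self.pixel_pitch_m
        )

    @property
    def magnification(self) -> float:
        return self.imaging_focal_m / self.collimator_focal_m

    def row_offsets_m(self, rows=None) -> np.ndarray:
        """Metric sensor displacement of row centres from the optical axis."""
        if rows is None:
            rows = np.arange(self.sensor_shape[0])
        return (np.asarray(rows, dtype=float) - self.axis[0]) * self.pixel_pitch_m

    def col_offsets_m(self, cols=None) -> np.ndarray:
        if cols is None:
            cols = np.arange(self.sensor_shape[1])
        return (np.asarray(cols, dtype=float) - self.axis[1]) * self.pitch_x

    def replace(self, **changes) -> "OpticalGeometry":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TransferMap:
    """Per-pixel cavity (or cascade) transmission, each value in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("transfer values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def max(self) -> float:
        return float(self.values.max())

    def min(self) -> float:
        return float(self.values.min())


# ---------------------------------------------------------------------------
# scalar figures of merit
# ---------------------------------------------------------------------------


def airy_transmission(cos_theta_internal, reflectance, thickness_m, index, wavelength_m):
    """Lossless Fabry-Perot (Airy) transmission.

    ``(1-R)^2 / (1 + R^2 - 2 R cos(4 pi n d cos(theta_int) / lambda))``,
    vectorised over ``cos_theta_internal``.
    """
    r = float(reflectance)
    if not 0.0 <= r < 1.0:
        raise ValueError("reflectance must lie in [0, 1)")
    for name, val in (
        ("thickness_m", thickness_m),
        ("index", index),
        ("wavelength_m", wavelength_m),
    ):
        if not val > 0:
            raise ValueError(f"{name} must be positive")
    cos_t = np.asarray(cos_theta_internal, dtype=float)
    if np.any(cos_t <= 0) or np.any(cos_t > 1 + 1e-12):
        raise ValueError("cos_theta_internal must lie in (0, 1]")
    phase = 4.0 * np.pi * index * thickness_m * cos_t / wavelength_m
    out = (1.0 - r) ** 2 / (1.0 + r * r - 2.0 * r * np.cos(phase))
    return out if out.ndim else float(out)


def effective_reflectance(reflectance_front: float, reflectance_back: float) -> float:
    """Equal-mirror reflectance whose Airy response matches an unequal pair.

    The geometric mean sqrt(R1 R2) preserves the round-trip amplitude loss,
    hence the resonance/anti-resonance extrema of the unequal-mirror cavity.
    """
    if not (0.0 <= reflectance_front <= 1.0 and 0.0 <= reflectance_back <= 1.0):
        raise ValueError("reflectances must lie in [0, 1]")
    return math.sqrt(reflectance_front * reflectance_back)


def free_spectral_range(
    thickness_m: float, index: float, cos_theta_internal: float = 1.0
) -> float:
    """Cavity free spectral range c / (2 n d cos(theta)) in GHz."""
    if not (thickness_m > 0 and index > 0 and cos_theta_internal > 0):
        raise ValueError("inputs must be positive")
    return C / (2.0 * index * thickness_m * cos_theta_internal) / GHZ


def finesse(reflectance: float) -> float:
    """Reflectivity finesse pi sqrt(R) / (1 - R)."""
    if not 0.0 <= reflectance < 1.0:
        raise ValueError("reflectance must lie in [0, 1)")
    return math.pi * math.sqrt(reflectance) / (1.0 - reflectance)


def airy_contrast(reflectance: float) -> float:
    """Peak-to-minimum ratio of the Airy function, ((1+R)/(1-R))^2."""
    if not 0.0 <= reflectance < 1.0:
        raise ValueError("reflectance must lie in [0, 1)")
    return ((1.0 + reflectance) / (1.0 - reflectance)) ** 2


def airy_contrast_db(reflectance: float) -> float:
    return 10.0 * math.log10(airy_contrast(reflectance))


def airy_mean_transmission(reflectance: float) -> float:
    """Phase-averaged Airy transmission over one full period, (1-R)/(1+R).

    This is the throughput of a stand-alone etalon illuminated uniformly over
    one free spectral range of incidence phase (cylindrically diverging input).
    """
    if not 0.0 <= reflectance < 1.0:
        raise ValueError("reflectance must lie in [0, 1)")
    return (1.0 - reflectance) / (1.0 + reflectance)


def mean_transmission(reflectance: float, num_samples: int = 200001) -> float:
    """Numerical phase average of the Airy function over one period.

    Cross-checks :func:`airy_mean_transmission`; kept numerical so throughput
    claims are recomputed rather than quoted.
    """
    r = float(reflectance)
    if not 0.0 <= r < 1.0:
        raise ValueError("reflectance must lie in [0, 1)")
    # midpoint rule over one 2*pi period of the round-trip phase
    phase = (np.arange(num_samples) + 0.5) * (2.0 * np.pi / num_samples)
    t = (1.0 - r) ** 2 / (1.0 + r * r - 2.0 * r * np.cos(phase))
    return float(t.mean())


# ---------------------------------------------------------------------------
# angle geometry and transfer maps
# ---------------------------------------------------------------------------


def _internal_cos(y_m, x_m, geometry: OpticalGeometry, cavity: CavitySpec):
    """Internal-angle cosine for metric sensor offsets (y_m, x_m)."""
    f = geometry.imaging_focal_m
    theta_y = np.asarray(y_m, dtype=float) / f + cavity.tilt_y_rad
    theta_x = np.asarray(x_m, dtype=float) / f + cavity.tilt_x_rad
    theta_ext = np.hypot(theta_y, theta_x)
    sin_int = np.sin(theta_ext) / cavity.index
    if np.any(np.abs(sin_int) >= 1.0):
        raise ValueError("external angle beyond total internal refraction limit")
    return np.sqrt(1.0 - sin_int * sin_int)


def pixel_to_internal_cos(pixel, geometry: OpticalGeometry, cavity: CavitySpec):
    """cos(theta_internal) for a (row, col) sensor pixel (fractional allowed).

    Field angles are first order in the imaging: ``theta = offset / f`` per
    axis, the cavity tilt adds linearly per axis, the two axes combine in
    quadrature, and Snell's law maps the external angle into the cavity.
    """
    row, col = pixel
    rows, cols = geometry.sensor_shape
    if np.any(np.asarray(row) < -0.5) or np.any(np.asarray(row) > rows - 0.5):
        raise ValueError("pixel row outside sensor bounds")
    if np.any(np.asarray(col) < -0.5) or np.any(np.asarray(col) > cols - 0.5):
        raise ValueError("pixel col outside sensor bounds")
    y = geometry.row_offsets_m(row)
    x = geometry.col_offsets_m(col)
    return _internal_cos(y, x, geometry, cavity)


def _cos_grid(cavity: CavitySpec, geometry: OpticalGeometry) -> np.ndarray:
    y = geometry.row_offsets_m()[:, None]
    x = geometry.col_offsets_m()[None, :]
    return _internal_cos(y, x, geometry, cavity)


def cavity_transfer_map(
    cavity: CavitySpec,
    geometry: OpticalGeometry,
    wavelength_m: float | None = None,
) -> TransferMap:
    """Airy transmission of one cavity evaluated at every sensor pixel."""
    lam = geometry.wavelength_m if wavelength_m is None else wavelength_m
    values = airy_transmission(
        _cos_grid(cavity, geometry),
        cavity.effective_reflectance,
        cavity.thickness_m,
        cavity.index,
        lam,
    )
    return TransferMap(values)


def cascade_transfer_map(
    cavities: Sequence[CavitySpec],
    geometry: OpticalGeometry,
    wavelength_m: float | None = None,
) -> TransferMap:
    """Pixelwise product of the cavity maps (VIPA first, then each etalon)."""
    cavities = list(cavities)
    if not cavities:
        raise ValueError("cascade requires at least one cavity")
    lam = geometry.wavelength_m if wavelength_m is None else wavelength_m
    total = None
    for cav in cavities:
        m = cavity_transfer_map(cav, geometry, lam).values
        total = m if total is None else total * m
    return TransferMap(total)


def cascade_transmission_at(
    row,
    col,
    cavities: Sequence[CavitySpec],
    geometry: OpticalGeometry,
    wavelength_m: float | None = None,
):
    """Cascade transmission at (possibly fractional) sensor coordinates.

    Useful for sub-pixel refinement of resonance peaks, e.g. verifying that a
    defect-free aligned cascade reaches unity transmission.
    """
    cavities = list(cavities)
    if not cavities:
        raise ValueError("cascade requires at least one cavity")
    lam = geometry.wavelength_m if wavelength_m is None else wavelength_m
    total = 1.0
    for cav in cavities:
        cos_t = pixel_to_internal_cos((row, col), geometry, cav)
        total = total * airy_transmission(
            cos_t, cav.effective_reflectance, cav.thickness_m, cav.index, lam
        )
    return total


def nonuniform_transfer(
    cavity: CavitySpec,
    geometry: OpticalGeometry,
    num_samples: int = 201,
    seed: int = 0,
    method: str = "normal",
    wavelength_m: float | None = None,
) -> TransferMap:
    """Transfer map averaged over a Normal thickness distribution.

    Real etalons are not perfectly flat; across the illuminated aperture the
    local thickness varies with standard deviation ``thickness_sigma_m``.  The
    spectrally averaged response is the mean of ideal maps over thickness
    draws d ~ Normal(d0, sigma), which broadens resonances and caps the peak
    transmission below unity.

    ``method="normal"`` uses fixed-seed pseudo-random draws (deterministic
    given ``seed``); ``method="gauss-hermite"`` uses deterministic
    Gauss-Hermite quadrature nodes/weights, suitable as an oracle.
    """
    if num_samples < 1:
        raise ValueError("num_samples must be >= 1")
    sigma = cavity.thickness_sigma_m
    if sigma == 0.0:
        return cavity_transfer_map(cavity, geometry, wavelength_m)
    if method == "normal":
        rng = np.random.default_rng(seed)
        draws = rng.normal(cavity.thickness_m, sigma, size=num_samples)
        weights = np.full(num_samples, 1.0 / num_samples)
    elif method == "gauss-hermite":
        # probabilists' Hermite quadrature: integral against the unit Normal
        nodes, w = hermite_e.hermegauss(num_samples)
        draws = cavity.thickness_m + sigma * nodes
        weights = w / math.sqrt(2.0 * math.pi)
        weights = weights / weights.sum()
    else:
        raise ValueError(f"unknown method {method!r}")
    lam = geometry.wavelength_m if wavelength_m is None else wavelength_m
    cos_grid = _cos_grid(cavity, geometry)
    r = cavity.effective_reflectance
    total = np.zeros(cos_grid.shape)
    for d, w in zip(draws, weights):
        total += w * airy_transmission(cos_grid, r, d, cavity.index, lam)
    return TransferMap(np.clip(total, 0.0, 1.0))


def matched_etalon_thickness(vipa: CavitySpec, etalon: CavitySpec) -> float:
    """Etalon thickness that matches the VIPA's optical thickness on axis.

    An etalon whose x-tilt differs from the VIPA's sees a slightly different
    internal angle at the optical axis; its resonances coincide with the
    VIPA's when the optical thicknesses n d cos(theta_int) are equal, i.e.
    ``d_etalon = d_vipa cos(theta_vipa) / cos(theta_etalon)`` (for equal
    indices).  The condition is purely geometric, hence wavelength
    independent; for a 0.1 deg x-tilt at a 2 deg y-tilt it amounts to a
    +2.44 nm thickness offset on a 3.37 mm plate.
    """
    cos_v = _axis_internal_cos(vipa)
    cos_e = _axis_internal_cos(etalon)
    return vipa.thickness_m * (vipa.index * cos_v) / (etalon.index * cos_e)


def _axis_internal_cos(cavity: CavitySpec) -> float:
    theta_ext = math.hypot(cavity.tilt_y_rad, cavity.tilt_x_rad)
    sin_int = math.sin(theta_ext) / cavity.index
    return math.sqrt(1.0 - sin_int * sin_int)


def peak_transmission_nonuniform(
    reflectance: float,
    thickness_m: float,
    index: float,
    wavelength_m: float,
    sigma_m: float,
    num_samples: int = 81,
) -> float:
    """Resonance-peak transmission of a thickness-averaged cavity.

    Gauss-Hermite average of the Airy function over phase offsets
    ``4 pi n (d - d0) / lambda`` with d ~ Normal(d0, sigma), evaluated at the
    nominal resonance (the symmetric average peaks there).  Equals 1 for
    sigma = 0 and decreases monotonically with sigma.
    """
    if not 0.0 <= reflectance < 1.0:
        raise ValueError("reflectance must lie in [0, 1)")
    if sigma_m < 0:
        raise ValueError("sigma_m must be >= 0")
    if sigma_m == 0.0:
        return 1.0
    r = reflectance
    sigma_phi = 4.0 * math.pi * index * sigma_m / wavelength_m
    nodes, w = hermite_e.hermegauss(num_samples)
    weights = w / w.sum()
    phases = sigma_phi * nodes
    t = (1.0 - r) ** 2 / (1.0 + r * r - 2.0 * r * np.cos(phases))
    return float(np.sum(weights * t))
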