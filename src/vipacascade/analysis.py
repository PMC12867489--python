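"""Extinction, contrast-enhancement and throughput trade-off analysis.

The figure of merit of a Brillouin spectrometer stage is its spectral
contrast: the ratio (in dB) between the transmission at an order peak and
the background between orders, which determines whether weak Stokes /
anti-Stokes peaks survive the elastic (Rayleigh) tails.  This module turns
rendered (or measured) sensor images into extinction curves over one central
FSR, quantifies the contrast enhancement contributed by cascaded etalon
stages, measures instrument-response FWHMs, scans cascade misalignments, and
maps the peak-transmission / contrast-enhancement trade-off of multi-stage
cascades with realistic thickness nonuniformity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .optics import (
    CavitySpec,
    OpticalGeometry,
    peak_transmission_nonuniform,
    pixel_to_internal_cos,
)
from .pipeline import (
    BrillouinFitResult,
    DispersionCalibration,
    calibrate_dispersion,
    detect_orders,
    extract_spectrum,
    fit_brillouin,
    _dispersion_profile,
)
from .sources import SensorImage, SourceSpec, SpectralLine, render_image

__all__ = [
    "ExtinctionCurve",
    "EnhancementCurve",
    "TradeoffPoint",
    "MisalignmentResult",
    "calibrate_image",
    "extinction_curve",
    "contrast_db",
    "enhancement_curve",
    "central_window",
    "fwhm_ghz",
    "misalignment_scan",
    "compensating_y_tilt",
    "solve_stage_reflectance",
    "tradeoff_curve",
]


# ---------------------------------------------------------------------------
# extinction curves
# ---------------------------------------------------------------------------


@dataclass
class ExtinctionCurve:
    """Intensity relative to the order-peak maximum (dB <= 0) over one FSR."""

    freq_ghz: np.ndarray
    level_db: np.ndarray

    def __post_init__(self) -> None:
        self.freq_ghz = np.asarray(self.freq_ghz, dtype=float)
        self.level_db = np.asarray(self.level_db, dtype=float)
        if self.freq_ghz.shape != self.level_db.shape:
            raise ValueError("grids must match")
        if np.any(np.diff(self.freq_ghz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if abs(self.level_db.max()) > 1e-9:
            raise ValueError("curve must be normalized to a 0 dB maximum")

    @property
    def span_ghz(self) -> float:
        return float(self.freq_ghz[-1] - self.freq_ghz[0])

    def at(self, freq_ghz):
        return np.interp(freq_ghz, self.freq_ghz, self.level_db)

    def window_mask(self, lo_ghz: float, hi_ghz: float) -> np.ndarray:
        return (self.freq_ghz >= lo_ghz) & (self.freq_ghz <= hi_ghz)


@dataclass
class EnhancementCurve:
    """Per-frequency dB suppression added by a cascade stage."""

    freq_ghz: np.ndarray
    delta_db: np.ndarray

    def at(self, freq_ghz):
        return np.interp(freq_ghz, self.freq_ghz, self.delta_db)

    def window_mean(self, lo_ghz: float, hi_ghz: float) -> float:
        mask = (self.freq_ghz >= lo_ghz) & (self.freq_ghz <= hi_ghz)
        if not mask.any():
            raise ValueError("empty frequency window")
        return float(self.delta_db[mask].mean())


def calibrate_image(
    image: SensorImage,
    fsr_ghz: float,
    column=None,
    column_halfwidth: int = 0,
    min_separation_px: int = 200,
) -> DispersionCalibration:
    """Detect orders in an image and calibrate its dispersion."""
    centers = detect_orders(
        image, min_separation_px=min_separation_px, column=column,
        column_halfwidth=column_halfwidth,
    )
    return calibrate_dispersion(centers, fsr_ghz)


def extinction_curve(
    image: SensorImage,
    calibration: DispersionCalibration,
    column=None,
    column_halfwidth: int = 0,
) -> ExtinctionCurve:
    """Normalized dB profile over the central FSR of an image.

    The dispersion-axis profile at the chosen column is taken between the two
    order centers bracketing the middle of the sensor and normalized to its
    maximum.  Pass the same calibration (e.g. from the reference, VIPA-only
    image) to several images to obtain curves on identical grids.
    """
    profile = _dispersion_profile(image, column, column_halfwidth)
    centers = calibration.order_positions_px
    if len(centers) < 2:
        raise ValueError("calibration must contain at least two orders")
    mid = (len(profile) - 1) / 2.0
    pair_mid = (centers[:-1] + centers[1:]) / 2.0
    k = int(np.argmin(np.abs(pair_mid - mid)))
    lo_px, hi_px = centers[k], centers[k + 1]
    rows = np.arange(int(math.ceil(lo_px)), int(math.floor(hi_px)) + 1)
    seg = profile[rows]
    if seg.max() <= 0:
        raise ValueError("profile is zero over the central FSR")
    freq = calibration.pixel_to_ghz(rows.astype(float))
    freq = freq - calibration.pixel_to_ghz(float(lo_px))
    level = 10.0 * np.log10(np.maximum(seg, 1e-300) / seg.max())
    return ExtinctionCurve(freq, level)


def contrast_db(
    curve: ExtinctionCurve,
    window: tuple[float, float] | None = None,
    mode: str = "min",
) -> float:
    """Spectral contrast: 0 minus the minimum (or mean) level in a window.

    The default peak-to-minimum convention over the central FSR matches the
    closed-form Airy contrast ((1+R)/(1-R))^2 for a single ideal cavity.
    """
    if window is None:
        mask = np.ones(len(curve.freq_ghz), dtype=bool)
    else:
        mask = curve.window_mask(*window)
        if not mask.any():
            raise ValueError("empty frequency window")
    vals = curve.level_db[mask]
    if mode == "min":
        return float(-vals.min())
    if mode == "mean":
        return float(-vals.mean())
    raise ValueError("mode must be 'min' or 'mean'")


def enhancement_curve(
    curve_without: ExtinctionCurve, curve_with: ExtinctionCurve
) -> EnhancementCurve:
    """Per-frequency dB difference (without - with) of two extinction curves.

    The grids must match sample for sample; derive both curves from the same
    dispersion calibration to guarantee this.
    """
    if curve_without.freq_ghz.shape != curve_with.freq_ghz.shape or not np.allclose(
        curve_without.freq_ghz, curve_with.freq_ghz, atol=1e-9
    ):
        raise ValueError("frequency grids do not match; use a shared calibration")
    return EnhancementCurve(
        curve_without.freq_ghz.copy(),
        curve_without.level_db - curve_with.level_db,
    )


def central_window(fsr_ghz: float, fraction: float = 0.1) -> tuple[float, float]:
    """Mid-FSR window: midpoint +/- ``fraction`` of the FSR."""
    return ((0.5 - fraction) * fsr_ghz, (0.5 + fraction) * fsr_ghz)


def fwhm_ghz(freq_ghz, values) -> float:
    """Full width at half maximum of a unimodal sampled peak.

    Half-maximum crossings are located by linear interpolation between
    samples; no profile model is fitted.  Raises when a crossing is missing
    on either side.
    """
    f = np.asarray(freq_ghz, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(f) < 8:
        raise ValueError("need >= 8 samples across the peak")
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = None
    for j in range(i, 0, -1):
        if y[j - 1] < half <= y[j]:
            left = f[j - 1] + (f[j] - f[j - 1]) * (half - y[j - 1]) / (y[j] - y[j - 1])
            break
    right = None
    for j in range(i, len(y) - 1):
        if y[j + 1] < half <= y[j]:
            right = f[j] + (f[j + 1] - f[j]) * (y[j] - half) / (y[j] - y[j + 1])
            break
    if left is None or right is None:
        raise ValueError("no half-maximum crossing on one side of the peak")
    return float(right - left)


# ---------------------------------------------------------------------------
# misalignment scans
# ---------------------------------------------------------------------------


@dataclass
class MisalignmentResult:
    """Throughput and Brillouin-shift metrics of a perturbed cascade."""

    peak_transmission: float
    fit: BrillouinFitResult
    baseline_fit: BrillouinFitResult

    @property
    def shift_ghz(self) -> float:
        return self.fit.shift_ghz

    @property
    def peak_separation_ghz(self) -> float:
        return self.fit.peak_separation_ghz


def _perturb(
    cavities: Sequence[CavitySpec],
    stage: int,
    delta_tilt_y_rad: float,
    delta_tilt_x_rad: float,
    delta_thickness_m: float,
) -> list[CavitySpec]:
    cavs = list(cavities)
    cav = cavs[stage]
    cavs[stage] = cav.replace(
        tilt_y_rad=cav.tilt_y_rad + delta_tilt_y_rad,
        tilt_x_rad=cav.tilt_x_rad + delta_tilt_x_rad,
        thickness_m=cav.thickness_m + delta_thickness_m,
    )
    return cavs


def misalignment_scan(
    cavities: Sequence[CavitySpec],
    geometry: OpticalGeometry,
    source: SourceSpec,
    delta_tilt_y_rad: float = 0.0,
    delta_tilt_x_rad: float = 0.0,
    delta_thickness_m: float = 0.0,
    stage: int = -1,
    column=None,
    initial_shift_ghz: float | None = None,
) -> MisalignmentResult:
    """Render a perturbed cascade and fit its Brillouin spectrum.

    The perturbation is applied to one etalon stage (the last by default).
    The source spectrum should contain the elastic line plus the +/- nu_B
    Brillouin doublet.  Peak transmission is reported relative to the aligned
    baseline; the dispersion calibration of the baseline image is reused for
    the perturbed image so both spectra share one frequency axis.
    """
    if max(abs(delta_tilt_y_rad), abs(delta_tilt_x_rad)) > 10e-3:
        raise ValueError("perturbations must stay below 10 mrad")
    vipa = cavities[0]
    fsr = vipa.fsr_ghz()
    base_img = render_image(source, cavities, geometry)
    cal = calibrate_image(base_img, fsr, column=column)
    base_spec = extract_spectrum(base_img, cal, 1, column=column)
    base_fit = fit_brillouin(base_spec, initial_shift_ghz=initial_shift_ghz)

    pert = _perturb(
        cavities, stage, delta_tilt_y_rad, delta_tilt_x_rad, delta_thickness_m
    )
    pert_img = render_image(source, pert, geometry)
    pert_spec = extract_spectrum(pert_img, cal, 1, column=column)
    pert_fit = fit_brillouin(pert_spec, initial_shift_ghz=initial_shift_ghz)
    peak_t = float(pert_img.intensity.max() / base_img.intensity.max())
    return MisalignmentResult(peak_t, pert_fit, base_fit)


def compensating_y_tilt(
    cavities: Sequence[CavitySpec],
    geometry: OpticalGeometry,
    delta_tilt_x_rad: float = 0.0,
    delta_thickness_m: float = 0.0,
    at_offset_ghz: float = 0.0,
    stage: int = -1,
    bracket_rad: float = 2e-3,
) -> float:
    """y-tilt adjustment restoring etalon/VIPA fringe overlap at one offset.

    An x-tilt or thickness mismatch detunes the etalon's resonances from the
    VIPA's; a small y-tilt readjustment can cancel the detuning, but only at
    one chosen frequency offset (e.g. one Brillouin peak) -- the residual
    linear mismatch is what changes the apparent peak separation.

    Returns the ``delta_tilt_y_rad`` that zeroes the phase mismatch at the
    sensor position of ``at_offset_ghz`` relative to the central order.
    """
    vipa = cavities[0]
    stage_idx = stage % len(cavities)
    fsr = vipa.fsr_ghz()
    # locate the sensor row of the target offset from an elastic-only render
    probe = SourceSpec.point(
        geometry.pixel_pitch_m * 20.0, (SpectralLine(0.0, 1.0),)
    )
    img = render_image(probe, [vipa], geometry)
    cal = calibrate_image(img, fsr)
    centers = cal.order_positions_px
    mid_center = centers[np.argmin(np.abs(centers - (img.shape[0] - 1) / 2.0))]
    target_freq = cal.pixel_to_ghz(float(mid_center)) + at_offset_ghz
    row = float(cal.ghz_to_pixel(target_freq))
    col = geometry.axis[1]

    def mismatch(dty: float) -> float:
        pert = _perturb(
            cavities, stage_idx, dty, delta_tilt_x_rad, delta_thickness_m
        )[stage_idx]
        aligned = cavities[stage_idx]
        lam = geometry.wavelength_m
        phi_p = (
            4.0 * np.pi * pert.index * pert.thickness_m
            * pixel_to_internal_cos((row, col), geometry, pert) / lam
        )
        phi_a = (
            4.0 * np.pi * aligned.index * aligned.thickness_m
            * pixel_to_internal_cos((row, col), geometry, aligned) / lam
        )
        return float(phi_p - phi_a)

    return float(optimize.brentq(mismatch, -bracket_rad, bracket_rad))


# ---------------------------------------------------------------------------
# multi-stage trade-off
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TradeoffPoint:
    """One point of the peak-transmission vs contrast-enhancement trade-off."""

    n_stages: int
    stage_reflectance: float
    enhancement_db: float
    peak_transmission: float
    attainable: bool = True


def solve_stage_reflectance(enhancement_db: float, n_stages: int) -> float:
    """Per-stage mirror reflectance reaching a target mid-FSR enhancement.

    Each aligned stage suppresses the mid-FSR background by its Airy contrast
    10 log10(1 + F) dB with coefficient of finesse F = 4R/(1-R)^2; stages
    multiply, so dB adds.  Inverting for equal stages gives
    F = 10^(E / 10 k) - 1 and the quadratic F R^2 - (2F + 4) R + F = 0.
    """
    if enhancement_db < 0:
        raise ValueError("enhancement must be >= 0")
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    f_coeff = 10.0 ** (enhancement_db / (10.0 * n_stages)) - 1.0
    if f_coeff == 0.0:
        return 0.0
    b = 2.0 * f_coeff + 4.0
    disc = b * b - 4.0 * f_coeff * f_coeff
    return (b - math.sqrt(disc)) / (2.0 * f_coeff)


def tradeoff_curve(
    n_stages: int,
    target_enhancements_db: Sequence[float],
    sigma_m: float,
    thickness_m: float = 3.37e-3,
    index: float = 1.45,
    wavelength_m: float = 785e-9,
    max_reflectance: float = 0.9999,
) -> list[TradeoffPoint]:
    """Peak transmission vs target contrast enhancement for a k-stage cascade.

    For each target the equal per-stage reflectance is solved in closed form,
    then the cascade peak transmission is the product of per-stage
    thickness-averaged resonance peaks at nonuniformity ``sigma_m``.  Targets
    requiring a reflectance above ``max_reflectance`` are flagged
    unattainable.  At equal total enhancement, more (lower-finesse) stages
    never transmit less: broader per-stage resonances are less sensitive to
    the same thickness defects.
    """
    if n_stages not in (1, 2, 3):
        raise ValueError("n_stages must be 1, 2 or 3")
    points = []
    for target in target_enhancements_db:
        r = solve_stage_reflectance(target, n_stages)
        if r > max_reflectance:
            points.append(TradeoffPoint(n_stages, r, float(target), 0.0, False))
            continue
        t_stage = peak_transmission_nonuniform(
            r, thickness_m, index, wavelength_m, sigma_m
        )
        points.append(
            TradeoffPoint(n_stages, r, float(target), t_stage**n_stages, True)
        )
    return points
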