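"""Spectrum extraction and Brillouin fitting.

The analysis chain for VIPA spectrometer images:

1. detect the interference-order peaks along the dispersion axis;
2. calibrate the pixel -> frequency dispersion from the observed order
   spacing and the known free spectral range;
3. optionally merge an exposure series into a high-dynamic-range radiance
   image (the camera's ~12-bit range cannot span a 60+ dB extinction curve);
4. extract a spectrum over one FSR, averaging one to three orders;
5. fit a linear combination of Lorentzians -- one elastic peak centered near
   zero plus a Stokes / anti-Stokes Brillouin doublet with shared shift and
   linewidth -- to obtain the Brillouin shift;
6. summarize repeated fits into a precision (std of shifts) and an SNR
   (mean / std of the fitted Brillouin amplitude).

The fit is organised as a model object, ``BrillouinSpectrumModel``, whose
``fit()`` returns a ``BrillouinFitResult`` carrying estimates, standard
errors and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, signal
from scipy.interpolate import PchipInterpolator

from .sources import SensorImage

__all__ = [
    "DispersionCalibration",
    "Spectrum",
    "BrillouinSpectrumModel",
    "BrillouinFitResult",
    "detect_orders",
    "calibrate_dispersion",
    "hdr_merge",
    "extract_spectrum",
    "fit_brillouin",
    "precision_and_snr",
]


# ---------------------------------------------------------------------------
# order detection and dispersion calibration
# ---------------------------------------------------------------------------


def _dispersion_profile(image, column=None, column_halfwidth: int = 0) -> np.ndarray:
    """1-D profile along the dispersion (row) axis at a sensor column."""
    if isinstance(image, SensorImage):
        arr = image.intensity
    else:
        arr = np.asarray(image, dtype=float)
    if arr.ndim == 1:
        return arr
    if column is None:
        column = (arr.shape[1] - 1) // 2
    column = int(round(column))
    lo = max(0, column - column_halfwidth)
    hi = min(arr.shape[1], column + column_halfwidth + 1)
    return arr[:, lo:hi].mean(axis=1)


def detect_orders(
    image,
    min_separation_px: int = 200,
    column=None,
    column_halfwidth: int = 0,
) -> np.ndarray:
    """Sub-pixel interference-order centers along the dispersion axis.

    Peaks above half the global maximum and separated by at least
    ``min_separation_px`` are located with :func:`scipy.signal.find_peaks`;
    each is refined to the intensity-weighted centroid of its contiguous
    samples above half the peak height.  Raises if fewer than two orders are
    found (dispersion calibration impossible).
    """
    profile = _dispersion_profile(image, column, column_halfwidth)
    if profile.max() <= 0:
        raise ValueError("profile is empty; cannot detect orders")
    peaks, _ = signal.find_peaks(
        profile, height=0.5 * profile.max(), distance=max(1, int(min_separation_px))
    )
    # peaks sharing one contiguous above-half-max region (e.g. a noisy
    # saturated plateau) belong to the same order: merge before centroiding
    regions: list[tuple[int, int]] = []
    for p in peaks:
        half = 0.5 * profile[p]
        lo = p
        while lo > 0 and profile[lo - 1] >= half:
            lo -= 1
        hi = p
        while hi < len(profile) - 1 and profile[hi + 1] >= half:
            hi += 1
        if regions and lo <= regions[-1][1] + min_separation_px:
            regions[-1] = (regions[-1][0], max(hi, regions[-1][1]))
        else:
            regions.append((lo, hi))
    centers = []
    for lo, hi in regions:
        idx = np.arange(lo, hi + 1)
        # background-subtracted weights: removes the bias from the hard
        # truncation at the half-maximum boundary
        w = profile[idx] - 0.5 * profile[idx].max()
        w = np.clip(w, 0.0, None)
        centers.append(float(np.sum(idx * w) / np.sum(w)))
    centers = np.sort(np.asarray(centers))
    if len(centers) < 2:
        raise ValueError(
            f"found {len(centers)} order peak(s); >= 2 required for calibration"
        )
    return centers


@dataclass
class DispersionCalibration:
    """Monotone pixel -> frequency mapping anchored at the order centers.

    Consecutive order centers map to exactly one FSR apart by construction;
    frequencies are relative (first detected order = 0 GHz), increasing with
    row index.
    """

    order_positions_px: np.ndarray
    fsr_ghz: float
    _forward: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.order_positions_px, dtype=float)
        if len(pos) < 2:
            raise ValueError("calibration requires >= 2 orders")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("order positions must be strictly increasing")
        self.order_positions_px = pos

    def pixel_to_ghz(self, pixel):
        out = self._forward(np.asarray(pixel, dtype=float))
        return float(out) if np.ndim(pixel) == 0 else np.asarray(out)

    def ghz_to_pixel(self, freq_ghz):
        lo = self.order_positions_px[0] - 0.5 * np.diff(self.order_positions_px)[0]
        hi = self.order_positions_px[-1] + 0.5 * np.diff(self.order_positions_px)[-1]
        grid = np.linspace(lo, hi, 20001)
        f = self.pixel_to_ghz(grid)
        out = np.interp(np.asarray(freq_ghz, dtype=float), f, grid)
        return float(out) if np.ndim(freq_ghz) == 0 else np.asarray(out)


def calibrate_dispersion(
    order_positions_px: Sequence[float], fsr_ghz: float
) -> DispersionCalibration:
    """Fit a smooth monotone pixel -> frequency map through the order centers.

    Order ``k`` maps to ``k * fsr_ghz``.  Two orders give a linear map, three
    an exact quadratic; with four or more a monotone piecewise-cubic (PCHIP)
    interpolant through the centers is used so that the one-FSR-per-order
    constraint holds exactly at every center.
    """
    pos = np.asarray(order_positions_px, dtype=float)
    if len(pos) < 2:
        raise ValueError("calibration requires >= 2 orders")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("order positions must be strictly increasing and distinct")
    if not fsr_ghz > 0:
        raise ValueError("fsr_ghz must be positive")
    freqs = np.arange(len(pos)) * fsr_ghz
    if len(pos) <= 3:
        coeffs = np.polyfit(pos, freqs, deg=len(pos) - 1)
        forward = lambda p: np.polyval(coeffs, p)  # noqa: E731
    else:
        interp = PchipInterpolator(pos, freqs, extrapolate=True)
        forward = interp
    return DispersionCalibration(pos, float(fsr_ghz), forward)


# ---------------------------------------------------------------------------
# HDR merging
# ---------------------------------------------------------------------------


def hdr_merge(
    images: Sequence[SensorImage], saturation_fraction: float = 0.9
) -> tuple[SensorImage, np.ndarray]:
    """Merge an exposure series into a radiance image.

    Per pixel, radiance (intensity per unit exposure) is estimated over every
    frame in which the pixel is below ``saturation_fraction`` of the frame's
    saturation level (guarding against near-full-well nonlinearity), using
    the exposure-weighted average  sum(I_i) / sum(e_i)  -- the
    maximum-likelihood combination for photon counting, which also keeps
    quantized low counts from short exposures from biasing the estimate.
    Pixels saturated in every frame are filled from the longest exposure and
    flagged in the returned boolean mask.
    """
    images = list(images)
    if not images:
        raise ValueError("hdr_merge requires at least one image")
    shape = images[0].shape
    for im in images:
        if im.shape != shape:
            raise ValueError("all images must share the same sensor shape")
        if im.exposure_s is None or not im.exposure_s > 0:
            raise ValueError("every image needs positive exposure metadata")
    num = np.zeros(shape)
    den = np.zeros(shape)
    for im in images:
        ok = im.intensity < saturation_fraction * im.saturation_level
        num += np.where(ok, im.intensity, 0.0)
        den += ok * im.exposure_s
    merged = np.divide(num, den, out=np.zeros(shape), where=den > 0)
    fully_saturated = den == 0
    if fully_saturated.any():
        longest = max(images, key=lambda im: im.exposure_s)
        merged[fully_saturated] = (
            longest.intensity[fully_saturated] / longest.exposure_s
        )
    return SensorImage(merged, exposure_s=1.0), fully_saturated


# ---------------------------------------------------------------------------
# spectrum extraction
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """Sampled spectrum: frequency offsets about an order center (GHz).

    ``saturated`` flags samples whose sensor pixels were at (or near) the
    camera's saturation level; fits exclude them.
    """

    freq_ghz: np.ndarray
    intensity: np.ndarray
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freq_ghz = np.asarray(self.freq_ghz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.freq_ghz.shape != self.intensity.shape:
            raise ValueError("freq and intensity must have the same shape")
        if self.saturated is not None:
            self.saturated = np.asarray(self.saturated, dtype=bool)
            if self.saturated.shape != self.freq_ghz.shape:
                raise ValueError("saturated mask must match the grid")


def extract_spectrum(
    image: SensorImage,
    calibration: DispersionCalibration,
    orders_to_combine: int = 1,
    column=None,
    column_halfwidth: int = 0,
    num_points: int | None = None,
) -> Spectrum:
    """Spectrum over one FSR, averaged over one to three central orders.

    Each requested order's dispersion-axis profile is expressed as signed
    frequency offsets about that order's center, resampled by linear
    interpolation onto a common grid spanning (-FSR/2, FSR/2), and the
    per-order spectra are arithmetically averaged.
    """
    if orders_to_combine not in (1, 2, 3):
        raise ValueError("orders_to_combine must be 1, 2 or 3")
    centers = calibration.order_positions_px
    if orders_to_combine > len(centers):
        raise ValueError(
            f"requested {orders_to_combine} orders but only {len(centers)} detected"
        )
    profile = _dispersion_profile(image, column, column_halfwidth)
    sat_level = (
        image.saturation_level if isinstance(image, SensorImage) else np.inf
    )
    sat_profile = (
        _dispersion_profile(
            np.asarray(
                image.intensity >= 0.9 * sat_level, dtype=float
            ),
            column,
            column_halfwidth,
        )
        if np.isfinite(sat_level)
        else np.zeros_like(profile)
    )
    rows = np.arange(len(profile), dtype=float)
    freqs = calibration.pixel_to_ghz(rows)
    fsr = calibration.fsr_ghz
    # the orders closest to the middle of the sensor
    mid = (len(profile) - 1) / 2.0
    chosen = np.argsort(np.abs(centers - mid))[:orders_to_combine]
    if num_points is None:
        px_per_fsr = np.median(np.diff(centers)) if len(centers) > 1 else len(profile)
        num_points = max(64, int(px_per_fsr))
    grid = np.linspace(-fsr / 2.0, fsr / 2.0, num_points)
    acc = np.zeros(num_points)
    sat = np.zeros(num_points)
    for k in chosen:
        center_freq = calibration.pixel_to_ghz(centers[k])
        offsets = freqs - center_freq
        mask = (offsets >= -fsr / 2.0) & (offsets <= fsr / 2.0)
        if mask.sum() < 8:
            raise ValueError("order does not span a usable frequency range")
        acc += np.interp(grid, offsets[mask], profile[mask])
        sat += np.interp(grid, offsets[mask], sat_profile[mask])
    return Spectrum(grid, acc / len(chosen), saturated=sat > 1e-6)


# ---------------------------------------------------------------------------
# double-Lorentzian Brillouin fit
# ---------------------------------------------------------------------------


def _lorentzian(freq, center, fwhm):
    """Unit-peak Lorentzian."""
    hw = fwhm / 2.0
    return hw * hw / ((freq - center) ** 2 + hw * hw)


@dataclass
class BrillouinFitResult:
    """Converged parameters of the elastic + Brillouin-doublet fit."""

    shift_ghz: float
    fwhm_ghz: float
    amp_brillouin: float
    amp_stokes: float
    amp_antistokes: float
    amp_elastic: float
    elastic_center_ghz: float
    elastic_fwhm_ghz: float
    baseline: float
    residual_rms: float
    success: bool
    message: str
    params: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)
    n_points: int = 0

    @property
    def peak_separation_ghz(self) -> float:
        """Fitted Stokes / anti-Stokes separation (= 2 x shift)."""
        return 2.0 * self.shift_ghz

    def predict(self, freq_ghz) -> np.ndarray:
        p = self.params
        f = np.asarray(freq_ghz, dtype=float)
        return (
            p["baseline"]
            + p["amp_elastic"] * _lorentzian(f, p["elastic_center_ghz"], p["elastic_fwhm_ghz"])
            + p["amp_stokes"]
            * _lorentzian(f, p["elastic_center_ghz"] - p["shift_ghz"], p["fwhm_ghz"])
            + p["amp_antistokes"]
            * _lorentzian(f, p["elastic_center_ghz"] + p["shift_ghz"], p["fwhm_ghz"])
        )

    def summary(self) -> str:
        lines = [
            "Brillouin double-Lorentzian fit",
            "=" * 46,
            f"{'n points':<22}{self.n_points:>12d}",
            f"{'converged':<22}{str(self.success):>12}",
            f"{'residual rms':<22}{self.residual_rms:>12.4g}",
            "-" * 46,
            f"{'parameter':<22}{'estimate':>12}{'std err':>12}",
            "-" * 46,
        ]
        for key in (
            "shift_ghz",
            "fwhm_ghz",
            "amp_stokes",
            "amp_antistokes",
            "amp_elastic",
            "elastic_center_ghz",
            "elastic_fwhm_ghz",
            "baseline",
        ):
            se = self.stderr.get(key, float("nan"))
            lines.append(f"{key:<22}{self.params.get(key, float('nan')):>12.5g}{se:>12.2g}")
        lines.append("=" * 46)
        return "\n".join(lines)


class BrillouinSpectrumModel:
    """Elastic + Brillouin-doublet model for one extracted spectrum.

    The model is a baseline plus three Lorentzians: an elastic (Rayleigh)
    peak centered near zero, and the Stokes / anti-Stokes pair at
    ``elastic_center -/+ shift`` sharing one shift and one linewidth::

        I(nu) = b + A_e L(nu; nu_e, G_e) + A_s L(nu; nu_e - nu_B, G)
                  + A_a L(nu; nu_e + nu_B, G)

    ``fit()`` performs bounded nonlinear least squares and returns a
    :class:`BrillouinFitResult`.
    """

    _PARAM_NAMES = (
        "baseline",
        "amp_elastic",
        "elastic_center_ghz",
        "elastic_fwhm_ghz",
        "amp_stokes",
        "amp_antistokes",
        "shift_ghz",
        "fwhm_ghz",
    )

    def __init__(self, freq_ghz, intensity, exclude=None):
        freq = np.asarray(freq_ghz, dtype=float)
        inten = np.asarray(intensity, dtype=float)
        if freq.ndim != 1 or freq.shape != inten.shape:
            raise ValueError("freq_ghz and intensity must be matching 1-D arrays")
        if exclude is not None:
            keep = ~np.asarray(exclude, dtype=bool)
            freq, inten = freq[keep], inten[keep]
        if len(freq) < 16:
            raise ValueError("spectrum too short to fit")
        if not (np.all(np.isfinite(freq)) and np.all(np.isfinite(inten))):
            raise ValueError("spectrum contains non-finite values")
        order = np.argsort(freq)
        self.freq = freq[order]
        self.intensity = inten[order]

    @classmethod
    def from_spectrum(cls, spectrum: Spectrum) -> "BrillouinSpectrumModel":
        """Build from an extracted spectrum, excluding saturated samples."""
        return cls(spectrum.freq_ghz, spectrum.intensity, exclude=spectrum.saturated)

    # -- initial guesses ---------------------------------------------------

    def _initial(self, initial_shift_ghz, elastic_bound):
        f, y = self.freq, self.intensity
        scale = y.max()
        elastic_mask = np.abs(f) <= elastic_bound
        if elastic_mask.any():
            i_e = np.argmax(np.where(elastic_mask, y, -np.inf))
        else:
            i_e = np.argmin(np.abs(f))
        nu_e = float(np.clip(f[i_e], -elastic_bound, elastic_bound))
        a_e = float(y[i_e])
        g_e = self._halfwidth_guess(i_e)
        if initial_shift_ghz is None:
            side = np.abs(f - nu_e) > max(1.0, 2.0 * g_e)
            if not side.any():
                raise ValueError("no samples beyond the elastic region")
            i_b = np.argmax(np.where(side, y, -np.inf))
            shift0 = abs(float(f[i_b]) - nu_e)
            g_b = self._halfwidth_guess(i_b)
        else:
            shift0 = float(initial_shift_ghz)
            i_b = np.argmin(np.abs(f - (nu_e + shift0)))
            g_b = self._halfwidth_guess(i_b)
        a_s = float(np.interp(nu_e - shift0, f, y))
        a_a = float(np.interp(nu_e + shift0, f, y))
        return (
            np.array([0.0, a_e, nu_e, g_e, max(a_s, 1e-6 * scale),
                      max(a_a, 1e-6 * scale), shift0, g_b]),
            scale,
        )

    def _halfwidth_guess(self, i_peak) -> float:
        f, y = self.freq, self.intensity
        half = y[i_peak] / 2.0
        lo = i_peak
        while lo > 0 and y[lo - 1] >= half:
            lo -= 1
        hi = i_peak
        while hi < len(y) - 1 and y[hi + 1] >= half:
            hi += 1
        width = abs(f[min(hi, len(f) - 1)] - f[max(lo, 0)])
        return max(width, 2.0 * np.median(np.diff(f)))

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        initial_shift_ghz: float | None = None,
        elastic_center_bound_ghz: float = 1.0,
        max_nfev: int = 2000,
    ) -> BrillouinFitResult:
        f, y = self.freq, self.intensity
        span = f.max() - f.min()
        p0, scale = self._initial(initial_shift_ghz, elastic_center_bound_ghz)
        yn = y / scale
        p0 = p0.copy()
        p0[[1, 4, 5]] /= scale
        step = float(np.median(np.diff(f)))
        # the elastic core may be excluded (saturation); its true amplitude can
        # exceed the largest remaining sample by orders of magnitude
        amp_cap = 1e7
        lower = np.array(
            [-0.5, 0.0, -elastic_center_bound_ghz, step, 0.0, 0.0, 2 * step, step]
        )
        upper = np.array(
            [0.5, amp_cap, elastic_center_bound_ghz, span, amp_cap, amp_cap, span, span]
        )
        p0 = np.clip(p0, lower + 1e-12, upper - 1e-12)

        def model(freq, b, a_e, nu_e, g_e, a_s, a_a, nu_b, g):
            return (
                b
                + a_e * _lorentzian(freq, nu_e, g_e)
                + a_s * _lorentzian(freq, nu_e - nu_b, g)
                + a_a * _lorentzian(freq, nu_e + nu_b, g)
            )

        try:
            popt, pcov = optimize.curve_fit(
                model, f, yn, p0=p0, bounds=(lower, upper), max_nfev=max_nfev
            )
            success, message = True, "converged"
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            return self._failure(str(exc))
        resid = yn - model(f, *popt)
        perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
        # restore intensity scale on the amplitude-like parameters
        for i in (0, 1, 4, 5):
            popt[i] *= scale
            perr[i] *= scale
        params = dict(zip(self._PARAM_NAMES, (float(v) for v in popt)))
        stderr = dict(zip(self._PARAM_NAMES, (float(v) for v in perr)))
        return BrillouinFitResult(
            shift_ghz=params["shift_ghz"],
            fwhm_ghz=params["fwhm_ghz"],
            amp_brillouin=0.5 * (params["amp_stokes"] + params["amp_antistokes"]),
            amp_stokes=params["amp_stokes"],
            amp_antistokes=params["amp_antistokes"],
            amp_elastic=params["amp_elastic"],
            elastic_center_ghz=params["elastic_center_ghz"],
            elastic_fwhm_ghz=params["elastic_fwhm_ghz"],
            baseline=params["baseline"],
            residual_rms=float(np.sqrt(np.mean(resid**2)) * scale),
            success=success,
            message=message,
            params=params,
            stderr=stderr,
            n_points=len(f),
        )

    def _failure(self, message: str) -> BrillouinFitResult:
        nan = float("nan")
        return BrillouinFitResult(
            shift_ghz=nan,
            fwhm_ghz=nan,
            amp_brillouin=nan,
            amp_stokes=nan,
            amp_antistokes=nan,
            amp_elastic=nan,
            elastic_center_ghz=nan,
            elastic_fwhm_ghz=nan,
            baseline=nan,
            residual_rms=nan,
            success=False,
            message=message,
            params={},
            stderr={},
            n_points=len(self.freq),
        )


def fit_brillouin(
    spectrum: Spectrum, initial_shift_ghz: float | None = None, **kwargs
) -> BrillouinFitResult:
    """Functional wrapper over :class:`BrillouinSpectrumModel`."""
    return BrillouinSpectrumModel.from_spectrum(spectrum).fit(
        initial_shift_ghz=initial_shift_ghz, **kwargs
    )


def precision_and_snr(fits: Sequence[BrillouinFitResult]) -> tuple[float, float]:
    """Precision and SNR over repeated acquisitions.

    Precision is the sample standard deviation of the fitted shifts; SNR is
    the mean fitted Brillouin amplitude over its standard deviation.  A
    zero-variance amplitude series yields an infinite SNR with a warning.
    """
    fits = [f for f in fits]
    if len(fits) < 3:
        raise ValueError("need >= 3 repeated fits")
    shifts = np.array([f.shift_ghz for f in fits])
    amps = np.array([f.amp_brillouin for f in fits])
    precision = float(np.std(shifts, ddof=1))
    amp_std = float(np.std(amps, ddof=1))
    if amp_std == 0.0:
        warnings.warn("identical amplitudes across repeats; SNR is infinite")
        return precision, float("inf")
    return precision, float(np.mean(amps) / amp_std)
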