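"""Synthetic sensor-image stacks with known ground truth.

Generates the acquisition products the analysis pipeline expects --
repeated frames at one exposure, or a multi-exposure series -- from a fully
specified truth: Brillouin shift, intrinsic linewidth, elastic-to-Brillouin
amplitude ratio and camera noise model.  Every generated stack embeds its
``TruthRecord`` so recovery tests compare against the generator's own truth,
never against hard-coded numbers.

Camera model: the ideal render is scaled to expected photoelectron counts by
exposure, then Poisson shot noise, Gaussian read noise, floor quantization to
integer digital numbers, and saturation clipping at the configured bit depth
are applied in that order.  The explicit read-noise term matters: these
spectrometers are typically not shot-noise limited.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .optics import CavitySpec, OpticalGeometry
from .sources import SensorImage, SourceSpec, SpectralLine, render_image

__all__ = [
    "TruthRecord",
    "brillouin_spectrum",
    "synth_brillouin_stack",
    "synth_exposure_series",
    "write_stack",
    "load_stack",
]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth and noise model for one synthetic acquisition.

    Defaults mirror a typical near-infrared Brillouin measurement of a
    transparent reference sample: a 7 GHz shift inside a ~30 GHz FSR, an
    intrinsic linewidth of 0.4 GHz, and an elastic line 30x stronger than
    each Brillouin peak, with the exposure chosen so the elastic peak sits
    just below saturation (fits on saturated elastic cores are unreliable;
    turbid-sample stacks with much larger ratios deliberately saturate and
    are analysed through the saturation mask / HDR path instead).
    ``photon_rate_peak`` is the expected photoelectron rate (counts/s) at the
    brightest pixel of the ideal image.
    """

    shift_ghz: float = 7.0
    fwhm_ghz: float = 0.4
    amplitude_ratio: float = 30.0
    photon_rate_peak: float = 1.2e4
    read_noise_dn: float = 2.0
    bit_depth: int = 12
    poisson: bool = True
    seed: int = 0
    intrinsic_samples: int = 15

    def __post_init__(self) -> None:
        for name in ("shift_ghz", "amplitude_ratio", "photon_rate_peak"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.fwhm_ghz < 0 or self.read_noise_dn < 0:
            raise ValueError("fwhm_ghz and read_noise_dn must be >= 0")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    @property
    def saturation_level(self) -> int:
        return 2**self.bit_depth - 1

    def spectrum(self) -> tuple[SpectralLine, ...]:
        return brillouin_spectrum(
            self.shift_ghz, self.fwhm_ghz, self.amplitude_ratio, self.intrinsic_samples
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(**d)


def brillouin_spectrum(
    shift_ghz: float,
    fwhm_ghz: float,
    amplitude_ratio: float,
    intrinsic_samples: int = 15,
) -> tuple[SpectralLine, ...]:
    """Elastic line plus a Lorentzian-broadened Stokes / anti-Stokes doublet.

    The intrinsic Brillouin line shape is represented by ``intrinsic_samples``
    equally weighted sub-lines placed at Lorentzian quantiles (central 90% of
    the distribution), so each Brillouin side carries unit total amplitude
    while the elastic line carries ``amplitude_ratio``.  ``fwhm_ghz = 0``
    collapses each side to a single monochromatic line.
    """
    lines = [SpectralLine(0.0, amplitude_ratio)]
    if fwhm_ghz == 0.0 or intrinsic_samples == 1:
        offsets = np.array([0.0])
    else:
        u = (np.arange(intrinsic_samples) + 0.5) / intrinsic_samples
        u = 0.05 + 0.9 * u  # central 90% of the Lorentzian CDF
        offsets = (fwhm_ghz / 2.0) * np.tan(np.pi * (u - 0.5))
    w = 1.0 / len(offsets)
    for sign in (-1.0, +1.0):
        for off in offsets:
            lines.append(SpectralLine(sign * shift_ghz + off, w))
    return tuple(lines)


def _noisy_frame(
    ideal_counts: np.ndarray, truth: TruthRecord, rng: np.random.Generator
) -> np.ndarray:
    counts = (
        rng.poisson(ideal_counts).astype(float) if truth.poisson else ideal_counts.copy()
    )
    if truth.read_noise_dn > 0:
        counts = counts + rng.normal(0.0, truth.read_noise_dn, size=counts.shape)
    dn = np.floor(counts)
    return np.clip(dn, 0, truth.saturation_level)


def synth_brillouin_stack(
    cavities: Sequence[CavitySpec],
    geometry: OpticalGeometry,
    source: SourceSpec,
    truth: TruthRecord,
    n_frames: int = 10,
    exposure_s: float = 0.25,
    rng: np.random.Generator | None = None,
) -> tuple[list[SensorImage], TruthRecord]:
    """Repeated noisy frames of the truth spectrum through the cascade.

    The spatial part of ``source`` (point diameter or line length) is kept;
    its spectrum is replaced by the truth spectrum.  Frames differ only by
    noise under the recorded seed sequence; the same truth (seed included)
    reproduces the stack exactly.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not exposure_s > 0:
        raise ValueError("exposure_s must be positive")
    src = source.with_spectrum(truth.spectrum())
    ideal = render_image(src, cavities, geometry).intensity
    ideal_counts = ideal / ideal.max() * truth.photon_rate_peak * exposure_s
    if ideal_counts.min() >= truth.saturation_level:
        raise ValueError("photon scale saturates every pixel; lower the exposure")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    frames = []
    for _ in range(n_frames):
        dn = _noisy_frame(ideal_counts, truth, rng)
        frames.append(
            SensorImage(dn, exposure_s=exposure_s, saturation_level=truth.saturation_level)
        )
    return frames, truth


def synth_exposure_series(
    cavities: Sequence[CavitySpec],
    geometry: OpticalGeometry,
    source: SourceSpec,
    truth: TruthRecord,
    exposures_s: Sequence[float],
    n_frames: int = 1,
) -> dict[float, list[SensorImage]]:
    """One seeded stack per exposure with a consistent underlying radiance."""
    exposures = [float(e) for e in exposures_s]
    if len(set(exposures)) != len(exposures):
        raise ValueError("exposures must be distinct")
    if any(e <= 0 for e in exposures):
        raise ValueError("exposures must be positive")
    seq = np.random.SeedSequence(truth.seed)
    children = seq.spawn(len(exposures))
    stacks: dict[float, list[SensorImage]] = {}
    for exp, child in zip(exposures, children):
        frames, _ = synth_brillouin_stack(
            cavities,
            geometry,
            source,
            truth,
            n_frames=n_frames,
            exposure_s=exp,
            rng=np.random.default_rng(child),
        )
        stacks[exp] = frames
    return stacks


# ---------------------------------------------------------------------------
# on-disk stacks (TIFF frames + JSON truth/exposure sidecar)
# ---------------------------------------------------------------------------


def write_stack(
    directory, frames: Sequence[SensorImage], truth: TruthRecord | None = None
) -> pathlib.Path:
    """Write frames as 16-bit TIFFs plus a JSON sidecar with metadata."""
    import tifffile

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"frames": [], "truth": truth.to_dict() if truth else None}
    for i, frame in enumerate(frames):
        name = f"frame_{i:04d}.tif"
        tifffile.imwrite(
            directory / name, frame.intensity.astype(np.uint16), compression=None
        )
        meta["frames"].append(
            {
                "file": name,
                "exposure_s": frame.exposure_s,
                "saturation_level": float(frame.saturation_level),
            }
        )
    sidecar = directory / "stack.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_stack(directory) -> tuple[list[SensorImage], TruthRecord | None]:
    import tifffile

    directory = pathlib.Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    frames = []
    for entry in meta["frames"]:
        data = tifffile.imread(directory / entry["file"]).astype(float)
        frames.append(
            SensorImage(
                data,
                exposure_s=entry["exposure_s"],
                saturation_level=entry["saturation_level"],
            )
        )
    truth = TruthRecord.from_dict(meta["truth"]) if meta["truth"] else None
    return frames, truth
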