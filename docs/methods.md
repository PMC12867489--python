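# Methods

## Model

Every dispersive element — the VIPA and each cascaded etalon — is modeled as
a lossless plane-parallel Fabry–Pérot cavity. Its intensity transmission at
vacuum wavelength λ and internal refraction angle θ is the Airy function

    T(θ, λ) = (1 − R)² / (1 + R² − 2R cos φ),   φ = 4π n d cos θ / λ,

with plate thickness d, index n and equal-mirror reflectance R. Unequal
mirrors (the VIPA's 100%/92% pair) are reduced to the equal reflectance
√(R₁R₂), which preserves the round-trip amplitude loss and hence the
resonance and anti-resonance extrema. The VIPA is treated as a standard
etalon for its *normalized* transfer function; its near-unity absolute
throughput is asserted, not derived.

**Internal vs external angle.** The phase uses the Snell-corrected internal
angle, `sin θ_int = sin θ_ext / n`, because the round trip folds inside the
medium. The distinction is a sub-ppm phase correction at the ≤2° tilts used,
but it is load-bearing for cascade matching: with it, a +2.44 nm thickness
offset exactly compensates a 0.1° etalon x-tilt on a 3.37 mm plate
(`matched_etalon_thickness` solves d·n·cosθ_int equality, a purely geometric,
wavelength-independent condition). The shipped presets use the rounded
+2.5 nm offset, leaving a ~7 MHz residual detuning — negligible against the
~0.6 GHz instrument linewidth.

**Angle mapping.** Sensor pixels map to field angles at first order:
θ = (offset from optical axis)/f_imaging per axis; cavity tilts add linearly
per axis and the two axes combine in quadrature. This small-angle imaging is
consistent with uniform angular illumination along the dispersion axis.

**Image formation.** The sensor image is the product of two independent
maps: the cascade transfer function (the pixelwise product of per-cavity
Airy maps, one per spectral line at its shifted wavelength λ′ = c/(c/λ + Δν))
and the system response without the cavities — the source re-imaged along x
with magnification f_imaging/f_collimator (Gaussian for a point source, flat
top for a line) and spread uniformly along the dispersion axis y. Images are
sampled pointwise at pixel centers; a validation check requires ≥8 row
pixels per instrument FWHM and the presets provide ≥64.

**Thickness nonuniformity.** Real plates vary in thickness across the
aperture. The averaged response is the mean of ideal maps over
d ~ Normal(d₀, σ): seeded pseudo-random draws (201 by default) or a
deterministic Gauss–Hermite quadrature mode used as the oracle. For R = 94%,
σ = 1.5 nm and λ = 785 nm the resonance peak drops to 0.816; the
trade-off analysis (`tradeoff_curve`) combines this per-stage peak with the
closed-form per-stage suppression 10·log₁₀(1 + 4R/(1−R)²) dB, solved for
equal-reflectance stages — which is why two or three low-finesse etalons
beat one high-finesse etalon at equal total enhancement.

## Misalignment phenomenology

A pure y-tilt mismatch between etalon and VIPA detunes the etalon's fringe
comb almost uniformly across an order (the position-dependent part is ~3% of
the uniform part, independent of the mismatch size). All three peaks —
elastic, Stokes, anti-Stokes — are attenuated and pulled equally, so the
throughput falls while the recovered shift is unchanged. An x-tilt or
thickness mismatch is also a uniform detune; the peak *separation* changes
only in the compensated configuration: a y-tilt readjustment that restores
fringe overlap at one Brillouin peak (`compensating_y_tilt`) leaves a
residual detune that is linear in position, attenuating and pulling the
*other* peak. For the confocal preset, a 5 mrad x-tilt mismatch needs a
~0.6 mrad y-tilt adjustment and changes the apparent separation by
~80 MHz.

## Analysis chain

- **Order detection**: peaks above half the global maximum
  (`scipy.signal.find_peaks`), refined to background-subtracted centroids of
  the contiguous above-half-max region; peaks sharing one region (a noisy
  saturated plateau) are merged first.
- **Dispersion calibration**: order k maps to k·FSR. Two orders give a
  linear map, three an exact quadratic; four or more use a monotone PCHIP
  through the centers so the one-FSR-per-order constraint holds exactly at
  every center (an LSQ quadratic would not).
- **HDR merging**: per pixel, radiance = Σ(counts)/Σ(exposure) over frames
  below 90% of saturation. The exposure-weighted form is the Poisson
  maximum-likelihood combination; a plain average of per-frame radiances
  would let quantized near-zero counts from short exposures bias dim pixels
  by tens of percent. Pixels saturated everywhere are filled from the
  longest exposure and flagged. The 90% threshold guards against
  near-full-well nonlinearity and is configurable.
- **Spectrum extraction**: per-order profiles as signed offsets about each
  order center, linearly resampled onto a common (−FSR/2, FSR/2) grid and
  averaged over 1–3 central orders; samples from saturated pixels are
  flagged and excluded from fits.
- **Brillouin fit**: baseline + three Lorentzians — an elastic peak with
  free center bounded to |ν| < 1 GHz, and a Stokes/anti-Stokes pair at
  center ∓/± ν_B sharing one shift and one linewidth but with independent
  amplitudes (misaligned cascades attenuate the two sides differently).
  Bounded least squares (`scipy.optimize.curve_fit`, trust-region) on the
  max-normalized spectrum; initial values from the largest non-elastic local
  maximum and its half-width. Non-convergence returns a flagged result with
  diagnostics rather than raising. The reported shift is the shared ν_B
  (half the fitted doublet separation).
- **Precision and SNR**: precision is the sample standard deviation of the
  fitted shifts over repeated frames; SNR is the mean fitted Brillouin
  amplitude over its standard deviation (infinite-SNR sentinel with a
  warning for zero variance).

## Synthetic data

The generator renders a truth spectrum — elastic line at 0 plus a
Stokes/anti-Stokes doublet whose intrinsic Lorentzian lineshape is
represented by 15 equally weighted sub-lines at Lorentzian quantiles
(central 90%) — scales it to expected photoelectron counts, then applies
Poisson shot noise, Gaussian read noise (the instrument is not shot-noise
limited, so the explicit read term matters), floor quantization and 12-bit
saturation. Defaults model a transparent reference sample: 7 GHz shift,
0.4 GHz intrinsic width, elastic:Brillouin 30, elastic just under
saturation at 250 ms. Frames differ only by noise under the recorded seed;
identical truth records reproduce stacks bit for bit.

What the generator does *not* emulate: speckle, the objective PSF, slit or
camera pixel diffraction, back-reflection echoes between VIPA and etalon,
laser side modes and drift, and aberration backgrounds. Passing recovery
tests therefore demonstrate the correctness of the analysis chain under the
stated noise model, not performance on raw laboratory images.

## Parameters and problem sizes

- Presets: VIPA 3.3700000 mm / etalon 3.3700025 mm, n = 1.45 (fused
  silica), y-tilt 2°, etalon x-tilt 0.1°, reflectances 100%/92% (VIPA) and
  94% or 75% (etalons); λ = 785 nm confocal (f = 50/200 mm), 532 nm
  line-scan (f = 75/300 mm) with a 110 µm line. FSR ≈ 30.7 GHz.
- The sensor grid is an idealized oversampled detector: 0.15 µm row pitch ×
  20000 rows (≈2.5 FSR, ~70 pixels per fringe FWHM — above the ≥64 target),
  with a coarser column pitch (1–2 µm) because the envelope and fringe
  inclination vary on a ~100 µm scale along x. The point-source diameter
  (5 µm at the source, 20 µm on the sensor) is an arbitrary default; the
  modeled contrast quantities do not depend on it.
- Monte-Carlo sizes: 201 thickness draws for nonuniform averaging (41-node
  Gauss–Hermite for oracles), 50–100 noise realisations for recovery and
  bias studies at 20000×64 pixels per frame — chosen to hold statistical
  error well below the asserted tolerances while keeping the whole suite in
  the minutes range on one CPU.

## Known limitations

- First-order (paraxial) angle mapping; no wave-optics propagation,
  polarization, or intracavity absorption.
- The VIPA's absolute throughput and entrance-window geometry are not
  modeled — only its normalized transfer function.
- Extinction floors are ideal: measured curves include camera artifacts
  (e.g. pixel diffraction) that cap real line-scan enhancement below the
  modeled value.
- Dispersion calibration assumes the frequency axis is smooth between
  orders (quadratic/PCHIP); gross distortions would need a denser reference.
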