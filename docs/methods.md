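# Methods

Models, parameters, and numerical choices behind the `biospeckle`
package, with the known limits of each.

## 1. Speckle field model

### 1.1 Spatial statistics

A fully developed speckle field is a circular complex Gaussian random
field: at each pixel the real and imaginary parts are independent
zero-mean Gaussians, so intensity I = |E|² is exponentially
distributed (contrast 1). The generator produces such a field by
sampling independent complex Gaussian coefficients on a circular
low-pass support in the spatial-frequency plane and inverse-FFTing.
Only the in-support coefficients are drawn (the spectrum is sparse),
and the field is normalized to unit mean intensity per realization.

The support radius sets the speckle size. We define speckle size as
the FWHM of the intensity autocovariance. For a circular pupil of
cutoff ρ_c (cycles/pixel), the field autocorrelation is the Airy-type
kernel 2J₁(x)/x with x = 2πρ_c·r, and the intensity autocovariance is
its square, so the FWHM condition is 2J₁(x)/x = 2^(−1/2). The root
x_half ≈ 1.61633 is found once with `scipy.optimize.brentq` on
`scipy.special.j1`; the cutoff for a requested size S pixels is
ρ_c = x_half/(π·S). A validation test confirms the realized
autocovariance FWHM matches the request within 15% for S between 3 and
10 pixels (the bias comes from finite grids and radial binning).

### 1.2 Optical geometry

Objective (free-space) speckle size is λD/a: wavelength λ = 635 nm,
propagation distance D = 167 mm, illuminated spot width a = 2.45 mm,
giving 43.3 μm, or 8.32 pixels at the 5.2 μm detector pitch — the
speckle grain is comfortably oversampled. All four numbers are
configuration fields of `OpticalGeometry` with these defaults.

### 1.3 Temporal dynamics

Frame-to-frame evolution uses first-order autoregressive mixing of the
complex field:

E_{k+1} = ρ·E_k + √(1−ρ²)·F_{k+1},

with F fresh independent speckle of the same spatial statistics. This
keeps every frame exactly fully developed, gives field correlation ρᵏ
at lag k, and — by the Siegert relation for Gaussian fields —
intensity correlation ρ²ᵏ. The centered normalized frame correlation r
therefore has expectation ρ²ᵏ and the noise-free Biospeckle Activity
is analytic:

BA(k) = 1 − ρ²ᵏ.

This closed form is the package's main internal oracle: acceptance
tests verify the full simulate→correlate chain against it to
Monte-Carlo precision. A further exactness we exploit: temporal
subsampling of an AR(1) sequence (every m-th frame) is the same
process with per-step correlation ρᵐ, which makes cheap,
statistically exact calibration runs possible (§5).

**Realism limits.** Real leaf speckle is not a single-ρ AR(1) process:
activity is spatially heterogeneous (veins vs lamina), non-stationary
over the 20 s record, and its correlation decay need not be
exponential in lag. The model also has no static (specular or
surface) component, so measured BA curves saturate at the Siegert
plateau instead of the partially-developed plateaus of real tissue.
The AR(1) field model was chosen because it is the simplest process
with (a) exact fully-developed marginals at every frame and (b) a
closed-form BA curve to test against; it reproduces the shape —
fast early rise, stable plateau — of measured leaf BA curves, not
their microscopic mechanism.

## 2. Camera model

Intensity (unit mean) is scaled to a target mean gray level — default
one quarter of full scale, 64 on the default 8-bit camera — then
Gaussian readout noise is added and the result is clipped to
[0, 2^bits − 1] and rounded to integers. Readout noise is specified in
electrons (default 25 e⁻ RMS) and converted to gray levels by a
full-well scale factor (default 50 e⁻/gray), i.e. σ ≈ 0.5 gray.
Quantization adds ~1/12 gray² of variance, which the constant-field
test accounts for. With the mean at quarter scale, the exponential
intensity tail clips at 4× the mean (about 1.8% of pixels) — the same
mild saturation a real exposure-controlled camera shows on speckle.

Dark frames (for the noise floor, §4) are readout noise around a small
fixed offset (default 10 gray), quantized the same way.

## 3. Biospeckle Activity

For frames A (reference, frame 0) and B (frame k),

r = Σ(A−Ā)(B−B̄) / √(Σ(A−Ā)² · Σ(B−B̄)²),  BA = 1 − r ∈ [0, 2].

The implementation vectorizes the double sum over pixels in float64; a
literal loop transcription is kept in the test suite as an oracle and
the two agree to 1e-12 relative error. Frames with zero variance (a
correlation with an undefined denominator) raise `DegenerateFrameError`
naming the frame index rather than returning NaN.

Curve summaries: the *early window* is the mean BA over lags with
t ≤ 5 s (the steep, condition-discriminating part), the *plateau* the
mean over the final 5 s. The early-window mean (rather than a single
endpoint) was chosen to reduce per-lag noise; both windows raise
`WindowError` if the record is too short to contain them.

Speckle size is estimated from a single frame as the FWHM of the
radially-averaged intensity autocovariance (FFT-based), with the
background level taken as the median of the outer half of the radial
profile and sub-bin interpolation at the half-maximum crossing.

## 4. Study protocol and statistics

The exposure protocol is 10 min blank, then a 20 s recording at
15 fps, then 1 min of sound, repeated 5 times per cycle for 3 cycles:
15 records per plant per condition, 6 plants per condition by default.

- **Replicate unit.** The 15 within-plant records are averaged into one
  curve per (plant, condition, age); SEM and significance tests use
  the plant as the replicate (n = 6), not the 90 records — within-plant
  records share physiology and are not independent.
- **Normalization.** Early-window BA of each condition is divided by
  the same plant's control value; the reported value is the mean ratio
  across plants with its SEM.
- **Significance.** Two-sided two-sample Student t-test on the raw
  early-window values (pooled variance by default, Welch optional) via
  `scipy.stats.ttest_ind`. With fewer than 2 plants per group the test
  is undefined and is reported as absent rather than fabricated.
- **Phantom noise floor.** An inanimate diffuser (ρ = 1: static field,
  camera noise only) must produce BA indistinguishable from
  measurement noise. The floor is estimated by bootstrap: dark-frame
  residuals (after removing the per-pixel fixed pattern) are resampled
  onto the phantom's temporal-mean frame and re-quantized, giving
  noise-only surrogate sequences with the same dithering behaviour the
  camera applies at fractional gray levels. The threshold is the
  mean + 3 sd of the *per-sequence maximum* BA over 200 surrogates,
  and the verdict compares the maximum of the replicate-averaged
  phantom curve against it. Using the max-distribution (rather than
  mean + 3 sd of single-lag BA) matters: the maximum over ~300 lags of
  a noise-only curve exceeds a single-lag 3σ bound almost surely, so a
  single-lag threshold would flag every correctly-behaving phantom.
  Re-quantization matters too: without it the surrogates miss the
  quantization dither that dominates at these amplitudes (BA ~ 1e-4).

### Condition calibration

The generator maps experimental conditions to ρ through the *plateau*
BA they should produce: the mean of 1 − ρ²ᵏ over the final 5 s of a
20 s record at 15 fps, inverted for ρ by `brentq`. Default plateaus
(dimensionless BA): control 0.90 at both ages; 100 Hz 0.88 (14 dap) /
0.80 (30 dap); 1 kHz 0.85/0.65; 10 kHz 0.82/0.45; classical music
0.70; rock music 0.50; phantom ρ = 1 exactly. Note the direction: the
*control* decorrelates fastest (highest BA); sound exposure slows the
speckle dynamics, increasingly so with frequency and age. Each plant
draws its own plateau from N(plateau, 0.05), clipped to [0.02, 0.98],
as a simple model of between-plant biological variability — without
it, every between-plant contrast would be trivially significant.

**These plateau values are generator calibration targets, not
measurements**: they define what the synthetic study simulates, and
the pipeline's job is to recover them from the frames.

## 5. Statistical calibration

`biospeckle.calibration` measures the actual operating characteristics
of the condition-vs-control test under the generator itself. To make
thousands of replicates tractable, each simulated acquisition is run
at 3 fps on a 48×48 grid with 3-pixel speckles — exact for the AR(1)
model (ρ_sub = ρ⁵) and unbiased for the early-window mean. Measured:
type-I error consistent with the nominal 0.05 at 2000 null replicates,
and power ≈ 1.0 for the rock-vs-control contrast (plateau 0.5 vs 0.9)
at n = 6 plants.

## 6. Stomatal time-course model and analysis

Layout: 3 seedlings × 3 leaves × 5 stomata = 45 stomata per condition,
observed at −10, 0, 10, 20, 30 minutes relative to the end of a
1-minute exposure. Each stoma keeps a fixed baseline size (major axis
25 μm, minor 15 μm, 8% between-stoma CV, minor ≤ major enforced);
per-observation multiplicative noise has 1.5% CV. The sound condition
applies a multiplicative reduction 1 − e·exp(−t/τ) with e = 6% and
τ = 3 min, so the t = 0 after/before ratio is 0.94 in expectation and
the deficit is under 0.3% by the first 10-minute observation.

Analysis: the after/before ratio of *group means* (mean size at time t
over the mean pre-exposure size of the same stomata), with a
percentile bootstrap CI over stomata in which each resampled stoma
keeps its before/after pairing. Recovery time is the earliest grid
time from which the ratio stays within ±0.02 of 1 at all later times;
with the default generator this is 10 min for the sound condition and
the first observation for controls. Acceptance testing confirms the
injected 6% effect is recovered (CI covers 0.94) and the 10-minute
recovery detected in ≥90% of 200 seeds.

**Limits.** The generator has no circadian drift, no between-leaf or
between-seedling variance components (only between-stoma), and
exponential recovery is an assumption — the analysis functions do not
depend on it.

## 7. Numerical and reproducibility choices

- All statistics in float64 regardless of frame dtype.
- Default test/analysis grid 64×64 (study) to 256×256 (oracles)
  rather than full camera resolution: BA is a spatial average, so
  precision scales with the number of speckles, and ~60–950
  independent speckles per frame resolve all the effects simulated
  here at desk-scale runtime. Full resolution is a config field.
- Seeds: every random stream derives from one master seed via SHA-256
  of a labelled key string (first 4 bytes mod 2³¹), then
  `numpy.random.SeedSequence` spawning per frame. Identical config and
  seed give byte-identical output files.
- Root finding (`brentq`) for the pupil cutoff and plateau inversion;
  tolerances 1e-14, far below any statistical uncertainty.
- Monte-Carlo acceptance checks use 3-SE bands; where many lags are
  checked simultaneously, a pre-declared independent confirmation
  batch distinguishes a genuine bias (fails both batches) from the
  ~15% familywise chance of a single 3σ fluctuation.
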