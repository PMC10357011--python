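# Methods

This note documents the models behind `ospra`: what the simulator
generates, how each processing stage is defined, the defaults and why,
and what the package's passing tests do and do not demonstrate about a
physical instrument.

## Sensor model

The simulator emulates a miniature grating spectrometer read by a 288-site
CMOS line sensor through a 10-bit ADC. Photosite `p` maps to wavelength
through a degree-5 polynomial `λ_p = Σ_k c_k p^k` (manufacturer
convention for this sensor family); the default coefficients
`(320, 2, −6·10⁻⁴, 0, 0, 0)` span ≈320–845 nm with mild curvature. The
bin width `B_p` is half the distance between neighbouring photosites'
wavelengths (one-sided at the ends), which makes `Σ B_p` equal the
spectral span plus half an end bin on each side.

An open-shutter frame is generated as

    ideal_p = S_true,p · scene(λ_p) · T · B_p            (linear counts)
    photo_p ~ Poisson(ideal_p)                            (shot noise)
    c_p = round(dark_p + g⁻¹(photo_p) + stray + ε_read),  clipped to [0, 1023]

where `S_true` is the ground-truth responsivity (counts ms⁻¹ per unit
spectral flux per nm; default a smooth positive curve peaking at 50 near
560 nm), `T` the integration time in ms, `g⁻¹` the inverse of the
linearisation response below (so that linearising with matched
coefficients recovers `ideal` exactly), `dark_p ~ N(dark_mean, dark_sd²)`
and `ε_read ~ N(0, read_noise_sd²)`.

Noise defaults — `dark_mean = 18` counts, `dark_sd = 1.2`,
`read_noise_sd = 0.8`, Poisson shot noise at unit gain (one count treated
as one photoelectron) — are stated assumptions chosen once as realistic
for a 10-bit CMOS line sensor; they are not measured properties of any
physical unit. The same holds for the stray-light model: a fraction of
the total in-band linear signal spread uniformly over all photosites,
present only with the shutter open and therefore immune to dark
subtraction, which reproduces the qualitative low-light near-IR artefact.
Dark level is modelled independent of integration time; slow thermal
drift is not modelled (the interleaved-dark logic is exercised, but the
drift it exists to track is absent).

Exposure limits are 1 ms to 30 s. The usable saturation ceiling is 900 of
the 1024 ADC levels, giving a theoretical single-exposure dynamic range
of 900:1 (ceiling over the one-count quantisation floor).

## Acquisition

*Scan count*: the largest `n ≤ 50` with `n · T` strictly under 1 s,
floored at 3 ("less than" is read as a strict inequality).

*Auto-exposure*: starting at the minimum integration time, test exposures
double until any photosite's raw count reaches the ceiling (or the 30 s
cap). The last unsaturated test, with a matched dark frame, gives the
rescaling `T* = T_last · 0.8 · ceiling / peak_darkfree`, clamped to the
permitted range. Saturation is detected on raw light counts (it is
invisible after dark subtraction); the 0.8 targeting uses dark-free
counts. The exposure target is defined on the *linear* response — the
rescale rule is a proportionality, so on a sensor with a non-identity
count nonlinearity the landing point deviates by roughly the local
curvature of the response (about one ADC count at the defaults).

*Averaging*: `n` light and `n` dark frames, alternated when `T > 1 s`,
block-wise otherwise (the arithmetic is identical; the order encodes the
temporal pairing). Output counts are `mean(light) − mean(dark)` per
photosite, kept as signed reals.

## Linearisation

The count response is modelled, on counts normalised to the 900-count
full scale, by the two-coefficient family

    f(x; a, b) = x^b (1 + a) / (1 + a x),  a ≥ 0, b ≳ 1.

Properties: `f(0⁺) = 0` and the curve levels smoothly into zero below one
count instead of diverging or going negative (the failure modes of
log-linear and gamma-variate corrections, which amplify noise around the
black point); `f(1) = 1` for any coefficients, matching the max-normalised
fit data by construction; strictly increasing for `b ≥ 1`; asymptotically
log-log linear with slope `b`; the identity response is exactly
`(a, b) = (0, 1)`. The functional family is this package's own design —
chosen to satisfy these constraints — and all of its tests are round-trip
or self-consistency checks that hold within the family.

The fit uses an exposure ramp of a stable source in one-octave steps,
ramped down from saturation and back up (so source drift would be
visible). Each observation is the 380–780 nm band sum of a dark-subtracted
measurement; saturated observations are excluded; at least four usable
points spanning three octaves are required. Expected rates are
proportional to integration time; both axes are scaled to max = 1, which
makes the fit invariant to overall count scale. Nonlinear least squares
(`scipy.optimize.curve_fit`) starts from `(0.14, 1.06)` with a small
multi-start fallback; bounds `a ∈ [0, 100]`, `b ∈ [0.2, 5]`.

Per-photosite application normalises by the full scale and uses an odd
extension: `linearise(c) = sign(c) · κ · f(|c|/κ)` with `κ = 900`, so
negative noise excursions are mapped symmetrically and zero maps to zero.
The simulator's generative nonlinearity is the exact inverse of this map,
which makes linearisation recovery exactly identifiable — a deliberate
choice so that round-trip failures indicate pipeline defects, not model
mismatch.

Note that the coefficients fitted to *summed* band counts aggregate many
photosites at different fractions of full scale, so they are an effective
description of the unit's ramp response; they need not equal the
generative per-photosite coefficients, and the package's recovery checks
therefore generate their reference ramps by direct inversion of `f`.

## Sensitivity calibration

Relative sensitivity: `S_p ∝ (c_linear,p / T / B_p) / reference(λ_p)`,
with the reference resampled by linear interpolation (the instrument's
~9 nm FWHM makes higher-order interpolation immaterial), smoothed with a
Gaussian of σ = 3 in photosite-index units (the native grid), and scaled
to peak = 1. The absolute scale is a single scalar chosen by least squares
so the calibrated spectrum of a known standard reproduces its true
spectrum; sites where the relative curve is numerically zero are excluded
from the regression.

The σ = 3 smoothing biases the recovered curve where the true sensitivity
has structure; for smooth truths the bias is under 1% RMS, which the
tests assert.

## Radiometric conversion and low-light processing

    value_p = c_linear,p / (S_p · T · B_p)

in W sr⁻¹ m⁻² nm⁻¹ (radiance) or W m⁻² nm⁻¹ (irradiance). Negative values
are preserved — clipping would bias any downstream averaging of low-light
spectra. Raw counts travel with every calibrated spectrum, so
re-calibration with a different record is exact and idempotent.

Low-light stages, in the fixed order offset → calibrate → smooth →
normalise: a constant dark offset (0.5 counts radiance, 0.2 irradiance,
configurable) subtracted from raw counts to compensate scene-driven
internal scatter; Gaussian smoothing (σ = 3, reflective boundary);
area normalisation dividing by `Σ v_p B_p` over 425–650 nm (bin-weighted
sums, not trapezoids, to stay consistent with the bin semantics of the
conversion). Smoothing before normalisation was an open ordering choice;
it is fixed this way and the normalisation is idempotent either way.

## Photometry

Luminance/illuminance is `K_m Σ_p v_p ȳ(λ_p) B_p` with
`K_m = 683 lm W⁻¹` (configurable). `ȳ` is an analytic two-lobe
piecewise-Gaussian approximation of the photopic luminous-efficiency
curve — lobes `0.821·G(568.8; 46.9/40.5)` and `0.286·G(530.9; 16.3/31.1)`
nm, asymmetric widths below/above the centre — rescaled to a peak of
exactly one and truncated to 360–830 nm. The curve is evaluated on each
unit's own wavelength grid, so units with different wavelength polynomials
weight the same spectrum consistently. Tests pin the peak location and
value, support, linearity/additivity, the 683 cd m⁻² monochromatic line at
555 nm, and agreement with fine-grid quadrature to 0.5%.

## Cosine corrector

Degraded diffusers are modelled as `q cos θ + (1 − q) cos² θ` for quality
`q ∈ [0, 1]` — a minimal sub-Lambertian family with the correct endpoints
(ideal at `q = 1`, normal incidence unaffected). The evaluation divides
angle-normalised readings by `cos θ`; under the model the deviation curve
is exactly `q + (1 − q) cos θ`, which the sweep tests check. Housing
shadowing at grazing angles is not modelled.

## Problem sizes and determinism

Simulated checks run at desk scale: 1000-frame Monte-Carlo means,
200-replicate averaging-law estimates, and 100 replicate noisy-ramp fits
(8 octave steps, down-and-up, scan counts per the controller rule). All
randomness flows through explicit seeds (`numpy.random.default_rng`);
identical configuration and seed reproduce frames bit-for-bit.

## Limitations

- The simulator's noise magnitudes, stray-light fraction and sensitivity
  shape are plausible but invented; passing round-trip tests demonstrates
  the *pipeline's* correctness and stability under realistic noise, not
  the absolute accuracy of any physical unit.
- Thermal dark drift, voltage collapse beyond 30 s, second-order
  diffraction of near-IR-rich sources and real lamp spectra are out of
  scope; references are smooth synthetic spectra.
- Photon-flux (quantal) output and non-human spectral weightings are not
  implemented.
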