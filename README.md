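# ospra

A hardware-free implementation of a low-cost spectroradiometer's complete
measurement chain, aimed at sensory ecology and light-pollution (ALAN)
research, where spectra must be measured from daylight down to starlight
levels across the UV-A to near-IR range.

The package pairs a generative simulator of a 288-photosite CMOS
line-sensor spectrometer (Hamamatsu C12880MA class: 10-bit ADC, ~900
usable count levels, per-site dark level, shot and read noise, a
two-coefficient count nonlinearity, saturation clipping, and a shutter
with closed/radiance/irradiance positions) with the full processing
pipeline such an instrument needs:

- **Acquisition** — auto-exposure that doubles the integration time until
  saturation and then targets the peak at 0.8 of the ceiling (1 ms–30 s);
  scan averaging (3–50 exposures, under 1 s of total light time) with
  matched shutter-closed dark frames, interleaved for exposures over 1 s;
  dark subtraction `c_p = mean(l_p) − mean(d_p)`; saturation accounting on
  the raw light frames.
- **Linearisation** — a two-coefficient response curve
  `f(x; a, b) = x^b (1+a)/(1+a x)` fitted by least squares to an
  octave-stepped exposure ramp (summed 380–780 nm counts vs expected rate,
  both scaled to max = 1), applied per photosite with an odd extension for
  negative counts so noise about the black point is never amplified.
- **Radiometric calibration** — relative spectral sensitivity transferred
  from a reference source (Gaussian-smoothed, σ = 3 photosites), absolute
  scale pinned against a standard by least squares, then
  `value_p = c_linear,p / (S_p · T · B_p)` with per-photosite wavelengths
  from a degree-5 polynomial and bin widths `B_p` in nm.
- **Cosine-corrector evaluation** — angular sweeps 0–80° against the
  Lambertian cos θ ideal.
- **Low-light processing** — fixed dark-offset correction (0.5 counts
  radiance / 0.2 irradiance) for internal stray light, smoothing, and
  425–650 nm area normalisation for shape comparison.
- **Photometry** — luminance (cd m⁻²) / illuminance (lx) via an analytic
  photopic luminous-efficiency curve evaluated on the unit's own
  wavelength grid, with K_m = 683 lm W⁻¹.
- **Persistence** — `calibration_data.csv` / append-only `data.csv`
  schemas with raw counts retained, so every measurement can be
  re-calibrated after recording.

## Worked example

Fitting the linearisation from a simulated exposure ramp
(`examples/02_linearisation_fit.py`):

```text
fitted a = 0.06993, b = 1.06361  (R^2 = 1.00000)
2 saturated ramp points were excluded
```

The two coefficients describe how the unit's summed count rate droops at
low counts; an R² near one means the curve captures the whole ramp.
Calibrating and checking a unit against the reference it was trained on
(`examples/03_sensitivity_calibration.py`):

```text
relative sensitivity peaks at 561 nm
absolute scale factor vs relative curve: 49.8 counts ms^-1 per (W sr^-1 m^-2)
round-trip RMS error of the calibrated instrument: 0.28%
```

The remaining examples cover auto-exposed measurement, cosine-corrector
sweeps, the low-light stray-light correction and photometric summaries.

## Command line

A thin CLI mirrors the instrument app:

```sh
ospra --seed 1 simulate --scene scene.csv --mode radiance --unit A --out data.csv
ospra --seed 1 calibrate-linearity --unit A --out calibration_data.csv
ospra --seed 1 calibrate-sensitivity --unit A --out calibration_data.csv
ospra --seed 1 cosine-eval --quality 0.8
ospra process --calibration calibration_data.csv --in data.csv \
      --dark-offset auto --smooth 3 --normalize 425:650 --out processed.csv
ospra photometry --in data.csv
ospra recalibrate --in data.csv --calibration calibration_data.csv --unit A --out new.csv
```

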