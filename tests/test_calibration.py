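"""Linearisation fitting, sensitivity derivation and cosine evaluation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ospra import (
    CountSpectrum,
    ExposurePlan,
    LinearisationModel,
    RampObservation,
    SceneSpectrum,
    SensorConfig,
    WavelengthMap,
    absolute_scale,
    acquire,
    choose_scan_count,
    cosine_deviation,
    derive_sensitivity,
    expected_rates,
    fit_linearisation,
    gaussian_smooth,
    linearisation_r2,
    linearise,
    simulate_angle_sweep,
    summed_band_counts,
)
from ospra.sensor import ideal_open_counts

from conftest import broadband_scene

UNIT_C = LinearisationModel(0.14231, 1.06125)


def octave_ramp(model, n_octaves=10, c_max=150000.0):
    """Noiseless ramp generated by inverting the response curve."""
    ts = [2.0**k for k in range(n_octaves + 1)]
    r = expected_rates(ts)
    counts = model.inverse_response(r) * c_max
    return [RampObservation(t, c) for t, c in zip(ts, counts)]


# ------------------------------------------------------------- band counting


def test_summed_band_counts_counts_in_band_sites():
    wmap = WavelengthMap((320.0, 2.0))
    cs = CountSpectrum(np.ones(288), 10.0, 3)
    lam = wmap.wavelengths
    n_in = int(np.sum((lam >= 380) & (lam <= 780)))
    assert summed_band_counts(cs, wmap) == n_in


def test_summed_band_counts_matches_brute_force():
    rng = np.random.default_rng(0)
    wmap = WavelengthMap((320.0, 2.0, -6e-4))
    c = rng.normal(size=288)
    cs = CountSpectrum(c, 10.0, 3)
    lam = wmap.wavelengths
    oracle = sum(c[p] for p in range(288) if 380.0 <= lam[p] <= 780.0)
    assert summed_band_counts(cs, wmap) == pytest.approx(oracle, abs=1e-12)


def test_summed_band_counts_rejects_empty_band():
    wmap = WavelengthMap((320.0, 2.0))
    cs = CountSpectrum(np.ones(288), 10.0, 3)
    with pytest.raises(ValueError):
        summed_band_counts(cs, wmap, 0.0, 100.0)


@pytest.mark.parametrize(
    "ts, expected",
    [([1, 2, 4], [0.25, 0.5, 1.0]), ([7], [1.0])],
)
def test_expected_rates_proportional_to_time(ts, expected):
    np.testing.assert_allclose(expected_rates(ts), expected)


def test_expected_rates_octave_ramp_doubles():
    r = expected_rates([2.0**k for k in range(11)])
    np.testing.assert_allclose(r[1:] / r[:-1], 2.0)
    assert r[-1] == 1.0


def test_expected_rates_rejects_bad_input():
    with pytest.raises(ValueError):
        expected_rates([])
    with pytest.raises(ValueError):
        expected_rates([1.0, 0.0])


# ---------------------------------------------------------------- fit & apply


def test_fit_recovers_published_coefficients_from_noiseless_ramp():
    model, r2 = fit_linearisation(octave_ramp(UNIT_C))
    assert model.a == pytest.approx(0.14231, abs=1e-3)
    assert model.b == pytest.approx(1.06125, abs=1e-3)
    assert r2 > 0.999999


def test_fit_on_linear_sensor_returns_identity():
    model, r2 = fit_linearisation(octave_ramp(LinearisationModel(0.0, 1.0)))
    grid = np.linspace(0.01, 1.0, 50)
    np.testing.assert_allclose(model.response(grid), grid, atol=1e-6)
    assert r2 >= 0.999


def test_fit_is_scale_consistent():
    ramp = octave_ramp(UNIT_C)
    scaled = [RampObservation(o.integration_ms, o.summed_counts * 37.0) for o in ramp]
    m1, _ = fit_linearisation(ramp)
    m2, _ = fit_linearisation(scaled)
    assert m1.a == pytest.approx(m2.a, rel=1e-9)
    assert m1.b == pytest.approx(m2.b, rel=1e-9)


def test_fit_excludes_saturated_observations():
    ramp = octave_ramp(UNIT_C)
    ramp.append(RampObservation(4096.0, ramp[-1].summed_counts * 1.01, saturated=True))
    model, _ = fit_linearisation(ramp)
    assert model.a == pytest.approx(0.14231, abs=1e-3)


def test_fit_rejects_insufficient_or_narrow_ramps():
    ramp = octave_ramp(UNIT_C)
    with pytest.raises(ValueError, match="unsaturated"):
        fit_linearisation(ramp[:3])
    narrow = [RampObservation(t, t / 4.0) for t in (1.0, 2.0, 3.0, 4.0)]
    with pytest.raises(ValueError, match="octave"):
        fit_linearisation(narrow)


def test_fit_quality_on_noisy_simulated_ramp():
    """Quantisation + shot noise on an octave ramp still fits with
    R^2 at or above the 0.989 floor."""
    cfg = SensorConfig(rng_seed=3)
    rng = cfg.rng()
    scene = broadband_scene(cfg, peak_rate_counts_per_ms=9.0)
    wmap = WavelengthMap(cfg.wavelength_coeffs)
    ts = [2.0**k for k in range(8)]
    obs = []
    for t in list(reversed(ts)) + ts:
        cs = acquire(scene, ExposurePlan(t, choose_scan_count(t), t > 1000), cfg, rng)
        obs.append(RampObservation(t, summed_band_counts(cs, wmap), cs.n_saturated > 0))
    _, r2 = fit_linearisation(obs)
    assert r2 >= 0.989


def test_cross_unit_coefficients_still_fit_well():
    """Applying one unit's coefficients to another unit's ramp stays above
    R^2 = 0.99 for the between-unit spread modelled here."""
    unit_e = LinearisationModel(0.19, 1.03)
    assert linearisation_r2(unit_e, octave_ramp(UNIT_C)) >= 0.99
    assert linearisation_r2(UNIT_C, octave_ramp(unit_e)) >= 0.99


def test_linearise_zero_maps_to_zero():
    cs = CountSpectrum(np.zeros(5), 10.0, 3)
    assert np.all(linearise(cs, UNIT_C) == 0.0)


@given(st.floats(min_value=0.0, max_value=900.0))
def test_linearise_is_odd(x):
    plus = UNIT_C.apply_counts(np.array([x]))
    minus = UNIT_C.apply_counts(np.array([-x]))
    assert minus[0] == -plus[0]


def test_linearise_inverts_the_generative_nonlinearity():
    v = np.linspace(1e-3, 1.0, 200) * 900.0
    distorted = UNIT_C.invert_counts(v)
    np.testing.assert_allclose(UNIT_C.apply_counts(distorted), v, atol=1e-9)


@given(st.floats(min_value=1e-6, max_value=1.0), st.floats(min_value=1e-6, max_value=1.0))
def test_response_is_strictly_increasing_and_non_negative(x1, x2):
    lo, hi = sorted((x1, x2))
    r_lo, r_hi = UNIT_C.response(lo), UNIT_C.response(hi)
    assert r_lo >= 0
    if hi > lo:
        assert r_hi > r_lo


# ------------------------------------------------------ sensitivity transfer


def test_flat_reference_and_counts_give_flat_sensitivity():
    wmap = WavelengthMap((320.0, 2.0))  # uniform 2 nm bins
    cs = CountSpectrum(np.full(288, 200.0), 10.0, 3)
    ref = SceneSpectrum(wmap.wavelengths, np.full(288, 5.0), "radiance")
    S = derive_sensitivity(cs, ref, wmap, "radiance").S
    np.testing.assert_allclose(S, 1.0, atol=1e-9)


def test_reference_scale_cancels_after_peak_normalisation():
    wmap = WavelengthMap((320.0, 2.0, -6e-4))
    rng = np.random.default_rng(1)
    cs = CountSpectrum(100.0 + 50.0 * rng.random(288), 10.0, 3)
    lam = wmap.wavelengths
    ref = SceneSpectrum(lam, 1.0 + 0.5 * np.sin(lam / 60.0) ** 2, "radiance")
    ref2 = ref.scaled(2.0)
    S1 = derive_sensitivity(cs, ref, wmap, "radiance").S
    S2 = derive_sensitivity(cs, ref2, wmap, "radiance").S
    np.testing.assert_allclose(S1, S2, atol=1e-12)


def test_reference_must_be_positive_in_band():
    wmap = WavelengthMap((320.0, 2.0))
    cs = CountSpectrum(np.full(288, 10.0), 10.0, 3)
    lam = wmap.wavelengths
    vals = np.where(lam > 600, 0.0, 1.0)
    with pytest.raises(ValueError):
        derive_sensitivity(cs, SceneSpectrum(lam, vals, "radiance"), wmap, "radiance")


def test_sensitivity_recovered_from_simulator_within_one_percent(noiseless_linear_config):
    cfg = noiseless_linear_config
    scene = broadband_scene(cfg, peak_rate_counts_per_ms=60.0)
    cs = acquire(scene, ExposurePlan(10.0, 3, False), cfg)
    wmap = WavelengthMap(cfg.wavelength_coeffs)
    S = derive_sensitivity(cs, scene, wmap, "radiance").S
    truth = gaussian_smooth(cfg.true_sensitivity, 3.0)
    truth = truth / truth.max()
    rms = np.sqrt(np.mean((S - truth) ** 2)) / truth.mean()
    assert rms < 0.01


def test_absolute_scale_self_consistency_and_scaling():
    cfg = SensorConfig(nonlin_a=0.0, nonlin_b=1.0).noiseless()
    wmap = WavelengthMap(cfg.wavelength_coeffs)
    lam, B = wmap.wavelengths, wmap.bin_widths
    from ospra.calibration import SensitivityCurve

    rel = SensitivityCurve("radiance", cfg.true_sensitivity / cfg.true_sensitivity.max())
    truth_vals = 0.2 + 0.1 * np.sin(lam / 100.0) ** 2
    T = 10.0
    counts = rel.S * truth_vals * T * B  # exactly the Eq.-style prediction
    cs = CountSpectrum(counts, T, 3)
    truth = SceneSpectrum(lam, truth_vals, "radiance")
    cal = absolute_scale(rel, cs, truth, wmap)
    np.testing.assert_allclose(cal.S, rel.S, rtol=1e-12)  # k = 1
    cs10 = CountSpectrum(counts * 10.0, T, 3)
    cal10 = absolute_scale(rel, cs10, truth, wmap)
    np.testing.assert_allclose(cal10.S, rel.S * 10.0, rtol=1e-12)  # k = 10
    truth10 = SceneSpectrum(lam, truth_vals * 10.0, "radiance")
    cal_div = absolute_scale(rel, cs, truth10, wmap)
    np.testing.assert_allclose(cal_div.S, rel.S / 10.0, rtol=1e-12)


def test_absolute_scale_rejects_zero_standard():
    cfg = SensorConfig().noiseless()
    wmap = WavelengthMap(cfg.wavelength_coeffs)
    from ospra.calibration import SensitivityCurve

    rel = SensitivityCurve("radiance", np.ones(288))
    cs = CountSpectrum(np.zeros(288), 10.0, 3)
    zero = SceneSpectrum(wmap.wavelengths, np.zeros(288), "radiance")
    with pytest.raises(ValueError):
        absolute_scale(rel, cs, zero, wmap)


# ------------------------------------------------------------ cosine corrector


def test_ideal_lambertian_readings_give_unit_deviation():
    angles = np.arange(0.0, 81.0, 10.0)
    table = cosine_deviation(angles, np.cos(np.deg2rad(angles)))
    np.testing.assert_allclose(table["deviation"], 1.0, atol=1e-12)


def test_cos_squared_reading_at_sixty_degrees():
    table = cosine_deviation([0.0, 60.0], [1.0, np.cos(np.deg2rad(60.0)) ** 2])
    assert table["deviation"].iloc[1] == pytest.approx(0.5, abs=1e-12)


def test_cosine_deviation_rejects_grazing_angles():
    with pytest.raises(ValueError):
        cosine_deviation([0.0, 90.0], [1.0, 0.0])


def test_degraded_corrector_matches_closed_form(noiseless_linear_config):
    """For quality q the deviation curve is q + (1 - q) cos(theta)."""
    cfg = noiseless_linear_config
    q = 0.8
    angles = np.arange(0.0, 81.0, 10.0)
    sweep = simulate_angle_sweep(0.2, angles, q, cfg, n_frames=1)
    dark = cfg.dark_mean_array
    readings = [float(np.sum(frames[0].counts - dark)) for frames in sweep]
    table = cosine_deviation(angles, readings)
    expected = q + (1.0 - q) * np.cos(np.deg2rad(angles))
    np.testing.assert_allclose(table["deviation"], expected, atol=0.01)
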