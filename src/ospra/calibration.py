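"""Per-unit calibration: count linearisation, spectral sensitivity and
cosine-corrector evaluation.

Linearisation model
-------------------
CMOS count response is close to linear in flux but droops at low counts,
which would make low-light measurements underestimate intensity.  The
correction is a two-coefficient response curve fitted to an exposure ramp
of a stable source.  With counts expressed as a fraction ``x`` of the
full usable scale, the modelled linear rate is::

    f(x; a, b) = x**b * (1 + a) / (1 + a * x)

The curve passes through f(1) = 1, is strictly increasing for b >= 1,
tends smoothly to zero as counts fall below one (rather than diverging or
going negative like log-linear or gamma-variate corrections, which amplify
noise around the black point), and is asymptotically log-log linear.  The
identity response is a = 0, b = 1.

The fit uses summed in-band counts (380-780 nm, the emission range of the
ramp source) against the expected rate r proportional to integration time,
both scaled to a maximum of one so that units with different absolute
sensitivity are directly comparable.  Negative dark-subtracted counts are
linearised through an odd extension of f: the sign is switched before and
restored after, so noise about zero is never systematically amplified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq, curve_fit

from .acquisition import CountSpectrum
from .sensor import SceneSpectrum

__all__ = [
    "LinearisationModel",
    "RampObservation",
    "SensitivityCurve",
    "summed_band_counts",
    "expected_rates",
    "fit_linearisation",
    "linearisation_r2",
    "linearise",
    "derive_sensitivity",
    "absolute_scale",
    "cosine_deviation",
    "FULL_SCALE",
]

#: default full-scale counts used to normalise photosite counts into the
#: response curve's domain (the usable saturation ceiling)
FULL_SCALE = 900.0


@dataclass(frozen=True)
class LinearisationModel:
    """Two-coefficient count-rate response f(x) = x^b (1+a)/(1+a x)."""

    a: float
    b: float

    def response(self, x: np.ndarray | float) -> np.ndarray:
        """Linearised rate for non-negative normalised counts x."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("response is defined for x >= 0; use apply_counts "
                             "for signed values")
        with np.errstate(divide="ignore"):
            out = np.where(x > 0, x**self.b * (1.0 + self.a) / (1.0 + self.a * x), 0.0)
        return out

    def inverse_response(self, y: np.ndarray | float) -> np.ndarray:
        """Inverse of :meth:`response` (Newton in log space, brentq fallback)."""
        y = np.asarray(y, dtype=float)
        if np.any(y < 0):
            raise ValueError("inverse_response is defined for y >= 0")
        a, b = self.a, self.b
        out = np.zeros_like(y)
        pos = y > 0
        if not np.any(pos):
            return out
        yp = y[pos]
        target = np.log(yp)
        u = np.log(yp)  # start at the identity response
        for _ in range(100):
            eu = np.exp(u)
            g = b * u + np.log1p(a) - np.log1p(a * eu)
            gp = b - a * eu / (1.0 + a * eu)
            step = (g - target) / gp
            u = u - step
            if np.max(np.abs(step)) < 1e-14:
                break
        x = np.exp(u)
        bad = np.abs(self.response(x) - yp) > 1e-9 * np.maximum(yp, 1.0)
        if np.any(bad):
            for i in np.nonzero(bad)[0]:
                yi = yp[i]
                hi = max(1.0, yi)
                while self.response(hi) < yi:
                    hi *= 2.0
                x[i] = brentq(lambda t: float(self.response(t) - yi), 0.0, hi)
        out[pos] = x
        return out

    def apply_counts(
        self, counts: np.ndarray | float, full_scale: float = FULL_SCALE
    ) -> np.ndarray:
        """Linearise signed counts: odd extension, zero maps to zero."""
        c = np.asarray(counts, dtype=float)
        return np.sign(c) * full_scale * self.response(np.abs(c) / full_scale)

    def invert_counts(
        self, linear_counts: np.ndarray | float, full_scale: float = FULL_SCALE
    ) -> np.ndarray:
        """Inverse of :meth:`apply_counts` (the generative nonlinearity)."""
        s = np.asarray(linear_counts, dtype=float)
        return np.sign(s) * full_scale * self.inverse_response(np.abs(s) / full_scale)


@dataclass
class RampObservation:
    """One point of the exposure ramp: integration time and the summed
    in-band counts it produced."""

    integration_ms: float
    summed_counts: float
    saturated: bool = False


def summed_band_counts(
    counts: CountSpectrum,
    wmap,
    lo_nm: float = 380.0,
    hi_nm: float = 780.0,
) -> float:
    """Sum dark-subtracted counts over photosites with lo <= lambda <= hi."""
    lam = np.asarray(wmap.wavelengths, dtype=float)
    mask = (lam >= lo_nm) & (lam <= hi_nm)
    if not np.any(mask):
        raise ValueError(f"no photosites fall in the band [{lo_nm}, {hi_nm}] nm")
    return float(np.sum(counts.c[mask]))


def expected_rates(integrations_ms: Sequence[float]) -> np.ndarray:
    """Expected linear count rate, proportional to integration time and
    rescaled so the maximum is one."""
    t = np.asarray(integrations_ms, dtype=float)
    if t.size == 0:
        raise ValueError("at least one integration time is required")
    if np.any(t <= 0):
        raise ValueError("integration times must be positive")
    return t / t.max()


def fit_linearisation(
    ramp: Sequence[RampObservation],
) -> tuple[LinearisationModel, float]:
    """Least-squares fit of the response curve to an exposure ramp.

    Saturated observations are excluded.  Requires at least four usable
    points spanning at least three octaves of integration time.  Returns
    the fitted model and the coefficient of determination of the fit.
    """
    usable = [o for o in ramp if not o.saturated]
    if len(usable) < 4:
        raise ValueError(
            f"need >= 4 unsaturated ramp observations, got {len(usable)}"
        )
    t = np.array([o.integration_ms for o in usable], dtype=float)
    if t.max() / t.min() < 8.0:
        raise ValueError(
            "ramp must span at least three octaves of integration time "
            f"(spans {np.log2(t.max() / t.min()):.2f})"
        )
    c = np.array([o.summed_counts for o in usable], dtype=float)
    if c.max() <= 0:
        raise ValueError("ramp counts are non-positive; cannot normalise")
    x = c / c.max()
    r = expected_rates(t)
    if np.any(x <= 0):
        raise ValueError("normalised ramp counts must be positive")

    def model_fn(xv, a, b):
        return xv**b * (1.0 + a) / (1.0 + a * xv)

    starts = [(0.14, 1.06), (0.0, 1.0), (1.0, 1.2), (5.0, 1.5), (0.5, 0.9)]
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                model_fn, x, r, p0=p0, bounds=([0.0, 0.2], [100.0, 5.0]), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((model_fn(x, *popt) - r) ** 2))
        if best is None or ss < best[1]:
            best = (popt, ss)
    if best is None:
        raise ValueError("linearisation fit failed to converge from any start")
    (a, b), _ = best
    model = LinearisationModel(float(a), float(b))
    return model, linearisation_r2(model, usable)


def linearisation_r2(
    model: LinearisationModel, ramp: Sequence[RampObservation]
) -> float:
    """R^2 of a (possibly foreign) model against a normalised ramp —
    used to quantify how well one unit's coefficients fit another unit."""
    usable = [o for o in ramp if not o.saturated]
    t = np.array([o.integration_ms for o in usable], dtype=float)
    c = np.array([o.summed_counts for o in usable], dtype=float)
    x = c / c.max()
    r = expected_rates(t)
    pred = model.response(x)
    ss_res = float(np.sum((pred - r) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def linearise(
    counts: CountSpectrum,
    model: LinearisationModel,
    full_scale: float = FULL_SCALE,
) -> np.ndarray:
    """Per-photosite linearised counts (odd extension for negatives)."""
    return model.apply_counts(counts.c, full_scale=full_scale)


@dataclass
class SensitivityCurve:
    """Per-photosite responsivity, counts ms^-1 per (spectral flux * nm)."""

    mode: str
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.mode not in ("radiance", "irradiance"):
            raise ValueError("mode must be 'radiance' or 'irradiance'")


def derive_sensitivity(
    measured: CountSpectrum,
    reference: SceneSpectrum,
    wmap,
    mode: str,
    sigma: float = 3.0,
) -> SensitivityCurve:
    """Relative spectral sensitivity from a measurement of a known source.

    ``measured.c`` must already be linearised and unsaturated.  The
    reference spectrum is resampled to the photosite wavelengths by linear
    interpolation; the count rate per nm divided by the reference gives the
    responsivity shape, which is Gaussian-smoothed (sigma in photosite
    units) and scaled to a peak of one.
    """
    lam = np.asarray(wmap.wavelengths, dtype=float)
    ref = np.interp(lam, reference.wavelengths, reference.values)
    if np.any(ref <= 0):
        raise ValueError("reference spectrum must be positive across the instrument band")
    B = np.asarray(wmap.bin_widths, dtype=float)
    S = (measured.c / measured.integration_ms / B) / ref
    S = gaussian_filter1d(S, sigma, mode="reflect") if sigma > 0 else S
    peak = float(np.max(S))
    if peak <= 0:
        raise ValueError("derived sensitivity is non-positive everywhere")
    return SensitivityCurve(mode=mode, S=S / peak)


def absolute_scale(
    relative: SensitivityCurve,
    measured_of_standard: CountSpectrum,
    standard_truth: SceneSpectrum,
    wmap,
) -> SensitivityCurve:
    """Pin the relative sensitivity to absolute units with one scalar.

    ``measured_of_standard.c`` must be linearised.  The scalar k is chosen
    by least squares so that the calibrated spectrum computed with k*S
    reproduces the known absolute spectrum of the standard.
    """
    lam = np.asarray(wmap.wavelengths, dtype=float)
    truth = np.interp(lam, standard_truth.wavelengths, standard_truth.values)
    if not np.any(truth > 0):
        raise ValueError("standard spectrum is zero everywhere on the instrument grid")
    B = np.asarray(wmap.bin_widths, dtype=float)
    mask = relative.S > 1e-6 * np.max(relative.S)
    v_rel = (measured_of_standard.c[mask] / measured_of_standard.integration_ms
             / B[mask] / relative.S[mask])
    # value with scaled sensitivity is v_rel / k; least squares in u = 1/k
    denom = float(np.dot(v_rel, v_rel))
    if denom == 0:
        raise ValueError("standard measurement contains no signal")
    u = float(np.dot(v_rel, truth[mask])) / denom
    if u <= 0:
        raise ValueError("absolute scaling is non-positive; inputs inconsistent")
    return SensitivityCurve(mode=relative.mode, S=relative.S / u)


def cosine_deviation(
    angles_deg: Sequence[float], readings: Sequence[float]
) -> "pandas.DataFrame":
    """Angular response of a cosine corrector against the Lambertian ideal.

    Normalises each reading by the 0-degree reading and divides by
    cos(theta); an ideal corrector gives a deviation of exactly one at
    every angle.
    """
    import pandas as pd

    angles = np.asarray(angles_deg, dtype=float)
    vals = np.asarray(readings, dtype=float)
    if angles.shape != vals.shape:
        raise ValueError("one reading per angle is required")
    if np.any(angles >= 90) or np.any(angles < 0):
        raise ValueError("angles must lie in [0, 90) degrees")
    zero = np.isclose(angles, 0.0)
    if not np.any(zero):
        raise ValueError("a 0-degree reference reading is required")
    r0 = float(vals[zero][0])
    if r0 <= 0:
        raise ValueError("the 0-degree reading must be positive")
    normalised = vals / r0
    deviation = normalised / np.cos(np.deg2rad(angles))
    return pd.DataFrame(
        {"angle_deg": angles, "normalised": normalised, "deviation": deviation}
    )
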