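"""Luminance and illuminance from calibrated spectra.

Weights a spectral radiance or irradiance measurement by the photopic
luminous-efficiency function evaluated on the unit's own wavelength grid:

    luminance  = K_m * sum_p  L_e,p * ybar(lambda_p) * B_p     [cd m^-2]
    illuminance = K_m * sum_p E_e,p * ybar(lambda_p) * B_p     [lx]

with K_m = 683 lm W^-1.  The luminous-efficiency curve is an analytic
piecewise-Gaussian approximation (two asymmetric lobes, coefficients
below) to the CIE photopic ybar function, rescaled to a peak of exactly
one near 555 nm and truncated to its 360-830 nm support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radiometry import CalibratedSpectrum, WavelengthMap

__all__ = [
    "LuminosityFunction",
    "luminous_efficiency",
    "luminosity_on_grid",
    "luminance",
    "K_M",
]

#: maximum luminous efficacy of radiation, lm W^-1
K_M = 683.0

#: support of the photopic curve, nm
SUPPORT_NM = (360.0, 830.0)

# piecewise-Gaussian lobes (amplitude, centre nm, sigma below centre, sigma
# above centre) approximating the photopic luminous-efficiency curve
_YBAR_LOBES = (
    (0.821, 568.8, 46.9, 40.5),
    (0.286, 530.9, 16.3, 31.1),
)


def _ybar_raw(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    out = np.zeros_like(lam)
    for amp, mu, s_lo, s_hi in _YBAR_LOBES:
        sigma = np.where(lam < mu, s_lo, s_hi)
        out += amp * np.exp(-0.5 * ((lam - mu) / sigma) ** 2)
    return np.where((lam >= SUPPORT_NM[0]) & (lam <= SUPPORT_NM[1]), out, 0.0)


def _peak() -> float:
    grid = np.arange(500.0, 600.0, 0.01)
    return float(np.max(_ybar_raw(grid)))


_PEAK = _peak()


def luminous_efficiency(lam: np.ndarray | float) -> np.ndarray:
    """Relative photopic luminous efficiency, peak-normalised to one."""
    return _ybar_raw(np.asarray(lam, dtype=float)) / _PEAK


@dataclass
class LuminosityFunction:
    """The luminous-efficiency curve sampled on one unit's wavelength grid."""

    wavelengths: np.ndarray
    ybar: np.ndarray
    K_m: float = K_M

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ybar = np.asarray(self.ybar, dtype=float)
        if self.wavelengths.shape != self.ybar.shape:
            raise ValueError("wavelengths and ybar must align")


def luminosity_on_grid(wmap: WavelengthMap) -> LuminosityFunction:
    """Evaluate the luminous-efficiency curve at each photosite wavelength,
    matching the curve to the unit's spectral response."""
    lam = wmap.wavelengths
    return LuminosityFunction(wavelengths=lam, ybar=luminous_efficiency(lam))


def luminance(spectrum: CalibratedSpectrum, lf: LuminosityFunction) -> float:
    """Luminance (cd m^-2) of a radiance spectrum, or illuminance (lx) of an
    irradiance spectrum."""
    if len(lf.ybar) != len(spectrum.values) or not np.allclose(
        lf.wavelengths, spectrum.wavelengths
    ):
        raise ValueError("luminosity function grid does not match the spectrum")
    return float(
        lf.K_m * np.sum(spectrum.values * lf.ybar * spectrum.bin_widths)
    )
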