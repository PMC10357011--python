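"""Counts to calibrated spectra.

Converts dark-subtracted, linearised counts into spectral radiance
L_e (W sr^-1 m^-2 nm^-1) or spectral irradiance E_e (W m^-2 nm^-1)::

    value_p = c_linear,p / (S_p * T * B_p)

where S is the unit's sensitivity (counts ms^-1 per flux unit per nm), T
the integration time in ms and B_p the spectral width in nm of photosite
p's bin.  Also implements the low-light processing stages: the fixed
dark-offset correction for internal stray light, Gaussian smoothing over
the photosite grid, and area normalisation for comparing spectral shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .acquisition import CountSpectrum
from .calibration import FULL_SCALE, LinearisationModel

__all__ = [
    "WavelengthMap",
    "CalibrationRecord",
    "CalibratedSpectrum",
    "bin_widths",
    "bin_widths_from_wavelengths",
    "counts_to_spectrum",
    "dark_offset_correct",
    "gaussian_smooth",
    "normalize_area",
    "RADIANCE_DARK_OFFSET",
    "IRRADIANCE_DARK_OFFSET",
]

#: low-light stray-light compensation, counts subtracted from raw counts
RADIANCE_DARK_OFFSET = 0.5
IRRADIANCE_DARK_OFFSET = 0.2


def bin_widths_from_wavelengths(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(np.diff(lam) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    b = np.empty_like(lam)
    b[1:-1] = (lam[2:] - lam[:-2]) / 2.0
    b[0] = lam[1] - lam[0]
    b[-1] = lam[-1] - lam[-2]
    return b


@dataclass
class WavelengthMap:
    """Photosite index -> wavelength via the manufacturer polynomial
    lambda_p = sum_k coeffs[k] * p**k (degree 5, shorter inputs zero-padded)."""

    coeffs: tuple
    n_photosites: int = 288

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coeffs)
        if len(coeffs) > 6:
            raise ValueError("at most 6 polynomial coefficients are supported")
        self.coeffs = coeffs + (0.0,) * (6 - len(coeffs))
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength map must be strictly increasing")

    @property
    def wavelengths(self) -> np.ndarray:
        p = np.arange(self.n_photosites, dtype=float)
        out = np.zeros_like(p)
        for k, c in enumerate(self.coeffs):
            out += c * p**k
        return out

    @property
    def bin_widths(self) -> np.ndarray:
        return bin_widths_from_wavelengths(self.wavelengths)


def bin_widths(wmap: WavelengthMap) -> np.ndarray:
    """Spectral width (nm) of each photosite's bin: half the distance
    between its neighbours' wavelengths, one-sided at the ends."""
    return wmap.bin_widths


@dataclass
class CalibrationRecord:
    """Everything needed to calibrate one unit's measurements: wavelength
    polynomial, linearisation coefficients and both sensitivity curves."""

    unit_id: str
    wavelength_coeffs: tuple
    lin_a: float
    lin_b: float
    S_r: np.ndarray
    S_i: np.ndarray
    extra: dict = None

    def __post_init__(self) -> None:
        self.S_r = np.asarray(self.S_r, dtype=float)
        self.S_i = np.asarray(self.S_i, dtype=float)
        if self.S_r.shape != self.S_i.shape:
            raise ValueError("S_r and S_i must have the same length")
        if self.extra is None:
            self.extra = {}
        coeffs = tuple(float(c) for c in self.wavelength_coeffs)
        self.wavelength_coeffs = coeffs + (0.0,) * (6 - len(coeffs))

    @property
    def n_photosites(self) -> int:
        return len(self.S_r)

    @property
    def wavelength_map(self) -> WavelengthMap:
        return WavelengthMap(self.wavelength_coeffs, n_photosites=self.n_photosites)

    @property
    def linearisation(self) -> LinearisationModel:
        return LinearisationModel(self.lin_a, self.lin_b)

    def sensitivity(self, mode: str) -> np.ndarray:
        if mode == "radiance":
            return self.S_r
        if mode == "irradiance":
            return self.S_i
        raise ValueError("mode must be 'radiance' or 'irradiance'")


@dataclass
class CalibratedSpectrum:
    """A calibrated measurement row.

    Raw counts are always retained alongside the calibrated values, so any
    measurement can be re-calibrated after recording.
    """

    unit_id: str
    label: str
    timestamp: str
    mode: str
    wavelengths: np.ndarray
    values: np.ndarray
    integration_ms: float
    n_scans: int
    n_saturated: int
    raw_counts: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        if not (len(self.wavelengths) == len(self.values) == len(self.raw_counts)):
            raise ValueError("wavelengths, values and raw_counts must align")
        if self.mode not in ("radiance", "irradiance"):
            raise ValueError("mode must be 'radiance' or 'irradiance'")

    @property
    def bin_widths(self) -> np.ndarray:
        return bin_widths_from_wavelengths(self.wavelengths)


def counts_to_spectrum(
    counts: CountSpectrum,
    calib: CalibrationRecord,
    mode: str,
    label: str = "",
    timestamp: str = "",
    full_scale: float = FULL_SCALE,
) -> CalibratedSpectrum:
    """Apply linearisation and the sensitivity calibration (the radiometric
    conversion above).  Negative values are preserved, never clipped, so
    that averaging many low-light spectra stays unbiased."""
    S = calib.sensitivity(mode)
    if np.any(S <= 0):
        raise ValueError("sensitivity must be positive across the sensitive band")
    if counts.integration_ms <= 0:
        raise ValueError("integration time must be positive")
    wmap = calib.wavelength_map
    c_lin = calib.linearisation.apply_counts(counts.c, full_scale=full_scale)
    values = c_lin / (S * counts.integration_ms * wmap.bin_widths)
    return CalibratedSpectrum(
        unit_id=calib.unit_id,
        label=label,
        timestamp=timestamp,
        mode=mode,
        wavelengths=wmap.wavelengths,
        values=values,
        integration_ms=counts.integration_ms,
        n_scans=counts.n_scans,
        n_saturated=counts.n_saturated,
        raw_counts=counts.c.copy(),
    )


def dark_offset_correct(
    counts: CountSpectrum, mode: str, offset: float | None = None
) -> CountSpectrum:
    """Subtract the fixed low-light dark offset from every photosite.

    Internal stray light inflates the apparent signal in low-sensitivity
    regions of the spectrum; because it is scene-driven it survives the
    shutter-closed dark subtraction.  The compensation is a small constant:
    0.5 counts for radiance, 0.2 for irradiance by default.
    """
    if offset is None:
        offset = RADIANCE_DARK_OFFSET if mode == "radiance" else IRRADIANCE_DARK_OFFSET
    return counts.replace_counts(counts.c - offset)


def gaussian_smooth(values: Sequence[float], sigma: float = 3.0) -> np.ndarray:
    """Gaussian convolution over the photosite grid (reflective boundary);
    sigma is in photosite-index units and sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    values = np.asarray(values, dtype=float)
    if sigma == 0:
        return values.copy()
    return gaussian_filter1d(values, sigma, mode="reflect")


def normalize_area(
    spectrum: CalibratedSpectrum, lo_nm: float = 425.0, hi_nm: float = 650.0
) -> CalibratedSpectrum:
    """Scale so the bin-width-weighted area over [lo, hi] nm equals one.

    Used to compare spectral *shapes* across intensities (e.g. low-light
    spectra against a bright baseline).  Idempotent.
    """
    lam = spectrum.wavelengths
    mask = (lam >= lo_nm) & (lam <= hi_nm)
    if not np.any(mask):
        raise ValueError(f"no photosites fall in the band [{lo_nm}, {hi_nm}] nm")
    area = float(np.sum(spectrum.values[mask] * spectrum.bin_widths[mask]))
    if area == 0:
        raise ValueError("in-band area is zero; cannot normalise")
    return replace(spectrum, values=spectrum.values / area)
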