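"""Generative model of a 288-photosite CMOS line-sensor spectroradiometer.

Emulates the measurement head of a miniature grating spectrometer
(Hamamatsu C12880MA class) read through a 10-bit ADC, together with the
mechanical shutter that selects between closed (dark), radiance and
irradiance (cosine-corrected) light paths.  The simulator is the ground
truth for every round-trip test in the package: it applies a known
responsivity, a known count nonlinearity and a configurable noise model,
and the processing chain must recover the scene from its output.

Signal path for an open-shutter frame::

    ideal_p = S_true,p * scene(lambda_p) * T * B_p          (linear counts)
    photo_p ~ Poisson(ideal_p)                              (shot noise)
    c_p     = round(dark_p + nonlin(photo_p) + stray + read noise)
    c_p     = clip(c_p, 0, adc_levels - 1)

where ``nonlin`` is the inverse of the linearisation response (see
:mod:`ospra.calibration`), so that linearising a simulated frame with the
matching coefficients recovers the ideal linear counts exactly.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Shutter",
    "SensorConfig",
    "RawFrame",
    "SceneSpectrum",
    "simulate_frame",
    "simulate_angle_sweep",
    "dynamic_range",
    "default_sensitivity",
]


class Shutter(str, Enum):
    """Shutter-wheel position: closed (dark), radiance or irradiance port."""

    CLOSED = "closed"
    RADIANCE = "radiance"
    IRRADIANCE = "irradiance"


#: default wavelength polynomial: ~320-850 nm over 288 sites, mild curvature
DEFAULT_WAVELENGTH_COEFFS = (320.0, 2.0, -6.0e-4, 0.0, 0.0, 0.0)


def _polyval(coeffs: Sequence[float], p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    for k, c in enumerate(coeffs):
        out += c * p**k
    return out


def default_sensitivity(wavelengths: np.ndarray, peak: float = 50.0) -> np.ndarray:
    """Smooth single-humped responsivity, counts ms^-1 per (flux unit * nm).

    Peaks near 560 nm and stays strictly positive across the 320-850 nm
    range, loosely following the manufacturer curve for this sensor family.
    """
    return peak * np.exp(-(((wavelengths - 560.0) / 160.0) ** 2))


@dataclass
class SensorConfig:
    """Static description of one simulated spectroradiometer unit.

    ``nonlin_a``/``nonlin_b`` are the ground-truth coefficients of the
    count-rate nonlinearity, in the same parametrisation the calibration
    module fits; set ``nonlin_a=0, nonlin_b=1`` for a perfectly linear
    sensor.  ``dark_mean`` and ``true_sensitivity`` may be scalars or
    per-photosite arrays.
    """

    n_photosites: int = 288
    adc_levels: int = 1024
    usable_levels: int = 900
    min_integration_ms: float = 1.0
    max_integration_ms: float = 30000.0
    dark_mean: float | np.ndarray = 18.0
    dark_sd: float = 1.2
    read_noise_sd: float = 0.8
    shot_noise: bool = True
    true_sensitivity: np.ndarray | None = None
    nonlin_a: float = 0.14231
    nonlin_b: float = 1.06125
    wavelength_coeffs: tuple = DEFAULT_WAVELENGTH_COEFFS
    stray_light_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.usable_levels <= self.adc_levels - 1):
            raise ValueError(
                "usable_levels must satisfy 0 < usable_levels <= adc_levels - 1"
            )
        if self.min_integration_ms > self.max_integration_ms:
            raise ValueError("min_integration_ms must not exceed max_integration_ms")
        if self.dark_sd < 0 or self.read_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        coeffs = tuple(self.wavelength_coeffs)
        if len(coeffs) < 6:
            coeffs = coeffs + (0.0,) * (6 - len(coeffs))
        self.wavelength_coeffs = coeffs[:6]
        lam = self.wavelengths
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelength map must be strictly increasing")
        if self.true_sensitivity is None:
            self.true_sensitivity = default_sensitivity(lam)
        else:
            self.true_sensitivity = np.broadcast_to(
                np.asarray(self.true_sensitivity, dtype=float), (self.n_photosites,)
            ).copy()
        if np.any(self.true_sensitivity < 0):
            raise ValueError("true_sensitivity must be non-negative everywhere")

    @property
    def wavelengths(self) -> np.ndarray:
        """Per-photosite peak wavelength, nm."""
        return _polyval(self.wavelength_coeffs, np.arange(self.n_photosites, dtype=float))

    @property
    def bin_widths(self) -> np.ndarray:
        lam = self.wavelengths
        b = np.empty_like(lam)
        b[1:-1] = (lam[2:] - lam[:-2]) / 2.0
        b[0] = lam[1] - lam[0]
        b[-1] = lam[-1] - lam[-2]
        return b

    @property
    def dark_mean_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.dark_mean, dtype=float), (self.n_photosites,)
        ).copy()

    def noiseless(self) -> "SensorConfig":
        """Copy of this config with every noise source switched off."""
        return replace(self, dark_sd=0.0, read_noise_sd=0.0, shot_noise=False)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    # -- plain-text serialisation (key: value) -------------------------------

    def to_text(self) -> str:
        lines = []
        for key in (
            "n_photosites adc_levels usable_levels min_integration_ms "
            "max_integration_ms dark_sd read_noise_sd shot_noise nonlin_a "
            "nonlin_b stray_light_fraction rng_seed"
        ).split():
            lines.append(f"{key}: {getattr(self, key)!r}")
        lines.append(f"wavelength_coeffs: {list(self.wavelength_coeffs)!r}")
        lines.append(f"dark_mean: {np.asarray(self.dark_mean).tolist()!r}")
        lines.append(f"true_sensitivity: {np.asarray(self.true_sensitivity).tolist()!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SensorConfig":
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            kwargs[key.strip()] = ast.literal_eval(value.strip())
        for key in ("dark_mean", "true_sensitivity", "wavelength_coeffs"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = np.asarray(kwargs[key], dtype=float)
        if "wavelength_coeffs" in kwargs:
            kwargs["wavelength_coeffs"] = tuple(np.asarray(kwargs["wavelength_coeffs"]))
        return cls(**kwargs)


@dataclass
class RawFrame:
    """One ADC readout of all photosites at a single integration time."""

    counts: np.ndarray
    integration_ms: float
    shutter: Shutter

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.shutter = Shutter(self.shutter)


@dataclass
class SceneSpectrum:
    """The 'true' scene imaged by the simulator.

    ``values`` are spectral radiance (W sr^-1 m^-2 nm^-1) or spectral
    irradiance (W m^-2 nm^-1) on a strictly increasing wavelength grid;
    the scene is taken to be zero outside the grid.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    mode: str = "radiance"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have the same shape")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("scene wavelengths must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("scene values must be non-negative")
        if self.mode not in ("radiance", "irradiance"):
            raise ValueError("mode must be 'radiance' or 'irradiance'")

    def at(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.interp(wavelengths, self.wavelengths, self.values, left=0.0, right=0.0)

    def scaled(self, factor: float) -> "SceneSpectrum":
        return SceneSpectrum(self.wavelengths, self.values * factor, self.mode)


def dynamic_range(config: SensorConfig) -> float:
    """Theoretical single-exposure dynamic range (largest usable count over
    the one-count quantisation floor)."""
    return float(config.usable_levels)


def _nonlinearity(config: SensorConfig, linear_counts: np.ndarray) -> np.ndarray:
    """Map ideal linear counts to the sensor's distorted count response."""
    from .calibration import LinearisationModel

    model = LinearisationModel(config.nonlin_a, config.nonlin_b)
    return model.invert_counts(linear_counts, full_scale=float(config.usable_levels))


def ideal_open_counts(
    scene: SceneSpectrum, integration_ms: float, config: SensorConfig
) -> np.ndarray:
    """Noise-free linear photo-signal (counts) before nonlinearity and dark."""
    lam = config.wavelengths
    return config.true_sensitivity * scene.at(lam) * integration_ms * config.bin_widths


def simulate_frame(
    scene: SceneSpectrum | None,
    integration_ms: float,
    shutter: Shutter | str,
    config: SensorConfig,
    rng: np.random.Generator | None = None,
) -> RawFrame:
    """Produce one raw ADC frame.

    With the shutter closed the expected counts are the dark model alone;
    with it open they are dark + nonlinearity(ideal linear signal) + the
    stray-light pedestal.  Counts are rounded and clipped to the ADC range.
    """
    shutter = Shutter(shutter)
    if not (config.min_integration_ms <= integration_ms <= config.max_integration_ms):
        raise ValueError(
            f"integration_ms={integration_ms} outside the permitted range "
            f"[{config.min_integration_ms}, {config.max_integration_ms}] ms"
        )
    if rng is None:
        rng = config.rng()
    n = config.n_photosites
    counts = config.dark_mean_array
    if config.dark_sd > 0:
        counts = counts + rng.normal(0.0, config.dark_sd, n)

    if shutter is not Shutter.CLOSED:
        if scene is None:
            raise ValueError("an open-shutter frame requires a scene")
        if scene.mode != shutter.value:
            raise ValueError(
                f"scene mode {scene.mode!r} does not match shutter state {shutter.value!r}"
            )
        ideal = ideal_open_counts(scene, integration_ms, config)
        photo = rng.poisson(ideal).astype(float) if config.shot_noise else ideal
        counts = counts + _nonlinearity(config, photo)
        if config.stray_light_fraction > 0:
            # scattered light inside the housing: a uniform pedestal that the
            # closed-shutter dark cannot remove
            counts = counts + config.stray_light_fraction * ideal.sum() / n

    if config.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, config.read_noise_sd, n)
    counts = np.clip(np.rint(counts), 0, config.adc_levels - 1).astype(int)
    return RawFrame(counts=counts, integration_ms=float(integration_ms), shutter=shutter)


def amber_led_scene(intensity: float = 1.0) -> SceneSpectrum:
    """Narrow-band amber LED emission (peak 590 nm), irradiance mode."""
    lam = np.arange(500.0, 701.0, 1.0)
    shape = np.exp(-(((lam - 590.0) / 15.0) ** 2))
    return SceneSpectrum(lam, intensity * shape, mode="irradiance")


def simulate_angle_sweep(
    led_intensity: float,
    angles_deg: Sequence[float],
    corrector_quality: float,
    config: SensorConfig,
    integration_ms: float = 10.0,
    n_frames: int = 3,
    rng: np.random.Generator | None = None,
) -> list[list[RawFrame]]:
    """Simulate the cosine-corrector test: a point LED swept in elevation.

    An ideal (Lambertian) diffuser transmits proportionally to cos(theta);
    a degraded corrector of quality ``q`` follows
    ``q*cos(theta) + (1-q)*cos(theta)**2``.  Returns one list of irradiance
    frames per angle.
    """
    if led_intensity < 0:
        raise ValueError("led_intensity must be non-negative")
    if not 0.0 <= corrector_quality <= 1.0:
        raise ValueError("corrector_quality must lie in [0, 1]")
    angles = np.asarray(angles_deg, dtype=float)
    if np.any((angles < 0) | (angles >= 90)):
        raise ValueError("angles must lie in [0, 90) degrees")
    if rng is None:
        rng = config.rng()
    base = amber_led_scene(led_intensity)
    out: list[list[RawFrame]] = []
    for theta in angles:
        c = np.cos(np.deg2rad(theta))
        factor = corrector_quality * c + (1.0 - corrector_quality) * c * c
        scene = base.scaled(factor)
        out.append(
            [
                simulate_frame(scene, integration_ms, Shutter.IRRADIANCE, config, rng)
                for _ in range(n_frames)
            ]
        )
    return out
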