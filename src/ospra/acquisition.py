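"""Exposure planning and scan averaging.

Implements the controller's automated measurement behaviour: doubling
auto-exposure that targets the peak at 0.8 of the saturation ceiling, the
scan-count rule (up to 50 averaged exposures, at least 3, total light time
under one second), interleaved shutter-closed dark frames for long
exposures, and the dark subtraction c_p = mean(l_p) - mean(d_p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .sensor import RawFrame, SceneSpectrum, SensorConfig, Shutter, simulate_frame

__all__ = [
    "ExposurePlan",
    "CountSpectrum",
    "choose_scan_count",
    "auto_expose",
    "acquire",
    "DARK_INTERLEAVE_THRESHOLD_MS",
]

#: exposures longer than this get darks interleaved between light frames
DARK_INTERLEAVE_THRESHOLD_MS = 1000.0

#: total light-collection time for the averaged scans must stay under this
SCAN_BUDGET_MS = 1000.0

MAX_SCANS = 50
MIN_SCANS = 3

#: exposure target: peak dark-free counts as a fraction of the ceiling
EXPOSURE_TARGET = 0.8


@dataclass
class ExposurePlan:
    integration_ms: float
    n_scans: int
    interleave_dark: bool = False
    saturated_at_minimum: bool = False


@dataclass
class CountSpectrum:
    """Dark-subtracted, scan-averaged counts with exposure metadata.

    ``c`` may be negative (noise around the black point is retained, never
    clipped).  ``n_saturated`` counts photosites whose *raw light* counts
    reached the saturation ceiling in any scan, judged before subtraction
    because saturation is invisible afterwards.
    """

    c: np.ndarray
    integration_ms: float
    n_scans: int
    n_saturated: int = 0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)

    def replace_counts(self, c: np.ndarray) -> "CountSpectrum":
        return CountSpectrum(
            np.asarray(c, dtype=float), self.integration_ms, self.n_scans, self.n_saturated
        )


def choose_scan_count(integration_ms: float) -> int:
    """Largest scan count n <= 50 with n * t strictly under one second,
    floored at 3."""
    if integration_ms <= 0:
        raise ValueError("integration_ms must be positive")
    n = math.floor(SCAN_BUDGET_MS / integration_ms)
    if n * integration_ms >= SCAN_BUDGET_MS:
        n -= 1
    return int(min(MAX_SCANS, max(MIN_SCANS, n)))


def _plan_for(integration_ms: float) -> ExposurePlan:
    return ExposurePlan(
        integration_ms=float(integration_ms),
        n_scans=choose_scan_count(integration_ms),
        interleave_dark=integration_ms > DARK_INTERLEAVE_THRESHOLD_MS,
    )


def auto_expose(
    measure_fn: Callable[[float, bool], RawFrame], config: SensorConfig
) -> ExposurePlan:
    """Select the integration time automatically.

    ``measure_fn(integration_ms, dark)`` must return a RawFrame, with the
    shutter closed when ``dark`` is true.  Starting at the minimum
    integration, the routine doubles the exposure until any photosite
    reaches the saturation ceiling (or the maximum exposure is reached),
    then rescales the last unsaturated test so that the peak dark-free
    count would land at 0.8 of the ceiling, clamping to the permitted
    range.  A source that saturates even at the minimum integration is
    reported with ``saturated_at_minimum=True``.
    """
    t = config.min_integration_ms
    frame = measure_fn(t, False)
    if int(np.max(frame.counts)) >= config.usable_levels:
        plan = _plan_for(t)
        plan.saturated_at_minimum = True
        return plan

    t_unsat, frame_unsat = t, frame
    while t < config.max_integration_ms:
        t = min(2.0 * t, config.max_integration_ms)
        frame = measure_fn(t, False)
        if int(np.max(frame.counts)) >= config.usable_levels:
            break
        t_unsat, frame_unsat = t, frame

    dark = measure_fn(t_unsat, True)
    peak = float(np.max(frame_unsat.counts.astype(float) - dark.counts.astype(float)))
    if peak <= 0:
        target = config.max_integration_ms
    else:
        target = t_unsat * EXPOSURE_TARGET * config.usable_levels / peak
    target = min(max(target, config.min_integration_ms), config.max_integration_ms)
    return _plan_for(target)


def acquire(
    scene: SceneSpectrum | None,
    plan: ExposurePlan,
    config: SensorConfig,
    rng: np.random.Generator | None = None,
    shutter: Shutter | str | None = None,
) -> CountSpectrum:
    """Take ``n_scans`` light frames and ``n_scans`` matched dark frames and
    return the dark-subtracted average.

    Long exposures alternate light and dark frames (L, D, L, D, ...) so the
    black-point estimate tracks slow drifts; short ones take the light block
    first.  The averaging order does not change the arithmetic, only the
    temporal pairing it emulates.
    """
    if shutter is None:
        shutter = Shutter(scene.mode) if scene is not None else Shutter.CLOSED
    shutter = Shutter(shutter)
    if rng is None:
        rng = config.rng()

    light = np.empty((plan.n_scans, config.n_photosites))
    dark = np.empty_like(light)
    if plan.interleave_dark:
        for i in range(plan.n_scans):
            light[i] = simulate_frame(scene, plan.integration_ms, shutter, config, rng).counts
            dark[i] = simulate_frame(None, plan.integration_ms, Shutter.CLOSED, config, rng).counts
    else:
        for i in range(plan.n_scans):
            light[i] = simulate_frame(scene, plan.integration_ms, shutter, config, rng).counts
        for i in range(plan.n_scans):
            dark[i] = simulate_frame(None, plan.integration_ms, Shutter.CLOSED, config, rng).counts

    c = light.mean(axis=0) - dark.mean(axis=0)
    n_saturated = int(np.sum(np.any(light >= config.usable_levels, axis=0)))
    return CountSpectrum(
        c=c,
        integration_ms=plan.integration_ms,
        n_scans=plan.n_scans,
        n_saturated=n_saturated,
    )
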