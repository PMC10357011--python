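import numpy as np
import pytest
from hypothesis import settings

from ospra import SceneSpectrum, SensorConfig
from ospra.cli import ideal_calibration
from ospra.sensor import ideal_open_counts

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def noiseless_linear_config():
    """Noise off, identity nonlinearity: the sensor as an ideal integrator."""
    return SensorConfig(nonlin_a=0.0, nonlin_b=1.0).noiseless()


@pytest.fixture
def noiseless_config():
    """Noise off but with the default ground-truth count nonlinearity."""
    return SensorConfig().noiseless()


def broadband_scene(config, peak_rate_counts_per_ms=45.0, mode="radiance"):
    """Smooth broadband scene scaled so the brightest photosite integrates
    ``peak_rate_counts_per_ms`` linear counts per millisecond."""
    lam = config.wavelengths
    scene = SceneSpectrum(lam, 0.3 + 0.2 * np.sin(lam / 80.0) ** 2, mode)
    peak = ideal_open_counts(scene, 1.0, config).max()
    return scene.scaled(peak_rate_counts_per_ms / peak)


def matched_calibration(config, unit_id="sim"):
    """Calibration record equal to the simulator's ground truth."""
    return ideal_calibration(config, unit_id)
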