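"""Evaluate a cosine corrector's angular response.

Sweeps a point LED from 0 to 80 degrees in 10-degree steps over two
simulated diffusers — one ideal (Lambertian) and one degraded — and
tabulates the deviation from the ideal cos(theta) response.
"""

import numpy as np

from ospra import SensorConfig, cosine_deviation, simulate_angle_sweep

cfg = SensorConfig(nonlin_a=0.0, nonlin_b=1.0).noiseless()
angles = np.arange(0.0, 81.0, 10.0)
dark = cfg.dark_mean_array

for quality in (1.0, 0.8):
    sweep = simulate_angle_sweep(0.2, angles, quality, cfg, n_frames=1)
    readings = [float(np.sum(f[0].counts - dark)) for f in sweep]
    table = cosine_deviation(angles, readings)
    print(f"corrector quality {quality}:")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print()
# deviation = 1 at every angle is a perfect Lambertian diffuser; values
# below 1 at shallow angles mean irradiance there will be underestimated
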