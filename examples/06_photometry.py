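"""Luminance and illuminance summaries of calibrated spectra.

Weights a spectrum by the photopic luminous-efficiency curve evaluated on
the unit's own wavelength grid and integrates with K_m = 683 lm W^-1.
"""

import numpy as np

from ospra import (
    CalibratedSpectrum,
    WavelengthMap,
    luminance,
    luminosity_on_grid,
)

wmap = WavelengthMap((320.0, 2.0, -6e-4))
lam = wmap.wavelengths
lf = luminosity_on_grid(wmap)


def spectrum(values, mode):
    return CalibratedSpectrum("demo", "", "", mode, lam,
                              np.asarray(values, float), 10.0, 3, 0, np.zeros_like(lam))


# a 555 nm line of 1 W sr^-1 m^-2 nm^-1 in one bin: the definition of K_m
line = np.where(np.abs(lam - lam[np.argmin(np.abs(lam - 555))]) < 1e-9,
                1.0 / wmap.bin_widths, 0.0)
print(f"1 W sr^-1 m^-2 line at 555 nm -> {luminance(spectrum(line, 'radiance'), lf):.1f} cd m^-2")

# a dim warm broadband source, typical of night-time street lighting
warm = 2e-6 * np.exp(-(((lam - 600) / 90.0) ** 2))
print(f"dim broadband radiance       -> {luminance(spectrum(warm, 'radiance'), lf):.4f} cd m^-2")
print(f"same spectrum as irradiance  -> {luminance(spectrum(warm, 'irradiance'), lf):.4f} lx")
# the first number is ~683 (maximum luminous efficacy); the dim source sits
# in the range of real night-sky and street-light measurements
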