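"""CIE 1931 2-degree color-matching functions and the D65 illuminant.

Abridged 10 nm tables covering 380-780 nm, linearly interpolated onto the
cube's band grid at render time.  Values are the standard published ones at
4-significant-figure precision, which is ample for diagnostic RGB previews.
"""

from __future__ import annotations

import numpy as np

# wavelength (nm), x_bar, y_bar, z_bar
CIE_1931_2DEG = np.array([
    [380, 0.0014, 0.0000, 0.0065],
    [390, 0.0042, 0.0001, 0.0201],
    [400, 0.0143, 0.0004, 0.0679],
    [410, 0.0435, 0.0012, 0.2074],
    [420, 0.1344, 0.0040, 0.6456],
    [430, 0.2839, 0.0116, 1.3856],
    [440, 0.3483, 0.0230, 1.7471],
    [450, 0.3362, 0.0380, 1.7721],
    [460, 0.2908, 0.0600, 1.6692],
    [470, 0.1954, 0.0910, 1.2876],
    [480, 0.0956, 0.1390, 0.8130],
    [490, 0.0320, 0.2080, 0.4652],
    [500, 0.0049, 0.3230, 0.2720],
    [510, 0.0093, 0.5030, 0.1582],
    [520, 0.0633, 0.7100, 0.0782],
    [530, 0.1655, 0.8620, 0.0422],
    [540, 0.2904, 0.9540, 0.0203],
    [550, 0.4334, 0.9950, 0.0087],
    [560, 0.5945, 0.9950, 0.0039],
    [570, 0.7621, 0.9520, 0.0021],
    [580, 0.9163, 0.8700, 0.0017],
    [590, 1.0263, 0.7570, 0.0011],
    [600, 1.0622, 0.6310, 0.0008],
    [610, 1.0026, 0.5030, 0.0003],
    [620, 0.8544, 0.3810, 0.0002],
    [630, 0.6424, 0.2650, 0.0000],
    [640, 0.4479, 0.1750, 0.0000],
    [650, 0.2835, 0.1070, 0.0000],
    [660, 0.1649, 0.0610, 0.0000],
    [670, 0.0874, 0.0320, 0.0000],
    [680, 0.0468, 0.0170, 0.0000],
    [690, 0.0227, 0.0082, 0.0000],
    [700, 0.0114, 0.0041, 0.0000],
    [710, 0.0058, 0.0021, 0.0000],
    [720, 0.0029, 0.0010, 0.0000],
    [730, 0.0014, 0.0005, 0.0000],
    [740, 0.0007, 0.0002, 0.0000],
    [750, 0.0003, 0.0001, 0.0000],
    [760, 0.0002, 0.0001, 0.0000],
    [770, 0.0001, 0.0000, 0.0000],
    [780, 0.0000, 0.0000, 0.0000],
])

# wavelength (nm), relative spectral power (normalized to 100 at 560 nm)
D65_SPD = np.array([
    [380, 49.98], [390, 54.65], [400, 82.75], [410, 91.49], [420, 93.43],
    [430, 86.68], [440, 104.86], [450, 117.01], [460, 117.81], [470, 114.86],
    [480, 115.92], [490, 108.81], [500, 109.35], [510, 107.80], [520, 104.79],
    [530, 107.69], [540, 104.41], [550, 104.05], [560, 100.00], [570, 96.33],
    [580, 95.79], [590, 88.69], [600, 90.01], [610, 89.60], [620, 87.70],
    [630, 83.29], [640, 83.70], [650, 80.03], [660, 80.21], [670, 82.28],
    [680, 78.28], [690, 69.72], [700, 71.61], [710, 74.35], [720, 61.60],
    [730, 69.89], [740, 75.09], [750, 63.59], [760, 46.42], [770, 66.81],
    [780, 63.38],
])


def cmf_on_grid(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Interpolate the 2-degree color-matching functions onto a grid.

    Returns an (n_bands, 3) array with columns x_bar, y_bar, z_bar.
    """
    w = np.asarray(wavelengths_nm, dtype=float)
    out = np.empty((w.size, 3))
    for j in range(3):
        out[:, j] = np.interp(w, CIE_1931_2DEG[:, 0], CIE_1931_2DEG[:, 1 + j])
    return out


def d65_on_grid(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Interpolate the D65 spectral power distribution onto a grid."""
    w = np.asarray(wavelengths_nm, dtype=float)
    return np.interp(w, D65_SPD[:, 0], D65_SPD[:, 1])
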