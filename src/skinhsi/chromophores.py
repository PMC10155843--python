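"""Skin chromophore extinction curves.

The visible reflectance spectrum of skin is shaped chiefly by three
absorbers: eumelanin, oxygenated hemoglobin (HbO2) and deoxygenated
hemoglobin (Hb).  This module embeds compact anchor-point tables of their
relative extinction, approximating the standard published compilations:

* HbO2 — Soret band near 415 nm, the twin alpha/beta bands at 576 and
  542 nm with a valley near 560 nm, then a steep fall past 585 nm to a low
  red tail.
* Hb — Soret band near 430 nm, a single broad band peaking near 556 nm,
  a sharp downward knee through 600 nm, and a weak band near 760 nm.
* Eumelanin — featureless power-law decay (roughly lambda^-3.3), hence
  monotonically decreasing across the visible range.

Curves are tabulated in relative units, linearly interpolated onto the
requested band grid and rescaled so each curve's maximum on that grid is
exactly 1; only curve *shape* matters for the forward model and for the
spectral signatures the reducers should recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BandGrid

__all__ = ["ChromophoreLibrary", "build_chromophore_library", "CHROMOPHORE_NAMES"]

CHROMOPHORE_NAMES = ("melanin", "hbo2", "hb")

# (wavelength nm, relative extinction); anchors are denser around the
# hemoglobin alpha/beta bands so linear interpolation keeps the extrema
# at the tabulated wavelengths.
_HBO2_TABLE = np.array([
    [380, 0.070], [400, 0.550], [410, 0.950], [415, 1.000], [420, 0.620],
    [430, 0.240], [440, 0.085], [450, 0.062], [460, 0.040], [470, 0.031],
    [480, 0.028], [490, 0.030], [500, 0.042], [510, 0.055], [520, 0.073],
    [530, 0.095], [536, 0.105], [542, 0.118], [548, 0.108], [556, 0.082],
    [560, 0.070], [568, 0.086], [576, 0.120], [582, 0.090], [590, 0.035],
    [600, 0.0068], [610, 0.0032], [620, 0.0020], [630, 0.0013],
    [650, 0.00078], [670, 0.00060], [690, 0.00058], [710, 0.00062],
    [730, 0.00078], [750, 0.00110], [780, 0.00130],
])

_HB_TABLE = np.array([
    [380, 0.180], [400, 0.420], [420, 0.650], [425, 0.900], [430, 1.000],
    [435, 0.920], [440, 0.650], [450, 0.240], [460, 0.130], [470, 0.095],
    [480, 0.088], [490, 0.086], [500, 0.088], [510, 0.094], [520, 0.104],
    [530, 0.120], [540, 0.133], [548, 0.140], [556, 0.145], [560, 0.143],
    [568, 0.130], [576, 0.112], [584, 0.090], [592, 0.064], [600, 0.0395],
    [610, 0.0255], [620, 0.0176], [630, 0.0117], [650, 0.0100],
    [670, 0.0083], [690, 0.0063], [710, 0.0048], [730, 0.0040],
    [750, 0.0038], [760, 0.0044], [780, 0.0032],
])

# Power-law decay sampled every 20 nm; strictly decreasing.
_MELANIN_TABLE = np.array([
    [380, 1.0000], [400, 0.8430], [420, 0.7170], [440, 0.6140],
    [460, 0.5290], [480, 0.4595], [500, 0.4010], [520, 0.3518],
    [540, 0.3103], [560, 0.2750], [580, 0.2446], [600, 0.2185],
    [620, 0.1958], [640, 0.1763], [660, 0.1591], [680, 0.1440],
    [700, 0.1307], [720, 0.1190], [740, 0.1090], [760, 0.0994],
    [780, 0.0914],
])

_TABLES = {"melanin": _MELANIN_TABLE, "hbo2": _HBO2_TABLE, "hb": _HB_TABLE}


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Relative extinction curves resampled onto a shared band grid.

    Each curve is nonnegative with maximum exactly 1 on the grid.
    """

    band_grid: BandGrid
    extinction: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.band_grid)
        for name, curve in self.extinction.items():
            if curve.shape != (n,):
                raise ValueError(f"curve '{name}' does not match band grid")
            if np.any(curve < 0):
                raise ValueError(f"curve '{name}' has negative extinction")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.extinction)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.extinction[name]


def build_chromophore_library(band_grid: BandGrid) -> ChromophoreLibrary:
    """Resample the embedded extinction tables onto ``band_grid``.

    Linear interpolation between anchors, then per-curve rescaling to a
    maximum of 1.  Raises ``ValueError`` naming the offending wavelength if
    the grid extends past the tabulated 380-780 nm range.
    """
    w = band_grid.wavelengths
    lo, hi = _MELANIN_TABLE[0, 0], _MELANIN_TABLE[-1, 0]
    if w[0] < lo:
        raise ValueError(f"wavelength {w[0]:g} nm is below the tabulated range ({lo:g} nm)")
    if w[-1] > hi:
        raise ValueError(f"wavelength {w[-1]:g} nm is above the tabulated range ({hi:g} nm)")
    curves = {}
    for name, table in _TABLES.items():
        c = np.interp(w, table[:, 0], table[:, 1])
        curves[name] = c / c.max()
    return ChromophoreLibrary(band_grid=band_grid, extinction=curves)
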