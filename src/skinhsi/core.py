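"""Core data model for skin hyperspectral cubes.

A hyperspectral image (HSI) is a ``rows x cols x bands`` cube holding one
reflectance spectrum per pixel.  This module defines the shared wavelength
axis (:class:`BandGrid`), raw captures with their dark/white reference
frames, normalized reflectance cubes, and the flat pixel-by-band signature
table that every downstream statistical step consumes.

Conventions used throughout the package: pixel coordinates are 0-based and
row-major, rectangles are half-open ``(row0, row1, col0, col1)``, and the
tumor class is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _cie

__all__ = [
    "BandGrid",
    "RawCapture",
    "ReflectanceCube",
    "SignatureTable",
    "normalize_reflectance",
    "flatten",
    "unflatten",
    "crop_roi",
    "cube_to_rgb",
]

#: Physical wavelength range (nm) the data model accepts; matches the
#: sensitivity window of visible-range 2D spectroradiometers.
WAVELENGTH_MIN_NM = 380.0
WAVELENGTH_MAX_NM = 780.0


@dataclass(frozen=True)
class BandGrid:
    """Strictly increasing wavelength axis, in nanometres.

    All spectral objects in the package (cubes, signature tables, extinction
    curves, fitted reducers) share a :class:`BandGrid` so that band indices
    are interchangeable across them.
    """

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("band grid needs at least two wavelengths")
        if not np.all(np.diff(w) > 0):
            raise ValueError("band grid wavelengths must be strictly increasing")
        if w[0] < WAVELENGTH_MIN_NM or w[-1] > WAVELENGTH_MAX_NM:
            raise ValueError(
                f"band grid [{w[0]:g}, {w[-1]:g}] nm outside the supported "
                f"{WAVELENGTH_MIN_NM:g}-{WAVELENGTH_MAX_NM:g} nm window"
            )
        object.__setattr__(self, "wavelengths", w)
        self.wavelengths.setflags(write=False)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.allclose(self.wavelengths, other.wavelengths)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.wavelengths.size, float(self.wavelengths[0]),
                     float(self.wavelengths[-1])))

    def nearest(self, target_nm: float) -> int:
        """Index of the band closest to ``target_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - target_nm)))

    @classmethod
    def default(cls) -> "BandGrid":
        """The package default axis: 311 uniform bands over 420-750 nm.

        311 points across the visible window gives a spacing of about
        1.065 nm, fine enough to resolve the hemoglobin twin peaks.
        """
        return cls(np.linspace(420.0, 750.0, 311))


@dataclass(frozen=True)
class RawCapture:
    """Sensor counts plus the dark-current and white-reference frames.

    ``dark`` and ``white`` may be per-band vectors ``(bands,)`` (spatially
    uniform references) or full per-pixel frames ``(rows, cols, bands)``;
    both broadcast against ``intensity``.
    """

    intensity: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    band_grid: BandGrid

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        if inten.ndim != 3:
            raise ValueError("intensity must be a rows x cols x bands cube")
        if inten.shape[2] != len(self.band_grid):
            raise ValueError("intensity band count does not match band grid")
        for name in ("dark", "white"):
            ref = np.asarray(getattr(self, name), dtype=float)
            if ref.shape not in ((inten.shape[2],), inten.shape):
                raise ValueError(
                    f"{name} frame must be (bands,) or match the cube shape"
                )
            object.__setattr__(self, name, ref)
        object.__setattr__(self, "intensity", inten)


@dataclass
class ReflectanceCube:
    """Normalized reflectance cube with an optional tissue mask."""

    data: np.ndarray
    band_grid: BandGrid
    tissue_mask: np.ndarray | None = None
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("reflectance data must be rows x cols x bands")
        if self.data.shape[2] != len(self.band_grid):
            raise ValueError("band count does not match band grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance cube contains non-finite values")
        if self.tissue_mask is not None:
            m = np.asarray(self.tissue_mask, dtype=bool)
            if m.shape != self.data.shape[:2]:
                raise ValueError("tissue mask shape does not match cube")
            self.tissue_mask = m

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_mask(self, mask: np.ndarray) -> "ReflectanceCube":
        return replace(self, tissue_mask=np.asarray(mask, dtype=bool))


@dataclass
class SignatureTable:
    """Flat ``n_pixels x n_bands`` matrix of spectral signatures.

    Rows are masked pixels in row-major order; ``coords`` keeps the inverse
    mapping so per-pixel predictions can be re-imaged onto the cube.
    ``sample_ids`` is per-row so tables from several samples can be
    concatenated for dataset-scope model fitting.
    """

    spectra: np.ndarray
    coords: np.ndarray
    band_grid: BandGrid
    sample_ids: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be 2-D (pixels x bands)")
        if self.spectra.shape[1] != len(self.band_grid):
            raise ValueError("spectra band count does not match band grid")
        if self.coords.shape != (self.spectra.shape[0], 2):
            raise ValueError("coords must be (n_pixels, 2)")
        if self.sample_ids.shape != (self.spectra.shape[0],):
            raise ValueError("sample_ids must be per-row")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.spectra.shape[0],):
                raise ValueError("labels must be per-row")

    def __len__(self) -> int:
        return int(self.spectra.shape[0])

    @property
    def n_bands(self) -> int:
        return int(self.spectra.shape[1])

    @classmethod
    def concat(cls, tables: Sequence["SignatureTable"]) -> "SignatureTable":
        if not tables:
            raise ValueError("no tables to concatenate")
        grid = tables[0].band_grid
        for t in tables[1:]:
            if t.band_grid != grid:
                raise ValueError("tables have mismatched band grids")
        labels = None
        if all(t.labels is not None for t in tables):
            labels = np.concatenate([t.labels for t in tables])  # type: ignore[misc]
        return cls(
            spectra=np.concatenate([t.spectra for t in tables]),
            coords=np.concatenate([t.coords for t in tables]),
            band_grid=grid,
            sample_ids=np.concatenate([t.sample_ids for t in tables]),
            labels=labels,
        )


def normalize_reflectance(capture: RawCapture, clip: bool = False) -> ReflectanceCube:
    """Recover normalized reflectance r = (I - Ib) / (Iw - Ib).

    ``I`` is the raw intensity, ``Ib`` the dark-current frame and ``Iw`` the
    white-reference frame, applied per pixel per band.  Values outside
    [0, 1] (specular glints, noise) are preserved unless ``clip=True`` —
    silent clipping would bias any variance-based reducer downstream.

    Raises ``ValueError`` listing the offending band indices when the
    denominator ``Iw - Ib`` is not strictly positive somewhere.
    """
    denom = capture.white - capture.dark
    bad = denom <= 0
    if np.any(bad):
        bad_bands = np.unique(np.nonzero(bad)[-1])
        raise ValueError(
            "white reference does not exceed dark current at band indices "
            f"{bad_bands.tolist()}"
        )
    r = (capture.intensity - capture.dark) / denom
    if clip:
        r = np.clip(r, 0.0, 1.0)
    return ReflectanceCube(data=r, band_grid=capture.band_grid)


def flatten(cube: ReflectanceCube) -> SignatureTable:
    """Extract the spectral signatures of tissue pixels, row-major.

    The cube must carry a tissue mask; only masked pixels contribute a row.
    """
    if cube.tissue_mask is None:
        raise ValueError("cube has no tissue mask; set one before flattening")
    rows, cols = np.nonzero(cube.tissue_mask)
    if rows.size == 0:
        raise ValueError("tissue mask is empty")
    return SignatureTable(
        spectra=cube.data[rows, cols, :],
        coords=np.column_stack([rows, cols]),
        band_grid=cube.band_grid,
        sample_ids=np.full(rows.size, cube.sample_id, dtype=object),
    )


def unflatten(
    table: SignatureTable,
    values: np.ndarray,
    shape: tuple[int, int],
    fill: float = 0.0,
) -> np.ndarray:
    """Re-image per-row values onto the ``shape`` spatial grid.

    ``values`` may be per-row scalars ``(n,)`` or vectors ``(n, k)``; the
    output is ``shape`` or ``shape + (k,)`` with ``fill`` off-mask.
    """
    values = np.asarray(values)
    if values.shape[0] != len(table):
        raise ValueError("values row count does not match table")
    out_shape = shape + values.shape[1:]
    out = np.full(out_shape, fill, dtype=values.dtype if values.dtype.kind == "f" else float)
    out[table.coords[:, 0], table.coords[:, 1]] = values
    return out


def crop_roi(cube: ReflectanceCube, rect: tuple[int, int, int, int]) -> ReflectanceCube:
    """Crop a half-open 0-based rectangle ``(row0, row1, col0, col1)``.

    Masks are cropped identically; the result views the same memory.
    """
    r0, r1, c0, c1 = rect
    h, w = cube.data.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"rectangle {rect} is empty or exceeds cube bounds {(h, w)}")
    mask = None if cube.tissue_mask is None else cube.tissue_mask[r0:r1, c0:c1]
    return ReflectanceCube(
        data=cube.data[r0:r1, c0:c1, :],
        band_grid=cube.band_grid,
        tissue_mask=mask,
        sample_id=cube.sample_id,
    )


def cube_to_rgb(cube: ReflectanceCube) -> np.ndarray:
    """Render a reflectance cube to an sRGB preview image in [0, 1].

    Reflectance is integrated against the CIE 1931 2-degree color-matching
    functions under a D65 illuminant, converted XYZ -> sRGB and clipped.
    The grid must span at least 420-700 nm with 10 or more bands.
    """
    w = cube.band_grid.wavelengths
    if len(cube.band_grid) < 10:
        raise ValueError("band grid too sparse for color rendering (<10 bands)")
    if w[0] > 420.0 or w[-1] < 700.0:
        raise ValueError("band grid must cover 420-700 nm for RGB rendering")
    from skimage.color import xyz2rgb

    cmf = _cie.cmf_on_grid(w)
    spd = _cie.d65_on_grid(w)
    weights = cmf * spd[:, None]          # (bands, 3)
    norm = weights[:, 1].sum()            # luminance normalization on this grid
    xyz = np.tensordot(np.clip(cube.data, 0.0, None), weights, axes=([2], [0])) / norm
    return np.clip(xyz2rgb(xyz), 0.0, 1.0)
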