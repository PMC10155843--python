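"""Cube and scene I/O.

Two on-disk containers are supported:

* an HDF5 container (datasets ``raw``, ``dark``, ``white``, ``tissue_mask``,
  ``tumor_mask``, root attribute ``wavelengths_nm``) used for synthetic
  scenes and normalized cubes;
* ENVI header + flat binary pairs (BSQ / BIL / BIP interleaves, wavelength
  list in the header), the lingua franca of hyperspectral tooling.

Binary masks round-trip through PNG as 0/255 images.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from .core import BandGrid, ReflectanceCube
from .synthetic import SceneConfig, SyntheticScene

__all__ = [
    "save_scene", "load_scene",
    "save_cube", "load_cube",
    "write_envi", "read_envi",
    "save_mask_png", "load_mask_png",
]


def save_scene(scene: SyntheticScene, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["wavelengths_nm"] = scene.band_grid.wavelengths
        f.attrs["sample_id"] = scene.sample_id
        f.create_dataset("raw", data=scene.raw_cube, compression="gzip")
        f.create_dataset("dark", data=scene.dark_frame)
        f.create_dataset("white", data=scene.white_frame)
        f.create_dataset("tissue_mask", data=scene.tissue_mask.astype(np.uint8))
        f.create_dataset("tumor_mask", data=scene.tumor_mask.astype(np.uint8))
        f.create_dataset("reflectance", data=scene.reflectance, compression="gzip")
        g = f.create_group("truth_concentrations")
        for name, arr in scene.truth_concentrations.items():
            g.create_dataset(name, data=arr, compression="gzip")


def load_scene(path: str | os.PathLike) -> SyntheticScene:
    with h5py.File(path, "r") as f:
        grid = BandGrid(np.asarray(f.attrs["wavelengths_nm"]))
        return SyntheticScene(
            raw_cube=f["raw"][()],
            dark_frame=f["dark"][()],
            white_frame=f["white"][()],
            tissue_mask=f["tissue_mask"][()].astype(bool),
            tumor_mask=f["tumor_mask"][()].astype(bool),
            truth_concentrations={
                k: v[()] for k, v in f["truth_concentrations"].items()
            },
            reflectance=f["reflectance"][()],
            band_grid=grid,
            config=SceneConfig(
                height=int(f["raw"].shape[0]),
                width=int(f["raw"].shape[1]),
                band_grid=grid,
            ),
            sample_id=str(f.attrs.get("sample_id", "scene")),
        )


def save_cube(cube: ReflectanceCube, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["wavelengths_nm"] = cube.band_grid.wavelengths
        f.attrs["sample_id"] = cube.sample_id
        f.create_dataset("reflectance", data=cube.data, compression="gzip")
        if cube.tissue_mask is not None:
            f.create_dataset("tissue_mask", data=cube.tissue_mask.astype(np.uint8))


def load_cube(path: str | os.PathLike) -> ReflectanceCube:
    with h5py.File(path, "r") as f:
        mask = f["tissue_mask"][()].astype(bool) if "tissue_mask" in f else None
        return ReflectanceCube(
            data=f["reflectance"][()],
            band_grid=BandGrid(np.asarray(f.attrs["wavelengths_nm"])),
            tissue_mask=mask,
            sample_id=str(f.attrs.get("sample_id", "sample")),
        )


# --- ENVI ---------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64,
                12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_envi(cube: ReflectanceCube, base_path: str | os.PathLike,
               interleave: str = "bsq") -> tuple[Path, Path]:
    """Write ``<base>.hdr`` + ``<base>.img`` (float32, little-endian)."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave '{interleave}'")
    base = Path(base_path)
    hdr_path, img_path = base.with_suffix(".hdr"), base.with_suffix(".img")
    data = cube.data.astype("<f4")
    rows, cols, bands = data.shape
    if interleave == "bsq":
        ordered = np.transpose(data, (2, 0, 1))
    elif interleave == "bil":
        ordered = np.transpose(data, (0, 2, 1))
    else:
        ordered = data
    ordered.tofile(img_path)
    wl = ", ".join(f"{v:.4f}" for v in cube.band_grid.wavelengths)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return hdr_path, img_path


def read_envi(hdr_path: str | os.PathLike) -> ReflectanceCube:
    """Read an ENVI header + binary pair into a reflectance cube."""
    hdr_path = Path(hdr_path)
    text = hdr_path.read_text()
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError(f"{hdr_path} is not an ENVI header")
    # Join { ... } blocks onto single lines before parsing key = value pairs.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip().lower()] = value.strip()
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = np.dtype(_ENVI_DTYPES[int(fields["data type"])])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", "0"))
    wl_match = re.search(r"\{([^}]*)\}", fields.get("wavelength", ""))
    if not wl_match:
        raise ValueError("ENVI header lacks a wavelength list")
    wavelengths = np.array([float(v) for v in wl_match.group(1).split(",") if v.strip()])
    img_path = hdr_path.with_suffix(".img")
    if not img_path.exists():
        candidates = [p for p in hdr_path.parent.glob(hdr_path.stem + ".*")
                      if p.suffix not in (".hdr",)]
        if not candidates:
            raise FileNotFoundError(f"no binary companion for {hdr_path}")
        img_path = candidates[0]
    flat = np.fromfile(img_path, dtype=dtype, offset=offset)
    if flat.size != rows * cols * bands:
        raise ValueError("ENVI binary size does not match header dimensions")
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave '{interleave}'")
    return ReflectanceCube(
        data=np.ascontiguousarray(data, dtype=float),
        band_grid=BandGrid(wavelengths),
        sample_id=hdr_path.stem,
    )


def save_mask_png(mask: np.ndarray, path: str | os.PathLike) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask_png(path: str | os.PathLike) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127
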