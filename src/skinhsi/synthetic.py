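"""Synthetic gross-pathology skin HSI scenes.

Real gross-pathology HSI datasets of pigmented skin lesions are clinical
data and rarely shareable, so the package ships a forward simulator whose
output has the statistical structure the analysis pipeline assumes:

* excised tissue imaged surface-up on a dark (near-black) staging surface;
* per-pixel reflectance driven by a Beer-Lambert attenuation model,
  ``r(lambda) = r_base(lambda) * exp(-sum_i c_i(x, y) * eps_i(lambda))``,
  over the melanin / HbO2 / Hb extinction curves;
* an elliptical tumor region in which melanin and total hemoglobin
  concentrations are elevated (the optical correlates of melanocytic
  proliferation and angiogenesis), sized so tumor pixels are a configurable
  fraction of tissue pixels (default 32%);
* acquisition artifacts: small circular blood stains (hemoglobin-boosted,
  outside the tumor) and spectrally flat dark dye marks;
* raw sensor counts reconstructed as ``dark + r * (white - dark) + noise``
  together with the dark-current and white-reference frames, so reflectance
  recovery itself is exercised end to end.

Scenes are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import _cie
from .chromophores import ChromophoreLibrary, build_chromophore_library
from .core import BandGrid, RawCapture, ReflectanceCube, normalize_reflectance

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "generate_scene",
    "generate_dataset",
    "derive_scene_configs",
    "class_mean_spectra",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Concentrations are unitless loadings against the normalized extinction
    curves; multipliers are the tumor-to-healthy concentration ratios.
    ``noise_sd`` is the additive Gaussian noise level expressed in
    reflectance units (it is scaled by the sensor dynamic range when applied
    to raw counts).
    """

    height: int = 72
    width: int = 72
    band_grid: BandGrid = field(default_factory=BandGrid.default)
    tumor_fraction_target: float = 0.32
    tissue_axes_frac: tuple[float, float] = (0.42, 0.44)
    base_concentrations: dict[str, float] = field(
        default_factory=lambda: {"melanin": 0.8, "hbo2": 0.5, "hb": 0.35}
    )
    melanin_multiplier: float = 1.8
    hemoglobin_multiplier: float = 2.2
    spatial_variation_sd: float = 0.12
    n_blood_stains: int = 2
    blood_stain_radius: float = 2.5
    blood_stain_boost: float = 2.5
    n_dye_marks: int = 1
    dye_mark_radius: float = 3.0
    dye_attenuation: float = 0.2
    noise_sd: float = 0.003
    background_reflectance: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.tumor_fraction_target < 1.0):
            raise ValueError("tumor_fraction_target must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.height < 8 or self.width < 8:
            raise ValueError("scene must be at least 8 x 8 pixels")


@dataclass
class SyntheticScene:
    """A simulated capture with its ground truth.

    ``raw_cube`` holds sensor counts; ``dark_frame`` / ``white_frame`` are
    per-band reference vectors.  ``reflectance`` is the noise-free forward
    model output (the quantity reflectance recovery should reproduce), and
    ``truth_concentrations`` the per-pixel chromophore maps that generated it.
    """

    raw_cube: np.ndarray
    dark_frame: np.ndarray
    white_frame: np.ndarray
    tissue_mask: np.ndarray
    tumor_mask: np.ndarray
    truth_concentrations: dict[str, np.ndarray]
    reflectance: np.ndarray
    band_grid: BandGrid
    config: SceneConfig
    sample_id: str = "scene"

    def __post_init__(self) -> None:
        if np.any(self.tumor_mask & ~self.tissue_mask):
            raise ValueError("tumor mask extends outside the tissue mask")
        if not np.all(self.white_frame > self.dark_frame):
            raise ValueError("white frame must exceed dark frame everywhere")

    @property
    def tumor_fraction(self) -> float:
        return float(self.tumor_mask.sum() / self.tissue_mask.sum())

    def to_capture(self) -> RawCapture:
        return RawCapture(
            intensity=self.raw_cube,
            dark=self.dark_frame,
            white=self.white_frame,
            band_grid=self.band_grid,
        )

    def to_reflectance_cube(self, use_truth_mask: bool = True) -> ReflectanceCube:
        """Normalize the raw counts and attach the ground-truth tissue mask."""
        cube = normalize_reflectance(self.to_capture())
        cube.sample_id = self.sample_id
        if use_truth_mask:
            cube.tissue_mask = self.tissue_mask.copy()
        return cube


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    theta: float = 0.0,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """Zero-mean smooth random field with the requested pointwise SD."""
    if sd == 0:
        return np.zeros(shape)
    f = gaussian_filter(rng.standard_normal(shape), sigma=6.0, mode="reflect")
    f -= f.mean()
    s = f.std()
    return f * (sd / s) if s > 0 else f


def _place_disks(
    rng: np.random.Generator,
    n: int,
    radius: float,
    allowed: np.ndarray,
    max_tries: int = 200,
) -> np.ndarray:
    """Union of n disks whose centers fall in the allowed region."""
    mask = np.zeros(allowed.shape, dtype=bool)
    coords = np.argwhere(allowed)
    if coords.size == 0 or n == 0:
        return mask
    placed = 0
    for _ in range(max_tries):
        if placed >= n:
            break
        r, c = coords[rng.integers(len(coords))]
        disk = _ellipse_mask(allowed.shape, (float(r), float(c)), (radius, radius))
        if np.all(allowed[disk]):
            mask |= disk
            placed += 1
    return mask


def generate_scene(config: SceneConfig, sample_id: str = "scene") -> SyntheticScene:
    """Run the Beer-Lambert forward model for one scene.

    Deterministic for a fixed ``config.seed``.  Raises ``ValueError`` when no
    tumor ellipse of the target area fits inside the tissue region.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    grid = config.band_grid
    library = build_chromophore_library(grid)

    # --- geometry ------------------------------------------------------
    jitter = rng.uniform(-0.02, 0.02, size=2)
    center = (h / 2.0 * (1 + jitter[0]), w / 2.0 * (1 + jitter[1]))
    axes = (
        config.tissue_axes_frac[0] * h * rng.uniform(0.95, 1.05),
        config.tissue_axes_frac[1] * w * rng.uniform(0.95, 1.05),
    )
    tissue = _ellipse_mask((h, w), center, axes)
    tissue_area = int(tissue.sum())
    if tissue_area == 0:
        raise ValueError("tissue ellipse has zero area; enlarge the scene")

    target_area = config.tumor_fraction_target * tissue_area
    tumor = None
    for _ in range(200):
        aspect = rng.uniform(0.6, 1.0)
        a_t = np.sqrt(target_area / (np.pi * aspect))
        b_t = aspect * a_t
        theta = rng.uniform(0.0, np.pi)
        tc = (
            center[0] + rng.uniform(-0.25, 0.25) * axes[0],
            center[1] + rng.uniform(-0.25, 0.25) * axes[1],
        )
        cand = _ellipse_mask((h, w), tc, (a_t, b_t), theta)
        if cand.any() and not np.any(cand & ~tissue):
            achieved = cand.sum() / tissue_area
            if abs(achieved - config.tumor_fraction_target) <= 0.05:
                tumor = cand
                break
    if tumor is None:
        raise ValueError(
            "could not place a tumor ellipse of the target area inside the "
            "tissue region; reduce tumor_fraction_target or enlarge the scene"
        )

    # --- chromophore concentration maps --------------------------------
    conc: dict[str, np.ndarray] = {}
    for name, base in config.base_concentrations.items():
        fld = _smooth_field(rng, (h, w), config.spatial_variation_sd)
        c = base * (1.0 + fld)
        np.clip(c, 0.05 * base, None, out=c)
        conc[name] = c
    conc["melanin"][tumor] *= config.melanin_multiplier
    conc["hbo2"][tumor] *= config.hemoglobin_multiplier
    conc["hb"][tumor] *= config.hemoglobin_multiplier

    stain_zone = tissue & ~tumor
    stains = _place_disks(rng, config.n_blood_stains, config.blood_stain_radius, stain_zone)
    conc["hbo2"][stains] *= config.blood_stain_boost
    conc["hb"][stains] *= config.blood_stain_boost

    # --- forward model -------------------------------------------------
    wl = grid.wavelengths
    r_base = 0.55 + 0.10 * (wl - wl[0]) / (wl[-1] - wl[0])
    optical_depth = np.zeros((h, w, len(grid)))
    for name in conc:
        optical_depth += conc[name][:, :, None] * library[name][None, None, :]
    reflectance = r_base[None, None, :] * np.exp(-optical_depth)

    dye = _place_disks(rng, config.n_dye_marks, config.dye_mark_radius, stain_zone & ~stains)
    reflectance[dye] *= config.dye_attenuation
    reflectance[~tissue] = config.background_reflectance
    for name in conc:
        conc[name][~tissue] = 0.0

    # --- sensor model --------------------------------------------------
    dark = 100.0 + 10.0 * np.linspace(0.0, 1.0, len(grid))
    white = dark + 3500.0 * (_cie.d65_on_grid(wl) / 100.0)
    raw = dark + reflectance * (white - dark)
    if config.noise_sd > 0:
        raw = raw + config.noise_sd * (white - dark) * rng.standard_normal(raw.shape)

    return SyntheticScene(
        raw_cube=raw,
        dark_frame=dark,
        white_frame=white,
        tissue_mask=tissue,
        tumor_mask=tumor,
        truth_concentrations=conc,
        reflectance=reflectance,
        band_grid=grid,
        config=config,
        sample_id=sample_id,
    )


def derive_scene_configs(
    n_scenes: int, base_config: SceneConfig, seed: int
) -> list[SceneConfig]:
    """Per-scene configs with deterministic seed and parameter draws.

    Scene-to-scene variability emulates a multi-patient dataset: baseline
    chromophore concentrations jitter by about +/-15% and tumor contrast by
    about +/-10% around the base configuration.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be at least 1")
    ss = np.random.SeedSequence(seed)
    scene_seeds = [int(s) for s in ss.generate_state(n_scenes)]
    rng = np.random.default_rng(ss.spawn(1)[0])
    configs = []
    for i in range(n_scenes):
        base_conc = {
            name: value * float(rng.uniform(0.85, 1.15))
            for name, value in base_config.base_concentrations.items()
        }
        mel_mult = 1.0 + (base_config.melanin_multiplier - 1.0) * float(rng.uniform(0.9, 1.1))
        hem_mult = 1.0 + (base_config.hemoglobin_multiplier - 1.0) * float(rng.uniform(0.9, 1.1))
        configs.append(
            dataclasses.replace(
                base_config,
                base_concentrations=base_conc,
                melanin_multiplier=mel_mult,
                hemoglobin_multiplier=hem_mult,
                seed=scene_seeds[i],
            )
        )
    return configs


def generate_dataset(
    n_scenes: int, base_config: SceneConfig, seed: int
) -> list[SyntheticScene]:
    """Generate ``n_scenes`` labeled scenes sharing one band grid."""
    configs = derive_scene_configs(n_scenes, base_config, seed)
    return [
        generate_scene(cfg, sample_id=f"scene{i:02d}") for i, cfg in enumerate(configs)
    ]


def class_mean_spectra(scene: SyntheticScene) -> tuple[np.ndarray, np.ndarray]:
    """Mean noise-free reflectance spectra of (tumor, healthy-tissue) pixels."""
    healthy = scene.tissue_mask & ~scene.tumor_mask
    return (
        scene.reflectance[scene.tumor_mask].mean(axis=0),
        scene.reflectance[healthy].mean(axis=0),
    )
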