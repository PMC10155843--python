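"""Automatic tissue/background separation.

The staging surface under the specimen is a consistent near-black color, so
background removal works in color space rather than spectrally: the cube is
rendered to RGB, converted to CIE L*a*b*, and the chromaticity (a*, b*)
channels are clustered with K-means.  Any cluster that owns a pixel on the
image's outer one-pixel border is assumed to be background; the remaining
clusters form the tissue mask, which is tidied with binary morphological
closing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing
from skimage.color import rgb2lab
from skimage.morphology import disk
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .core import ReflectanceCube, cube_to_rgb

__all__ = ["MaskingConfig", "rgb_to_lab", "segment_background"]


@dataclass(frozen=True)
class MaskingConfig:
    """Background-removal parameters.

    ``n_color_levels`` color clusters are fitted ``n_runs`` times with fresh
    random initializations and the lowest-inertia solution is kept.
    """

    n_color_levels: int = 6
    n_runs: int = 3
    closing_radius: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_color_levels < 2:
            raise ValueError("need at least two color levels")
        if self.n_runs < 1:
            raise ValueError("need at least one clustering run")


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """CIE L*a*b* (D65, 2-degree observer) from sRGB in [0, 1]."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("rgb values must lie in [0, 1]")
    return rgb2lab(rgb)


def segment_background(
    cube: ReflectanceCube, config: MaskingConfig | None = None
) -> np.ndarray:
    """Tissue mask via K-means color clustering and border merging.

    Returns a boolean mask of tissue pixels.  Raises ``ValueError`` when
    every color cluster touches the border (no foreground found).
    """
    config = config or MaskingConfig()
    lab = rgb_to_lab(cube_to_rgb(cube))
    h, w = lab.shape[:2]
    ab = lab[..., 1:3].reshape(-1, 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(
            n_clusters=config.n_color_levels,
            n_init=config.n_runs,
            random_state=config.seed,
        ).fit(ab)
    labels = km.labels_.reshape(h, w)

    border = np.zeros((h, w), dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    background_clusters = np.unique(labels[border])
    mask = ~np.isin(labels, background_clusters)
    if not mask.any():
        raise ValueError("no foreground found: every color cluster touches the border")
    return binary_closing(mask, structure=disk(config.closing_radius))
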