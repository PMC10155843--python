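import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import skinhsi as sh

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_scene() -> sh.SyntheticScene:
    """Seeded scene at the package-default conditions (72x72, 311 bands)."""
    return sh.generate_scene(sh.SceneConfig(seed=3))


@pytest.fixture(scope="session")
def default_cube(default_scene) -> sh.ReflectanceCube:
    return default_scene.to_reflectance_cube()


@pytest.fixture(scope="session")
def default_table(default_cube) -> sh.SignatureTable:
    return sh.flatten(default_cube)


@pytest.fixture(scope="session")
def small_samples() -> list[sh.Sample]:
    """Six 48x48 labeled samples for cross-validation tests."""
    scenes = sh.generate_dataset(6, sh.SceneConfig(height=48, width=48), seed=4)
    return sh.prepare_samples(scenes)


def make_table(X: np.ndarray, y: np.ndarray | None = None,
               grid: sh.BandGrid | None = None) -> sh.SignatureTable:
    """Wrap a plain matrix as a signature table on a synthetic grid."""
    n, b = X.shape
    grid = grid or sh.BandGrid(np.linspace(420.0, 750.0, b))
    return sh.SignatureTable(
        spectra=X,
        coords=np.column_stack([np.arange(n) // 1000, np.arange(n) % 1000]),
        band_grid=grid,
        sample_ids=np.full(n, "s", dtype=object),
        labels=y,
    )
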