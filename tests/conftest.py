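import numpy as np
import pytest

from maizeskel.cloud import ColoredPointCloud
from maizeskel.synthetic import PlantSpec, make_plant


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cloud(rng):
    """200 random colored points in a unit-ish box."""
    pos = rng.random((200, 3)) * [2.0, 1.0, 1.0]
    col = rng.integers(0, 256, (200, 3))
    return ColoredPointCloud(pos, col)


@pytest.fixture(scope="session")
def easy_plant():
    """A small, clean synthetic plant with ground truth (no pot/outliers)."""
    spec = PlantSpec(seed=11, n_leaves=6, noise_sigma=0.001,
                     points_per_plant=6000)
    return make_plant(spec)


@pytest.fixture(scope="session")
def noiseless_plant():
    """Noise-free plant: every surface point lies exactly on its model."""
    spec = PlantSpec(seed=5, n_leaves=6, noise_sigma=0.0,
                     points_per_plant=6000)
    return make_plant(spec)


@pytest.fixture(scope="session")
def realistic_plant():
    """One plant under study conditions: 4 mm noise, pot, outliers."""
    spec = PlantSpec(seed=42, n_leaves=8, noise_sigma=0.004, pot=True,
                     outlier_fraction=0.01, points_per_plant=10000)
    return make_plant(spec)
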