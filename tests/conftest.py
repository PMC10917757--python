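import numpy as np
import pytest

from forestharm.raster import Grid
from forestharm.synthetic import SceneConfig, make_scene


@pytest.fixture(scope="session")
def small_scene():
    """64x64 scene, small enough for per-pixel loop oracles."""
    return make_scene(SceneConfig(grid_shape=(64, 64), seed=7))


@pytest.fixture(scope="session")
def default_scene():
    """Full-size (240x240, 12-zone) scene used by the integration tests."""
    return make_scene(SceneConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_scene():
    """Scene without pixel noise: per-unit observed/truth biomass ratios
    equal the drawn bias factors exactly."""
    return make_scene(SceneConfig(seed=11, noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def grid(values, **kw):
    return Grid(np.asarray(values, dtype=float), **kw)
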