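import numpy as np
import pytest

from asipipe import SceneConfig, simulate_scene

PIXEL_SIZE = 0.3  # µm/px used throughout the suite


@pytest.fixture(scope="session")
def small_scene():
    """A compact noise-free field reused by read-only tests."""
    cfg = SceneConfig(pixel_size=PIXEL_SIZE, n_cells=25, field_shape=(340, 340),
                      seed=11, true_asi=0.6)
    return simulate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
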