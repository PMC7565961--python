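import numpy as np
import pytest

from cardiomorph import (
    SyntheticScene,
    default_config,
    random_scene,
    render_scene,
    threshold_only_config,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def identity_cfg():
    """Pure-thresholding configuration (no morphology, no box padding)."""
    return threshold_only_config()


@pytest.fixture
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def small_scene():
    """A reproducible 5-cell noise-free scene shared across tests."""
    return random_scene(n_cells=5, seed=7)


@pytest.fixture(scope="session")
def small_scene_rendered(small_scene):
    return render_scene(small_scene)
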