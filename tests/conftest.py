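import numpy as np
import pytest

from camoquant import SceneSpec, calibrate_scene, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scene():
    """One rendered default scene, reused read-only across tests."""
    return generate_scene(SceneSpec(seed=7))


@pytest.fixture(scope="session")
def calibrated_default_scene(default_scene):
    stack, cmap = calibrate_scene(default_scene.raw, default_scene.standards)
    return default_scene, stack, cmap
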