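import numpy as np
import pytest

from centiz import make_template


@pytest.fixture(scope="session")
def template_and_masks():
    """Default 64^3 / 2 mm phantom template with the standard mask set."""
    return make_template(grid_shape=(64, 64, 64), voxel_mm=2.0, seed=0)


@pytest.fixture(scope="session")
def small_template_and_masks():
    """Smaller 52^3 grid for registration-heavy tests."""
    return make_template(grid_shape=(52, 52, 52), voxel_mm=2.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
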