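import numpy as np
import pytest

from hemiscope import GroundTruth, make_label_atlas, make_task_boxcar


@pytest.fixture(scope="session")
def boxcar():
    """Default task: alternating 20 s rest / 20 s move over 6 minutes."""
    return make_task_boxcar(block_s=20.0, total_s=360.0, dt=0.5)


@pytest.fixture(scope="session")
def short_boxcar():
    """Two-minute task for faster signal-level tests."""
    return make_task_boxcar(block_s=20.0, total_s=120.0, dt=0.5)


@pytest.fixture(scope="session")
def atlas():
    return make_label_atlas(shape=(16, 16, 16))


@pytest.fixture()
def truth():
    return GroundTruth(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
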