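import numpy as np
import pytest
from hypothesis import settings

from wanet.synthfundus import SynthConfig, generate_image

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_triple():
    """One deterministic (image, mask, fov) phantom shared across tests."""
    return generate_image(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def small_synth_cfg():
    """A reduced phantom for fast tests."""
    return SynthConfig(image_shape=(96, 96), n_trees=3, branch_depth=3,
                       root_width=3.0, segment_length=18.0, seed=11)
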