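import numpy as np
import pytest

from polsynth import phantom, tasks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Small phantom configuration that tiles into two 32x32 tiles."""
    return tasks.small_phantom_config(tile_side=32, seed=7)


@pytest.fixture
def small_frame(small_config):
    return phantom.generate_frame(small_config, "cancer", small_config.rng())
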