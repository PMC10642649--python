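import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def step_image():
    """32x32 vertical step edge 0|255 between columns 15 and 16."""
    img = np.zeros((32, 32), dtype=np.uint8)
    img[:, 16:] = 255
    return img
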