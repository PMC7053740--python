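import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_images(rng):
    """Small random gray images (various shapes) for oracle comparisons."""
    shapes = [(1, 1), (1, 7), (5, 1), (4, 4), (7, 5), (16, 16)]
    return [rng.integers(0, 256, size=s) for s in shapes]
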