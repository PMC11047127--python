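import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_pair():
    """Two voxels, two classes: the hand-arithmetic loss example."""
    g = np.array([[1.0, 0.0], [0.0, 1.0]])
    p = np.array([[0.8, 0.2], [0.4, 0.6]])
    return g, p
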