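import numpy as np
import pytest

from trabshape import BinaryVolume


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_binary_volume(rng, max_dim=16, p=0.5) -> BinaryVolume:
    dims = tuple(int(d) for d in rng.integers(3, max_dim + 1, size=3))
    return BinaryVolume(rng.random(dims) < p)
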