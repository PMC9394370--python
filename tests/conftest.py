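import numpy as np
import pytest

from ecgcs.preprocess import normalize_batch
from ecgcs.synthetic_data import make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """64 normalized synthetic segments shared by training smoke tests."""
    segs = make_dataset(64, seed=7)
    x, _ = normalize_batch(segs)
    return x
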