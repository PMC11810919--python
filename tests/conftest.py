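import numpy as np
import pytest

from mcaunet import data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """A small 32x32 phantom set for fast training/evaluation tests."""
    spec = data.PhantomSpec(size=(32, 32), fg_fraction_target=0.02, seed=9)
    return data.make_phantom_dataset(24, spec)


@pytest.fixture
def float64_engine():
    """Run the NN engine in float64 for numeric gradient checks."""
    from mcaunet import nn

    old = nn.DEFAULT_DTYPE
    nn.DEFAULT_DTYPE = np.float64
    yield
    nn.DEFAULT_DTYPE = old
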