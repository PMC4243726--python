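import numpy as np
import pytest

from chu9dmap import SyntheticConfig, generate


@pytest.fixture(scope="session")
def synth590():
    """Default synthetic paired sample at the study's size."""
    return generate(SyntheticConfig(n=590, seed=0))


@pytest.fixture(scope="session")
def synth5000():
    """Large synthetic sample for moment checks."""
    return generate(SyntheticConfig(n=5000, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
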