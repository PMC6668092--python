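import numpy as np
import pytest

from slreml import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate synthetic instance shared across stochastic-fit tests."""
    return simulate_dataset(300, 600, h2=0.5, c=3, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
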