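import numpy as np
import pytest

from palm.simulate import simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def case_b_small():
    """A modest Case B replicate shared by several suites."""
    return simulate_dataset("B", M=6000, L=10, seed=7)


@pytest.fixture(scope="session")
def case_a_small():
    return simulate_dataset("A", M=6000, L=10, seed=7)
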