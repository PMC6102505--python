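import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from dnmkit.synthetic import SimulationConfig, simulate_trio_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy cohort shared across read-only tests."""
    config = SimulationConfig(n_trios=4, n_sites=3000, mu=1e-3, seed=11)
    return simulate_trio_dataset(config)


@pytest.fixture(scope="session")
def perfect_dataset():
    """Error-free evidence cohort: every injected DNM is recoverable."""
    config = SimulationConfig(
        n_trios=4, n_sites=5000, mu=1e-3, perfect_calls=True, seed=7
    )
    return simulate_trio_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
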