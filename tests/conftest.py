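import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cdcat

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def q5():
    """The full 300-item, 5-attribute Q-matrix."""
    return cdcat.build_q_matrix(5)


@pytest.fixture(scope="session")
def q3():
    """A small 3-attribute Q-matrix for brute-force-friendly tests."""
    return cdcat.build_q_matrix(3, block_multipliers=(4, 3, 2))


def random_bank(model, q, seed, quality="mix"):
    return cdcat.sample_true_bank(model, quality, q, np.random.default_rng(seed))
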