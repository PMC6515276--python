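import numpy as np
import pytest

from stresswear.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def small_study(default_cfg):
    """A compact study shared across tests: 6 subjects x 3 sessions."""
    return simulate_study(default_cfg, n_subjects=6, sessions_per_subject=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
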