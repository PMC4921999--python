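import warnings

import numpy as np
import pytest

from mobipipe.synth import SessionConfig, generate_session

warnings.filterwarnings("ignore", message="only .* samples")


@pytest.fixture(scope="session")
def small_cfg():
    return SessionConfig().scaled("small")


@pytest.fixture(scope="session")
def tiny_cfg():
    return SessionConfig().scaled("tiny")


@pytest.fixture(scope="session")
def small_session(small_cfg):
    """One noisy small-scale session shared across tests (seed 21)."""
    return generate_session(small_cfg, rng_seed=21)


@pytest.fixture(scope="session")
def small_session_noise_free(small_cfg):
    return generate_session(small_cfg, rng_seed=21, noise=False)


@pytest.fixture(scope="session")
def tiny_session(tiny_cfg):
    return generate_session(tiny_cfg, rng_seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
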