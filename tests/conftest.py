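import numpy as np
import pytest

from lfpdisc import SynthConfig, generate_session


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured session configuration used across tests."""
    return SynthConfig(n_electrodes_per_side=3, n_trials_per_condition=20, seed=7)


@pytest.fixture(scope="session")
def small_session(small_config):
    session, truth = generate_session(small_config)
    return session, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
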