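import numpy as np
import pytest

from twotask2p import SimConfig, generate_session


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_neurons=40, session_minutes=4.0)


@pytest.fixture(scope="session")
def high_snr_config():
    """Small shared baseline and tight gain spread: latent classes are
    cleanly recoverable from mean rates."""
    return SimConfig(
        n_neurons=80, session_minutes=4.0, baseline_scale=0.01, gain_sigma=0.2
    )


@pytest.fixture(scope="session")
def session(small_config):
    return generate_session(small_config, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
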