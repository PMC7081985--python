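import numpy as np
import pytest

from vocolock.synth import SessionConfig, generate_condition_epochs, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact full session (neural + audio) shared across tests."""
    cfg = SessionConfig(
        n_faf_channels=4, n_cn_channels=2, n_calls_per_class=10,
        isolation_fraction=0.7, rng_seed=42,
    )
    return generate_session(cfg, with_audio=True)


@pytest.fixture(scope="session")
def cn_epochs_400():
    """400 epochs/class from a single striatal channel (echolocation carries
    a pre-call high-gamma burst); the workhorse for spectral/decoding tests."""
    cfg = SessionConfig(n_faf_channels=0, n_cn_channels=1, rng_seed=21)
    return generate_condition_epochs(cfg, 400, rng=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
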