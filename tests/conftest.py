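import numpy as np
import pytest

from enosekit import preprocess, simulate


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale mixture-series configuration: 128 sensors, fixed seed."""
    return simulate.dataset1_config(seed=7, n_sensors=128)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Simulated 41-measurement campaign (5 classes) plus raw responses."""
    recordings, labels = simulate.simulate_dataset(
        small_config, simulate.DATASET1_DESIGN
    )
    raw = preprocess.build_response_matrix(recordings, scale=False)
    return recordings, labels, raw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
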