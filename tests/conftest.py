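import numpy as np
import pytest

from oipr.synthetic_data import TaskDesignParams, generate_session


@pytest.fixture(scope="session")
def synthetic_session():
    """One mid-sized synthetic session shared by read-only tests:
    12 complete blocks, 30 neurons, default agent and tuning."""
    trials, spikes = generate_session(
        TaskDesignParams(n_blocks=12), n_neurons=30, seed=20
    )
    return trials, spikes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
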