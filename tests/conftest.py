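import numpy as np
import pytest

import dvmotifs as dm


@pytest.fixture(scope="session")
def small_session():
    """One modest synthetic session shared by read-only tests."""
    task = dm.TaskConfig(n_trials=320)
    trials, responses, gt = dm.simulate_session(task, seed=101)
    return trials, responses, gt


@pytest.fixture(scope="session")
def decoded_session(small_session):
    trials, responses, gt = small_session
    decoder = dm.PopulationDecoder(responses, trials)
    return trials, responses, gt, decoder, decoder.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
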