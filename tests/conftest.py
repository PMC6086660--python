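import numpy as np
import pytest

from emergelp.simulate import SessionConfig, make_session


@pytest.fixture(scope="session")
def emergence_session():
    """One default synthetic emergence session with its ground truth."""
    return make_session(SessionConfig(seed=3))


@pytest.fixture(scope="session")
def quiet_session():
    """Event-free emergence-state recording (null control)."""
    cfg = SessionConfig(seed=4, evoked_probability=0.0, evoked_probability_out=0.0,
                        spontaneous_fraction=0.0, min_events=0)
    return make_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
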