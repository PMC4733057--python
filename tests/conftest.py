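import pytest

from coopnet import SessionConfig, make_fixture_session, simulate_session
from coopnet.simulate import PRESETS


@pytest.fixture(scope="session")
def fixture_session():
    return make_fixture_session()


@pytest.fixture(scope="session")
def small_recipient_only_session():
    """One small simulated recipient-only session, shared across tests."""
    config = SessionConfig(n_participants=12, n_rounds=25,
                           treatment="recipient_only", candidate_sample_size=5)
    return simulate_session(config, PRESETS["recipient_only_default"], seed=7)


@pytest.fixture(scope="session")
def small_reciprocal_session():
    config = SessionConfig(n_participants=12, n_rounds=25,
                           treatment="reciprocal", candidate_sample_size=5)
    return simulate_session(config, PRESETS["reciprocal_default"], seed=11)
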