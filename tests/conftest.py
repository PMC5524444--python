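import numpy as np
import pytest

from metaconf import DesignSpec, ObserverParams, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design():
    return DesignSpec()


@pytest.fixture
def observer():
    return ObserverParams()


@pytest.fixture(scope="session")
def session_trials():
    """One deterministic 1024-trial session shared across read-only tests."""
    return simulate_session(
        DesignSpec(), ObserverParams(), np.random.default_rng(777), participant=1
    )
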