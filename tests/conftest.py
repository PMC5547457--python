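import numpy as np
import pytest

from genomatch import DEFAULT_PARAMS, HEParams, client_setup


@pytest.fixture
def params():
    return DEFAULT_PARAMS


@pytest.fixture
def toy_params():
    """A structurally valid but small ring for cheap protocol tests."""
    return HEParams(N=64, h=8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def default_keys():
    """One key pair at default parameters shared across the session."""
    rng = np.random.default_rng(1618)
    return client_setup(DEFAULT_PARAMS, rng)
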