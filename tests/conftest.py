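import numpy as np
import pytest

from wormnav import default_params


@pytest.fixture(scope="session")
def params():
    """The shipped default parameter set (session-wide, treated read-only)."""
    return default_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
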