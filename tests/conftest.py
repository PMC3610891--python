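import numpy as np
import pytest
from hypothesis import settings

from pmnet.params import preset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    """Calibrated standard parameters."""
    return preset("standard")


@pytest.fixture(scope="session")
def quiet_params(params):
    """Standard parameters with the dynamic noise switched off."""
    return params.replace(noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
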