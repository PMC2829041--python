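import numpy as np
import pytest

from adhesim import base_case, ScalingSpec


@pytest.fixture(scope="session")
def params():
    """Base-case parameter set."""
    return base_case()


@pytest.fixture(scope="session")
def params_high_ecm(params):
    """Monostable-high conditions (k_ecm above the bistable band)."""
    return params.with_overrides(k_ecm=0.3)


@pytest.fixture(scope="session")
def scaling():
    return ScalingSpec(n_star=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
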