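import numpy as np
import pytest

from burstfish import KineticParams


@pytest.fixture(scope="session")
def wt_params():
    """Fitted wild-type rates (per mRNA degradation time)."""
    return KineticParams(k_on=2.7, k_off=3.7, k_prod=1524.0)


@pytest.fixture(scope="session")
def mutant_params():
    """Fitted loss-of-function rates (per mRNA degradation time)."""
    return KineticParams(k_on=0.19, k_off=5.1, k_prod=571.0)


@pytest.fixture(scope="session")
def wt_small():
    """Wild-type switching rates with a desk-scale production rate."""
    return KineticParams(k_on=2.7, k_off=3.7, k_prod=50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
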