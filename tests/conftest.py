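import numpy as np
import pytest

from powerstrain import AthleteProfile, IRParams


@pytest.fixture
def profile():
    """The worked-example athlete: CP 300 W, W' 20 kJ, Pmax 1200 W."""
    return AthleteProfile(cp=300.0, w_prime=20000.0, pmax=1200.0)


@pytest.fixture
def fig6_params():
    """Reference simulation constants: k1=1, k2=1.5, tau1=20 d, tau2=7 d."""
    return IRParams(k1=1.0, k2=1.5, tau1=20.0, tau2=7.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
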