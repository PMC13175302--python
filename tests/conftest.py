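import numpy as np
import pytest

from neuroquant.ogden import OgdenParameters, uniaxial_nominal_stress
from neuroquant.mech_preprocess import HyperelasticCurve


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_curve(mu, alpha, n=100, lam_lo=0.85, lam_hi=1.0, label="none"):
    """Noiseless analytic averaged curve from known parameters."""
    lam = np.linspace(lam_lo, lam_hi, n)
    pzz = uniaxial_nominal_stress(lam, OgdenParameters(mu, alpha))
    return HyperelasticCurve(lam=lam, pzz=pzz, cycle=1, phase="averaged", label=label)


@pytest.fixture
def neo_hookean_curve():
    return make_curve(1000.0, 2.0)
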