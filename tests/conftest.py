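import numpy as np
import pytest

from tddcs.physics import DynamicsParams, OpticalProperties, g1_semi_infinite
from tddcs.synthetic import IRFSpec, make_irf


@pytest.fixture(scope="session")
def irf():
    """High-count synthetic IRF shared across fitting tests."""
    return make_irf(IRFSpec(), N_tot=2e6, seed=7)


@pytest.fixture(scope="session")
def tissue_props():
    return OpticalProperties(mua=0.07, musp=10.0, n=1.4, wavelength=830.0)


@pytest.fixture(scope="session")
def phantom_props():
    """Liquid-phantom optics used in the DCS characterization."""
    return OpticalProperties(mua=0.05, musp=7.0, n=1.33, wavelength=785.0)


@pytest.fixture(scope="session")
def phantom_g1(phantom_props):
    dyn = DynamicsParams(DB=1e-8, beta=0.5)

    def g1f(tau, rho=2.5):
        return g1_semi_infinite(np.asarray(tau, dtype=float), rho, phantom_props, dyn, 785.0)

    return g1f
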