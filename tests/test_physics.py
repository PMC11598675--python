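"""Forward-model tests: TD reflectance, correlation diffusion, Siegert,
Beer's law and Stokes-Einstein."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from tddcs.physics import (
    ChromophoreBasis,
    DynamicsParams,
    Layer,
    LayeredMedium,
    OpticalProperties,
    PhantomDynamics,
    beer_forward,
    beer_invert,
    boundary_coefficient,
    cw_reflectance,
    einstein_db,
    g1_semi_infinite,
    g1_two_layer,
    siegert,
    td_reflectance,
)

C_CM_PER_PS = 0.0299792458


def independent_td_reflectance(rho, t_ps, mua, musp, n):
    """Independent re-coding of the extrapolated-boundary closed form,
    written directly from the formula as the dual-implementation oracle."""
    D = 1.0 / (3.0 * musp)
    v = C_CM_PER_PS / n
    r_eff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    A = (1 + r_eff) / (1 - r_eff)
    z0 = 1.0 / musp
    zb = 2.0 * A * D
    out = []
    for t in np.atleast_1d(t_ps):
        if t <= 0:
            out.append(0.0)
            continue
        q = 4.0 * D * v * t
        pref = 0.5 * (np.pi * q) ** -1.5 * t**-1.0
        term = z0 * np.exp(-(z0**2) / q) + (z0 + 2 * zb) * np.exp(-((z0 + 2 * zb) ** 2) / q)
        out.append(pref * np.exp(-mua * v * t - rho**2 / q) * term)
    return np.asarray(out)


class TestTdReflectance:
    def test_causality_and_nonnegativity(self, tissue_props):
        t = np.linspace(-500.0, 8000.0, 600)
        r = td_reflectance(2.5, t, tissue_props)
        assert np.all(r[t <= 0] == 0.0)
        assert np.all(r >= 0.0)

    def test_absorption_factorization_exact(self):
        """R(t; mua) = R(t; 0) exp(-mua v t) channel by channel."""
        t = np.linspace(10.0, 9000.0, 700)
        p = OpticalProperties(mua=0.13, musp=8.0, n=1.4)
        p0 = OpticalProperties(mua=0.0, musp=8.0, n=1.4)
        lhs = td_reflectance(2.0, t, p)
        rhs = td_reflectance(2.0, t, p0) * np.exp(-p.mua * p.v * t)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-13)

    def test_dual_implementation_oracle(self):
        p = OpticalProperties(mua=0.1, musp=10.0, n=1.4)
        got = td_reflectance(2.5, np.array([1000.0]), p)
        want = independent_td_reflectance(2.5, 1000.0, 0.1, 10.0, 1.4)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_time_integral_matches_cw(self, tissue_props):
        """Self-consistency: integral of the TD curve equals the CW form."""
        total = quad(
            lambda t: td_reflectance(2.5, np.array([t]), tissue_props)[0], 0, 5e4, limit=300
        )[0]
        assert total == pytest.approx(cw_reflectance(2.5, tissue_props), rel=1e-3)

    def test_rejects_nonphysical(self):
        with pytest.raises(ValueError):
            OpticalProperties(mua=-0.1, musp=10.0)
        with pytest.raises(ValueError):
            OpticalProperties(mua=0.1, musp=0.0)
        with pytest.raises(ValueError):
            td_reflectance(-1.0, np.array([100.0]), OpticalProperties(mua=0.1, musp=10.0))


class TestG1:
    def test_normalization_and_static_limits(self, phantom_props):
        tau = np.logspace(-8, -2, 60)
        assert g1_semi_infinite([0.0], 2.5, phantom_props, DynamicsParams(DB=1e-8))[0] == 1.0
        static = g1_semi_infinite(tau, 2.5, phantom_props, DynamicsParams(DB=0.0))
        np.testing.assert_allclose(static, 1.0)

    def test_monotone_nonincreasing_bounded(self, phantom_props):
        tau = np.logspace(-8, -1, 200)
        g = g1_semi_infinite(tau, 2.5, phantom_props, DynamicsParams(DB=1e-8))
        assert np.all(np.diff(g) <= 1e-15)
        assert np.all((g >= 0) & (g <= 1))

    def test_dual_implementation_oracle(self, phantom_props):
        """Direct re-coding of the CW correlation-diffusion Green's-function
        ratio at tau = 1 us."""
        p = phantom_props
        tau = 1e-6
        k0 = 2 * np.pi * p.n / (785e-7)
        D = 1 / (3 * p.musp)
        A = boundary_coefficient(p.n)
        z0, zb = 1 / p.musp, 2 * A * D
        r1 = np.sqrt(2.5**2 + z0**2)
        r2 = np.sqrt(2.5**2 + (z0 + 2 * zb) ** 2)

        def G(k):
            return np.exp(-k * r1) / r1 - np.exp(-k * r2) / r2

        kd = np.sqrt(3 * p.mua * p.musp + 6 * p.musp**2 * k0**2 * 1e-8 * tau)
        want = G(kd) / G(np.sqrt(3 * p.mua * p.musp))
        got = g1_semi_infinite([tau], 2.5, p, DynamicsParams(DB=1e-8), 785.0)[0]
        assert got == pytest.approx(want, rel=1e-10)

    def test_rejects_negative_db(self, phantom_props):
        with pytest.raises(ValueError):
            DynamicsParams(DB=-1e-9)


class TestTwoLayer:
    def test_homogeneous_limit(self, phantom_props, phantom_g1):
        dyn = DynamicsParams(DB=1e-8)
        med = LayeredMedium(
            (Layer(1.0, phantom_props, dyn), Layer(np.inf, phantom_props, dyn)), rho=2.5
        )
        tau = np.logspace(-7, -3, 40)
        g2l = g1_two_layer(tau, med, 785.0)
        g1 = phantom_g1(tau)
        sel = g1 > 0.01
        np.testing.assert_allclose(g2l[sel], g1[sel], rtol=0.01)

    def test_thick_upper_layer_limit(self, phantom_props, phantom_g1):
        """A >= 30 mm top layer hides the (different) bottom layer."""
        med = LayeredMedium(
            (
                Layer(3.0, phantom_props, DynamicsParams(DB=1e-8)),
                Layer(np.inf, phantom_props, DynamicsParams(DB=8e-8)),
            ),
            rho=2.5,
        )
        tau = np.logspace(-7, -3, 40)
        g2l = g1_two_layer(tau, med, 785.0)
        g1 = phantom_g1(tau)
        sel = g1 > 0.01
        assert np.max(np.abs(g2l[sel] - g1[sel])) < 0.01

    def test_short_distance_weighs_upper_layer(self, phantom_props):
        """Homogeneous fits to bilayer curves: the short-distance fit lands
        closer to the (faster) upper layer, the long-distance fit closer to
        the bottom layer."""
        from tddcs.correlator import CorrelationCurve
        from tddcs.dcsfit import fit_g2

        up, lo = 3e-8, 1e-8
        tau = np.logspace(-7, -2.2, 120)
        fitted = {}
        for rho in (1.5, 2.5):
            med = LayeredMedium(
                (
                    Layer(0.5, phantom_props, DynamicsParams(DB=up)),
                    Layer(np.inf, phantom_props, DynamicsParams(DB=lo)),
                ),
                rho=rho,
            )
            g1 = g1_two_layer(tau, med, 785.0)
            curve = CorrelationCurve(lags=tau, g2=1 + 0.5 * g1**2, count_rate=1e5)
            fitted[rho] = fit_g2(curve, rho, phantom_props).DB
        assert lo < fitted[2.5] < fitted[1.5] < up
        assert abs(fitted[1.5] - up) < abs(fitted[2.5] - up)

    def test_validates_layer_count_and_geometry(self, phantom_props):
        dyn = DynamicsParams(DB=1e-8)
        with pytest.raises(ValueError):
            LayeredMedium((Layer(1.0, phantom_props, dyn),), rho=2.5)
        with pytest.raises(ValueError):
            g1_two_layer(
                [1e-6],
                LayeredMedium(
                    (
                        Layer(1.0, phantom_props, dyn),
                        Layer(1.0, phantom_props, dyn),
                        Layer(np.inf, phantom_props, dyn),
                    ),
                    rho=2.5,
                ),
            )


class TestSiegert:
    @pytest.mark.parametrize(
        "g1,beta,want",
        [(1.0, 0.5, 1.5), (0.0, 0.3, 1.0), (0.6, 0.5, 1.18)],
    )
    def test_values(self, g1, beta, want):
        assert siegert(np.array([g1]), beta)[0] == pytest.approx(want)

    def test_rejects_bad_beta(self):
        with pytest.raises(ValueError):
            siegert(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            siegert(np.array([1.0]), 1.5)


class TestBeer:
    def test_zero_concentrations(self):
        mua = beer_forward(0.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            beer_invert(mua[0], mua[1])

    def test_round_trip(self):
        mua = beer_forward(50.0, 25.0)
        hbo2, hhb, thb, sto2 = beer_invert(mua[0], mua[1])
        assert hbo2 == pytest.approx(50.0, rel=1e-9)
        assert hhb == pytest.approx(25.0, rel=1e-9)
        assert thb == pytest.approx(75.0, rel=1e-9)
        assert sto2 == pytest.approx(100 * 50 / 75, rel=1e-9)

    def test_against_cramers_rule(self):
        """Hand inversion of the shipped 2x2 extinction system."""
        basis = ChromophoreBasis()
        E = basis.E
        mua685, mua830 = 0.12, 0.11
        det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
        hbo2_hand = (mua685 * E[1, 1] - mua830 * E[0, 1]) / det
        hhb_hand = (E[0, 0] * mua830 - E[1, 0] * mua685) / det
        hbo2, hhb, _, _ = beer_invert(mua685, mua830)
        assert hbo2 == pytest.approx(hbo2_hand, rel=1e-12)
        assert hhb == pytest.approx(hhb_hand, rel=1e-12)

    def test_rejects_singular_basis(self):
        with pytest.raises(ValueError):
            ChromophoreBasis(E=np.array([[1.0, 2.0], [2.0, 4.0]]))


class TestEinstein:
    def test_reference_value(self):
        """Water at 20 C, 50 nm radius particles."""
        db = einstein_db(PhantomDynamics(T_abs=293.15, eta=1.0016e-3, r=50e-9))
        assert db == pytest.approx(4.29e-12, rel=2e-3)

    @given(
        T=st.floats(250.0, 400.0),
        eta=st.floats(1e-4, 1e-1),
        r=st.floats(1e-9, 1e-6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_exact_proportionalities(self, T, eta, r):
        base = einstein_db(PhantomDynamics(T_abs=T, eta=eta, r=r))
        assert einstein_db(PhantomDynamics(T_abs=2 * T, eta=eta, r=r)) == pytest.approx(2 * base)
        assert einstein_db(PhantomDynamics(T_abs=T, eta=2 * eta, r=r)) == pytest.approx(base / 2)
        assert einstein_db(PhantomDynamics(T_abs=T, eta=eta, r=2 * r)) == pytest.approx(base / 2)

    def test_glycerol_trend(self):
        """Monotone viscosity increase gives monotone DB decrease."""
        etas = [1.0e-3, 1.3e-3, 1.8e-3, 2.5e-3]  # ~0-30% glycerol
        dbs = [einstein_db(PhantomDynamics(293.15, e, 50e-9)) for e in etas]
        assert all(a > b for a, b in zip(dbs, dbs[1:]))
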