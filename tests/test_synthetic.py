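"""Synthetic-instrument tests: seed determinism, IRF/DTOF statistics,
Born perturbation behavior and speckle-stream statistics."""

import numpy as np
import pytest

from tddcs.dtof import DTOF, GateSpec, irf_descriptors
from tddcs.physics import OpticalProperties, boundary_coefficient
from tddcs.protocols import analyze_inclusion_scan, analyze_selectivity
from tddcs.synthetic import (
    IRFSpec,
    layer_pathlength,
    make_irf,
    simulate_dtof,
    simulate_inclusion_scan,
    simulate_selectivity_dataset,
    simulate_speckle_tags,
)


class TestSeedDeterminism:
    def test_irf_and_dtof_bit_identical(self, tissue_props):
        a = make_irf(IRFSpec(), N_tot=1e5, seed=42)
        b = make_irf(IRFSpec(), N_tot=1e5, seed=42)
        np.testing.assert_array_equal(a.histogram.counts, b.histogram.counts)
        d1 = simulate_dtof(tissue_props, 2.5, a, N_target=1e5, seed=9)
        d2 = simulate_dtof(tissue_props, 2.5, b, N_target=1e5, seed=9)
        np.testing.assert_array_equal(d1.counts, d2.counts)

    def test_speckle_streams_bit_identical(self, phantom_g1):
        a = simulate_speckle_tags(phantom_g1, 2e4, 0.5, beta=0.5, seed=5)
        b = simulate_speckle_tags(phantom_g1, 2e4, 0.5, beta=0.5, seed=5)
        np.testing.assert_array_equal(a.streams[0].timestamps, b.streams[0].timestamps)


class TestMakeIrf:
    def test_pure_gaussian_fwhm(self):
        spec = IRFSpec(fwhm=200.0, tail_weights=(0.0, 0.0), background_ap=0.0)
        irf = make_irf(spec, N_tot=2e6, seed=1)
        assert irf.fwhm == pytest.approx(200.0, abs=2 * 9.77)

    def test_total_counts_poisson(self):
        spec = IRFSpec(background_ap=0.0)
        irf = make_irf(spec, N_tot=1e6, seed=2)
        assert irf.histogram.total == pytest.approx(1e6, abs=4 * np.sqrt(1e6))

    def test_tail_shifts_center_of_mass_per_first_moment(self):
        """Convolving with the double-exponential tail moves the CoM by the
        kernel mean sum(w_i tau_i)."""
        base = IRFSpec(tail_weights=(0.0, 0.0), background_ap=0.0)
        tailed = IRFSpec(tail_taus=(150.0, 700.0), tail_weights=(0.2, 0.03), background_ap=0.0)
        kw = dict(N_tot=5e6, seed=3)
        com0 = irf_descriptors(make_irf(base, **kw).histogram, support_frac=1e-5)[1]
        com1 = irf_descriptors(make_irf(tailed, **kw).histogram, support_frac=1e-5)[1]
        want = 0.2 * 150.0 + 0.03 * 700.0
        assert com1 - com0 == pytest.approx(want, abs=8.0)

    def test_secondary_reflection_peak(self):
        spec = IRFSpec(reflection=(2000.0, 0.02), background_ap=0.0)
        irf = make_irf(spec, N_tot=5e6, seed=4)
        c = irf.histogram.counts.astype(float)
        ipk = int(np.argmax(c))
        sec = ipk + int(round(2000.0 / 9.77))
        local = c[sec - 5 : sec + 6].max()
        assert local > 5 * c[sec + 40 : sec + 60].mean()


class TestSimulateDtof:
    def test_total_counts(self, irf, tissue_props):
        d = simulate_dtof(tissue_props, 2.5, irf, N_target=5e5, seed=6)
        assert d.total == pytest.approx(5e5, abs=4 * np.sqrt(5e5))

    def test_high_absorption_approaches_irf_shape(self, irf):
        """At large mua the medium response collapses toward the IRF."""
        p_hi = OpticalProperties(mua=1.5, musp=10.0, n=1.4, wavelength=830.0)
        d = simulate_dtof(p_hi, 1.0, irf, N_target=1e6, seed=7)
        _, com_d, fwhm_d = irf_descriptors(d)
        assert fwhm_d < 2.0 * irf.fwhm


class TestLayerPathlength:
    def test_total_pathlength_identity(self, tissue_props):
        """Integrated over all depths the partial pathlength is v t."""
        zb = 2 * boundary_coefficient(tissue_props.n) * tissue_props.D
        t = np.array([500.0, 1000.0, 2000.0, 4000.0])
        L = layer_pathlength(-zb, 15.0, t, 2.5, tissue_props)
        np.testing.assert_allclose(L, tissue_props.v * t, rtol=2e-3)

    def test_late_photons_go_deeper(self, tissue_props):
        t = np.array([500.0, 1500.0, 3000.0])
        frac_deep = layer_pathlength(1.0, 10.0, t, 2.5, tissue_props) / (tissue_props.v * t)
        assert np.all(np.diff(frac_deep) > 0)


class TestInclusionScan:
    GATES = GateSpec([(500.0, 1000.0), (2000.0, 2500.0)], reference="peak")

    def test_zero_strength_zero_contrast(self, irf):
        p = OpticalProperties(mua=0.1, musp=10.0, n=1.33, wavelength=830.0)
        sim = simulate_inclusion_scan(
            p, 2.5, irf, positions=[0.5, 1.5], scan="z", dmua_v=0.0,
            gates=self.GATES, noiseless=True, seed=1,
        )
        scan = analyze_inclusion_scan(sim)
        np.testing.assert_allclose(scan.contrast, 0.0, atol=1e-12)

    def test_lateral_scan_symmetry(self, irf):
        p = OpticalProperties(mua=0.1, musp=10.0, n=1.33, wavelength=830.0)
        x = np.arange(-3.0, 3.01, 0.25)
        sim = simulate_inclusion_scan(
            p, 2.5, irf, positions=x, scan="x", fixed_depth=1.5,
            gates=self.GATES, noiseless=True, seed=2,
        )
        scan = analyze_inclusion_scan(sim)
        np.testing.assert_allclose(scan.contrast, scan.contrast[::-1], rtol=1e-8, atol=1e-12)

    def test_gate_ordering_vs_depth(self, irf):
        """Shallow inclusions: early gates dominate; deep inclusions: late
        gates dominate; early-gate contrast vanishes at shallower depth."""
        p = OpticalProperties(mua=0.1, musp=10.0, n=1.33, wavelength=830.0)
        z = np.arange(0.1, 3.01, 0.2)
        sim = simulate_inclusion_scan(
            p, 2.5, irf, positions=z, scan="z", gates=self.GATES, noiseless=True, seed=3
        )
        c = analyze_inclusion_scan(sim).contrast
        early, late = c[:, 0], c[:, 1]
        assert np.all(early[z <= 0.4] >= late[z <= 0.4])
        assert np.all(late[z >= 1.2] >= early[z >= 1.2])

        def vanish(curve):
            """First depth past the peak where the contrast decays below 1%
            of its maximum (inf if it survives the whole scan)."""
            thr = 0.01 * curve.max()
            idx = np.nonzero((curve < thr) & (z > z[np.argmax(curve)]))[0]
            return z[idx[0]] if len(idx) else np.inf

        assert vanish(early) < vanish(late)

    def test_cnr_drops_when_contrast_vanishes(self, irf):
        p = OpticalProperties(mua=0.1, musp=10.0, n=1.33, wavelength=830.0)
        z = np.arange(0.2, 3.01, 0.4)
        sim = simulate_inclusion_scan(
            p, 2.5, irf, positions=z, scan="z", gates=self.GATES, seed=4, N_target=5e6
        )
        scan = analyze_inclusion_scan(sim)
        late = scan.cnr[:, 1]
        assert late[0] > 10.0
        assert late[-1] < late[0] / 5.0


class TestSelectivity:
    def test_orderings(self, irf):
        """Late gates and larger rho are more selective for deep changes."""
        p = OpticalProperties(mua=0.15, musp=10.0, n=1.33, wavelength=830.0)
        gates = GateSpec([(500.0, 1000.0), (2000.0, 2500.0)], reference="peak")
        S = {}
        for rho in (1.5, 2.5):
            sim = simulate_selectivity_dataset(
                p, rho, irf, dmua_grid=[0.01, 0.03, 0.05, 0.1], gates=gates, noiseless=True, seed=5
            )
            S[rho] = analyze_selectivity(sim).S
        # late > early in the moderate-perturbation regime (at very large
        # dmua the late-gate superficial contrast saturates and the curves
        # may cross, as in the measured selectivity-vs-dmua trends)
        for rho in (1.5, 2.5):
            assert np.all(S[rho][:3, 1] > S[rho][:3, 0])
        assert np.all(S[2.5] > S[1.5])

    def test_small_perturbation_limit_finite(self, irf):
        p = OpticalProperties(mua=0.15, musp=10.0, n=1.33, wavelength=830.0)
        gates = GateSpec([(500.0, 1000.0), (2000.0, 2500.0)], reference="peak")
        sim = simulate_selectivity_dataset(
            p, 2.5, irf, dmua_grid=[1e-4, 0.01], gates=gates, noiseless=True, seed=6
        )
        r = analyze_selectivity(sim)
        assert np.all(np.isfinite(r.S))
        # the dmua -> 0 limit approaches the gate-sensitivity ratio smoothly
        np.testing.assert_allclose(r.S[0], r.S[1], rtol=0.1)


class TestSpeckleStatistics:
    def test_static_medium_is_poisson(self):
        """DB = 0 limit: constant intensity, photon counts pass a Poisson
        dispersion test and g2 = 1."""
        sim = simulate_speckle_tags(
            lambda tau: np.ones_like(np.asarray(tau, dtype=float)),
            count_rate=5e4, duration=4.0, beta=0.5, seed=8,
        )
        ts = sim.streams[0].timestamps
        counts = np.bincount((ts // 10**9).astype(int), minlength=4000)[:4000]  # 1 ms bins
        dispersion = counts.var(ddof=1) / counts.mean()
        assert dispersion == pytest.approx(1.0, abs=0.1)

    def test_rate_invariance_of_g2(self, phantom_g1):
        from tddcs.correlator import CorrelatorConfig, multitau_g2

        cfg = CorrelatorConfig(octaves=10)
        plateaus = []
        for rate, seed in ((2e4, 9), (4e4, 10)):
            sim = simulate_speckle_tags(phantom_g1, rate, 2.0, beta=0.5, seed=seed)
            curve = multitau_g2(sim.streams[0], cfg)
            plateaus.append(np.mean(curve.g2[:3]) - 1.0)
        assert plateaus[0] == pytest.approx(plateaus[1], abs=0.08)

    def test_beta_request_validation(self, phantom_g1):
        with pytest.raises(ValueError):
            simulate_speckle_tags(phantom_g1, 1e4, 1.0, beta=1.5)
        with pytest.raises(ValueError):
            simulate_speckle_tags(phantom_g1, 10.0, 1.0, beta=0.5)  # too few photons
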