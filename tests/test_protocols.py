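"""Protocol-statistics tests: the gated contrast/CNR/selectivity algebra,
noise scans, stability, reproducibility and linearity analysis."""

import numpy as np
import pandas as pd
import pytest

from tddcs.protocols import (
    NoiseScanResult,
    dcs_noise_scan,
    medphot_linearity,
    medphot_noise_scan,
    neuropt_cnr,
    neuropt_contrast,
    neuropt_selectivity,
    reproducibility_cv,
    scan_fwhm,
    stability_metrics,
)


class TestContrastAlgebra:
    def test_contrast_values(self):
        assert neuropt_contrast(100.0, 100.0) == 0.0
        assert neuropt_contrast(100.0 / np.e, 100.0) == pytest.approx(1.0)
        assert neuropt_contrast(90000.0, 100000.0) == pytest.approx(0.10536, abs=1e-5)
        assert neuropt_contrast(90000.0, 100000.0, base="10") == pytest.approx(
            np.log10(10 / 9), rel=1e-9
        )
        with pytest.raises(ValueError):
            neuropt_contrast(0.0, 100.0)

    def test_cnr(self):
        reps = np.log(np.array([1.00e5, 1.02e5, 0.98e5]))
        sigma = np.std(reps, ddof=1)
        assert neuropt_cnr(0.1, reps) == pytest.approx(0.1 / sigma)
        with pytest.raises(ZeroDivisionError):
            neuropt_cnr(0.1, np.array([np.log(1e5)] * 3))
        with pytest.raises(ValueError):
            neuropt_cnr(0.1, np.array([1.0]))

    def test_cnr_delta_method(self):
        """For Poisson gate counts, sigma[log N] ~ N^-1/2, so CNR ~ C sqrt(N)."""
        rng = np.random.default_rng(8)
        N0 = 1e6
        counts = rng.poisson(N0, size=200)
        C = 0.1
        cnr = neuropt_cnr(C, np.log(counts))
        assert cnr == pytest.approx(C * np.sqrt(N0), rel=0.15)

    def test_selectivity(self):
        assert neuropt_selectivity(0.2, 0.2) == pytest.approx(1.0)
        # deep-over-superficial orientation
        assert neuropt_selectivity(0.1, 0.3) == pytest.approx(3.0)
        with pytest.raises(ZeroDivisionError):
            neuropt_selectivity(0.0, 0.1)


class TestScanFwhm:
    def test_triangle(self):
        x = np.linspace(-4, 4, 161)
        w = 1.5
        c = np.clip(1 - np.abs(x) / w, 0, None)
        assert scan_fwhm(x, c) == pytest.approx(w, abs=0.01)

    def test_translation_invariance(self):
        x = np.linspace(-4, 4, 161)
        c0 = np.clip(1 - np.abs(x) / 1.5, 0, None)
        c1 = np.clip(1 - np.abs(x - 0.8) / 1.5, 0, None)
        assert scan_fwhm(x, c1) == pytest.approx(scan_fwhm(x, c0), abs=0.02)

    def test_no_peak(self):
        with pytest.raises(ValueError):
            scan_fwhm(np.arange(5.0), np.arange(5.0))


class TestNoiseScans:
    @staticmethod
    def _constructed(levels, coeff=300.0, exponent=-0.5):
        """Fit results whose sample CV follows coeff * N^exponent exactly."""
        out = {}
        for N in levels:
            cv = coeff * N**exponent / 100.0  # fractional
            m = 0.07
            d = cv * m / np.sqrt(2.5)  # sd of [m-2d..m+2d] is d*sqrt(2.5)
            out[N] = [m - 2 * d, m - d, m, m + d, m + 2 * d]
        return out

    def test_constructed_power_law(self):
        levels = [1e4, 3e4, 1e5, 3e5, 1e6]
        scan = medphot_noise_scan(self._constructed(levels))
        assert scan.slope == pytest.approx(-0.5, abs=1e-6)
        assert scan.r_squared == pytest.approx(1.0, abs=1e-9)
        # closed-form threshold: 300 N^-1/2 = 3 -> N = 1e4
        assert scan.level_at_cv(3.0) == pytest.approx(1e4, rel=1e-6)
        assert scan.level_at_cv(3.0, method="interp") == pytest.approx(1e4, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            medphot_noise_scan(self._constructed([1e4, 1e5]))
        bad = self._constructed([1e4, 1e5, 1e6])
        bad[1e4] = bad[1e4][:3]
        with pytest.raises(ValueError):
            medphot_noise_scan(bad)

    def test_dcs_scan_exact_cv(self):
        rng = np.random.default_rng(9)
        db = {}
        for rate, cv in [(1e4, 0.2), (4e4, 0.05), (1.6e5, 0.0125)]:
            db[rate] = 1e-8 * (1 + cv * rng.standard_normal(400))
        scan = dcs_noise_scan(db)
        assert scan.slope == pytest.approx(-1.0, abs=0.1)
        assert scan.level_at_cv(5.0, method="interp") == pytest.approx(4e4, rel=0.15)
        with pytest.raises(ValueError):
            dcs_noise_scan({1e4: db[1e4], 4e4: db[4e4]})


class TestStability:
    def test_constant_series(self):
        r = stability_metrics(np.full(100, 5.0), fs=1.0)
        assert r.warmup_s == 0.0
        assert r.cv_percent == 0.0
        assert r.stabilized

    def test_step_series(self):
        x = np.concatenate([np.full(30, 4.0), np.full(70, 5.0)])
        r = stability_metrics(x, fs=1.0)
        assert r.warmup_s == pytest.approx(30.0)

    def test_exponential_approach_closed_form(self):
        """x = ref (1 + D e^{-t/tau}): warm-up at tau ln(100 D / p)."""
        tau_c, D, p = 50.0, 0.10, 1.0
        t = np.arange(0, 1000.0)
        x = 10.0 * (1 + D * np.exp(-t / tau_c))
        r = stability_metrics(x, fs=1.0, band_percent=p)
        want = tau_c * np.log(100 * D / p)
        assert r.warmup_s == pytest.approx(want, abs=3.0)

    def test_never_stabilizes_flagged(self):
        x = np.linspace(0.0, 1.0, 50)  # still drifting into the last sample
        r = stability_metrics(x, fs=1.0, band_percent=0.01)
        assert not r.stabilized
        assert r.warmup_s == pytest.approx(50.0)


class TestReproducibility:
    def test_identical_days(self):
        assert reproducibility_cv([7.0, 7.0, 7.0]) == 0.0

    def test_two_day_arithmetic(self):
        assert reproducibility_cv([9.0, 11.0]) == pytest.approx(100 * np.sqrt(2) / 10)

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            reproducibility_cv([7.0])


class TestLinearity:
    @staticmethod
    def _grid(gain_a=1.0, gain_s=1.0):
        mua = np.array([0.05, 0.1, 0.2, 0.3, 0.4])
        musp = np.array([5.0, 10.0, 15.0, 20.0])
        rows = [
            {"mua_conv": a, "musp_conv": s, "mua_meas": gain_a * a, "musp_meas": gain_s * s}
            for a in mua
            for s in musp
        ]
        return pd.DataFrame(rows)

    def test_perfect_instrument(self):
        out = medphot_linearity(self._grid())
        assert out["mua_slope"] == pytest.approx(1.0)
        assert out["musp_slope"] == pytest.approx(1.0)
        assert out["mua_rel_err"] == pytest.approx(0.0, abs=1e-12)
        assert out["coupling_musp_on_mua"] == pytest.approx(0.0, abs=1e-12)
        assert out["coupling_mua_on_musp"] == pytest.approx(0.0, abs=1e-12)

    def test_three_percent_gain(self):
        out = medphot_linearity(self._grid(gain_a=1.03, gain_s=1.03))
        assert out["mua_rel_err"] == pytest.approx(0.03, rel=1e-9)
        assert out["musp_rel_err"] == pytest.approx(0.03, rel=1e-9)
        assert out["mua_slope"] == pytest.approx(1.03)

    def test_degenerate_grid_rejected(self):
        df = self._grid()
        with pytest.raises(ValueError):
            medphot_linearity(df[df.mua_conv == 0.1])


class TestEndToEndLinearity:
    def test_fitted_grid_slopes_and_coupling(self, irf):
        """Simulate -> fit over a phantom grid: slopes near 1, small
        crosstalk."""
        from tddcs.nirsfit import fit_dtof
        from tddcs.physics import OpticalProperties
        from tddcs.synthetic import simulate_dtof

        rows = []
        k = 0
        for mua in (0.05, 0.15, 0.30):
            for musp in (6.0, 10.0, 16.0):
                p = OpticalProperties(mua=mua, musp=musp, n=1.4, wavelength=830.0)
                d = simulate_dtof(p, 2.5, irf, N_target=5e5, seed=5000 + k)
                k += 1
                r = fit_dtof(d, irf, rho=2.5)
                rows.append(
                    {"mua_conv": mua, "musp_conv": musp, "mua_meas": r.mua, "musp_meas": r.musp}
                )
        out = medphot_linearity(pd.DataFrame(rows))
        assert out["mua_slope"] == pytest.approx(1.0, abs=0.05)
        assert out["musp_slope"] == pytest.approx(1.0, abs=0.05)
        # normalized coupling slopes: a value of 0.3 over the 0.25/cm mua
        # span would mean <= ~8% parameter drift from crosstalk; the
        # IRF-width-limited fits show a few percent at high absorption
        assert abs(out["coupling_musp_on_mua"]) < 0.3
        assert abs(out["coupling_mua_on_musp"]) < 0.3
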