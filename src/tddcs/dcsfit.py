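"""Fitting of intensity-autocorrelation curves for blood flow.

`G2Model` fits g2(tau) = 1 + beta |g1(tau; DB)|^2, with g1 from the
semi-infinite correlation diffusion equation under effective Brownian
motion, to a measured curve.  The fitted DB is reported as the blood flow
index (BFI = alpha*DB with alpha = 1).

Also implements a Koppel-type shot-noise variance model for multi-tau g2
estimates, used for optional lag weighting and as the theoretical
comparison curve in the DCS noise characterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from tddcs.correlator import CorrelationCurve
from tddcs.physics import (
    DynamicsParams,
    OpticalProperties,
    boundary_coefficient,
    g1_semi_infinite,
    optical_wavenumber,
)

__all__ = ["G2Model", "DcsFitResult", "fit_g2", "g2_noise_sigma", "decay_rate_estimate"]


@dataclass
class DcsFitResult:
    """Fitted dynamics of one g2 curve."""

    DB: float  # cm^2/s (= BFI)
    beta: float
    reduced_chi2: float
    success: bool
    fit_lag_range: tuple  # (tau_lo, tau_hi) s
    nobs: int
    bse: dict | None = None
    message: str = ""

    @property
    def bfi(self) -> float:
        return self.DB

    def summary(self) -> str:
        lines = [
            "g2 correlation-diffusion fit (semi-infinite, Brownian)",
            "=" * 54,
            f"{'converged':<22}{self.success}",
            f"{'lags in fit':<22}{self.nobs}",
            f"{'lag range [s]':<22}{self.fit_lag_range[0]:.3g} .. {self.fit_lag_range[1]:.3g}",
            f"{'reduced chi2':<22}{self.reduced_chi2:.3f}",
            "-" * 54,
        ]
        for name, unit in (("DB", "cm^2/s"), ("beta", "-")):
            val = getattr(self, name)
            se = (self.bse or {}).get(name)
            se_s = f" +/- {se:.3g}" if se is not None else ""
            lines.append(f"{name:<8}{val:12.5g}{se_s}   [{unit}]")
        return "\n".join(lines)


class G2Model:
    """Semi-infinite correlation-diffusion model for a measured g2 curve.

    Parameters
    ----------
    curve : measured correlation curve
    props : optical properties of the medium at the DCS wavelength
    rho : source-detector distance, cm
    wavelength : DCS wavelength, nm
    weights : None (uniform), or 'shotnoise' for Koppel-model weighting,
        or an explicit per-lag sigma array
    tail_frac : the iterated fit range ends where the model g2 - 1 falls
        below this fraction of the fitted beta
    """

    def __init__(
        self,
        curve: CorrelationCurve,
        props: OpticalProperties,
        rho: float = 2.5,
        wavelength: float = 785.0,
        weights=None,
        tail_frac: float = 0.01,
        min_lags: int = 10,
    ):
        if len(curve.lags) < min_lags:
            raise ValueError(f"need >= {min_lags} lags, got {len(curve.lags)}")
        self.curve = curve
        self.props = props
        self.rho = rho
        self.wavelength = wavelength
        self.weights = weights
        self.tail_frac = tail_frac
        ok = np.isfinite(curve.g2)
        self._tau = curve.lags[ok]
        self._g2 = curve.g2[ok]

    def g1(self, tau, DB: float) -> np.ndarray:
        return g1_semi_infinite(
            tau, self.rho, self.props, DynamicsParams(DB=DB, beta=0.5), self.wavelength
        )

    def _initial_guess(self):
        g2m1 = self._g2 - 1.0
        beta0 = float(np.clip(np.mean(g2m1[:3]), 0.05, 1.0))
        # lag where g2-1 decays to beta/e, then closed-form linearized decay
        target = beta0 / np.e
        below = np.nonzero(g2m1 < target)[0]
        if len(below) and below[0] > 0:
            i = below[0]
            tau_e = float(
                np.interp(target, [g2m1[i], g2m1[i - 1]], [self._tau[i], self._tau[i - 1]])
            )
        else:
            tau_e = float(self._tau[min(len(self._tau) - 1, 10)])
        p = self.props
        k0 = optical_wavenumber(p.n, self.wavelength)
        z0 = 1.0 / p.musp
        zb = 2.0 * boundary_coefficient(p.n) * p.D
        r1 = np.hypot(self.rho, z0)
        K0 = np.sqrt(3.0 * p.mua * p.musp)
        # |g1| = e^-1/2 when K - K0 = 1/(2 r1) in the single-exponential limit
        K1 = K0 + 0.5 / r1
        DB0 = (K1**2 - K0**2) / (6.0 * p.musp**2 * k0**2 * tau_e)
        return float(np.clip(DB0, 1e-12, 1e-4)), beta0

    def _sigma(self, tau):
        if self.weights is None:
            return np.ones_like(tau)
        if isinstance(self.weights, str) and self.weights == "shotnoise":
            c = self.curve
            DB0, beta0 = self._initial_guess()
            gamma = decay_rate_estimate(self, DB0)
            sig = g2_noise_sigma(
                tau,
                rate=max(c.count_rate, 1.0),
                t_total=max(c.window_length, tau[-1] * 10),
                beta=beta0,
                gamma=gamma,
                t_bin=tau[0],
            )
            return np.clip(sig, 1e-6, None)
        return np.asarray(self.weights, dtype=float)

    def _fit_once(self, tau, g2, x0):
        sig = self._sigma(tau)

        def resid(x):
            logDB, beta = x
            model = 1.0 + beta * self.g1(tau, 10.0**logDB) ** 2
            return (model - g2) / sig

        res = least_squares(
            resid,
            x0,
            bounds=([-12.0, 1e-3], [-4.0, 1.0]),
            xtol=1e-12,
            ftol=1e-12,
        )
        return res

    def fit(self, start: dict | None = None) -> DcsFitResult:
        """Weighted least-squares fit of (DB, beta).

        The fit is run once over all lags, then the lag range is cut where
        the fitted model's g2 - 1 falls below `tail_frac` * beta and the fit
        repeated (one iteration).
        """
        start = start or {}
        DB0, beta0 = self._initial_guess()
        DB0 = start.get("DB", DB0)
        beta0 = start.get("beta", beta0)
        x0 = np.array([np.log10(DB0), beta0])
        x0 = np.clip(x0, [-12.0, 1e-3], [-4.0, 1.0])

        tau, g2 = self._tau, self._g2
        res = self._fit_once(tau, g2, x0)
        logDB, beta = res.x
        model = 1.0 + beta * self.g1(tau, 10.0**logDB) ** 2
        keep = model - 1.0 >= self.tail_frac * beta
        if keep.sum() >= 10 and keep.sum() < len(tau):
            cut = int(np.nonzero(keep)[0][-1]) + 1
            tau, g2 = tau[:cut], g2[:cut]
            res = self._fit_once(tau, g2, res.x)
            logDB, beta = res.x

        DB = 10.0**logDB
        dof = max(len(tau) - 2, 1)
        red = float(np.sum(res.fun**2)) / dof
        bse = None
        try:
            cov = np.linalg.inv(res.jac.T @ res.jac) * red
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            bse = {"DB": float(se[0] * DB * np.log(10)), "beta": float(se[1])}
        except np.linalg.LinAlgError:
            pass
        return DcsFitResult(
            DB=float(DB),
            beta=float(beta),
            reduced_chi2=red,
            success=bool(res.success),
            fit_lag_range=(float(tau[0]), float(tau[-1])),
            nobs=len(tau),
            bse=bse,
            message=res.message,
        )


def fit_g2(
    c: CorrelationCurve,
    rho: float,
    props: OpticalProperties,
    wavelength: float = 785.0,
    n: float | None = None,
    **opts,
) -> DcsFitResult:
    """Functional wrapper: build a `G2Model` and fit it."""
    if n is not None and abs(n - props.n) > 1e-12:
        props = OpticalProperties(mua=props.mua, musp=props.musp, n=n, wavelength=props.wavelength)
    start = opts.pop("start", None)
    return G2Model(c, props, rho=rho, wavelength=wavelength, **opts).fit(start=start)


def decay_rate_estimate(model: G2Model, DB: float) -> float:
    """Effective single-exponential decay rate of |g1|, 1/s."""
    tau_probe = np.logspace(-7, -2, 64)
    g1 = model.g1(tau_probe, DB)
    below = np.nonzero(g1 < np.exp(-1))[0]
    tau_c = tau_probe[below[0]] if len(below) else tau_probe[-1]
    return 1.0 / tau_c


def g2_noise_sigma(tau, rate: float, t_total: float, beta: float, gamma: float, t_bin: float):
    """Koppel-type standard deviation of a multi-tau g2 estimate.

    Shot-noise model for photon-counting correlators with detected rate
    `rate` (Hz), total integration `t_total` (s), coherence decay rate
    `gamma` (1/s) and correlator bin `t_bin` (s, taken equal to the lag
    spacing of the first octave).  Used for weighting and for theoretical
    noise-trend comparisons; only the scaling with rate/duration matters.
    """
    tau = np.asarray(tau, dtype=float)
    # local bin width of the multi-tau ladder: bins double per octave, so a
    # lag in octave o is measured with bin ~ tau/12 (m = 16 lags/octave)
    t_loc = np.maximum(t_bin, tau / 12.0)
    n_mean = rate * t_loc
    e2gt = np.exp(-2.0 * gamma * t_loc)
    e2gtau = np.exp(-2.0 * gamma * tau)
    egtau = np.exp(-gamma * tau)
    m = np.maximum(tau / t_loc, 1.0)
    term_speckle = (
        beta**2
        * ((1.0 + e2gt) * (1.0 + e2gtau) + 2.0 * m * (1.0 - e2gt) * e2gtau)
        / np.maximum(1.0 - e2gt, 1e-12)
    )
    term_cross = 2.0 * beta * (1.0 + e2gtau) / n_mean
    term_shot = (1.0 + beta * egtau) / n_mean**2
    return np.sqrt(np.clip(t_loc / t_total * (term_speckle + term_cross + term_shot), 0, None))
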