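"""End-to-end analysis pipelines and spectral tools.

The stepped-occlusion pipeline turns synchronized DTOF series and photon
tag streams into hemodynamic traces: semi-infinite diffusion fits per
wavelength -> Beer's law -> HbO2/HHb/tHb/StO2, and windowed correlation ->
5-sample running median -> correlation-diffusion fit -> BFI; a 5-sample
moving average is applied to all output signals afterwards (median before
fitting, average after — the order matters and is preserved).

The pulsatility pipeline fits fast windowed g2 curves (e.g. 30 ms) and
computes the Welch power spectral density of the BFI signal (Hamming
windows, 20 s, 50% overlap by default).

`dcs_noise_study` is the simulation driver for the DCS noise
characterization: CV of fitted DB over repeated one-second windows as a
function of detected count rate (and optionally duration or channel
count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from tddcs.correlator import (
    CorrelatorConfig,
    average_curves,
    median_filter_curves,
    multitau_g2,
    windowed_g2,
)
from tddcs.dcsfit import G2Model
from tddcs.dtof import DTOF
from tddcs.nirsfit import DtofModel
from tddcs.physics import (
    ChromophoreBasis,
    DynamicsParams,
    OpticalProperties,
    beer_invert,
    g1_semi_infinite,
)

__all__ = [
    "HemodynamicTrace",
    "PsdResult",
    "welch_psd",
    "moving_average",
    "run_occlusion_pipeline",
    "run_pulsatility_pipeline",
    "tdnirs_noise_study",
    "dcs_noise_study",
]


@dataclass
class HemodynamicTrace:
    """Hemodynamic time series at one source-detector distance.

    Concentrations in uM, StO2 in %, BFI in cm^2/s; `flags` is True for
    samples where every underlying fit converged.
    """

    t: np.ndarray  # s, window centers
    hbo2: np.ndarray
    hhb: np.ndarray
    thb: np.ndarray
    sto2: np.ndarray
    bfi: np.ndarray
    flags: np.ndarray
    rho: float
    fs: float
    mua: dict = field(default_factory=dict)  # per-wavelength fitted mua
    musp: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        d = {
            "t": self.t,
            "HbO2": self.hbo2,
            "HHb": self.hhb,
            "tHb": self.thb,
            "StO2": self.sto2,
            "BFI": self.bfi,
            "ok": self.flags,
        }
        for lam, v in self.mua.items():
            d[f"mua_{int(lam)}"] = v
        return pd.DataFrame(d)


@dataclass
class PsdResult:
    """One-sided Welch power spectral density."""

    f: np.ndarray  # Hz
    psd: np.ndarray  # signal^2 / Hz
    window_s: float
    overlap: float

    def peak_frequency(self, f_min: float = 0.5) -> float:
        sel = self.f >= f_min
        return float(self.f[sel][np.argmax(self.psd[sel])])


def welch_psd(x, fs: float, window_s: float = 20.0, overlap: float = 0.5) -> PsdResult:
    """Welch PSD with Hamming windows (default 20 s, 50% overlap)."""
    x = np.asarray(x, dtype=float)
    nper = int(round(window_s * fs))
    if len(x) < 2 * nper - int(nper * overlap):
        raise ValueError("signal shorter than two Welch windows")
    f, p = sp_signal.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nper,
        noverlap=int(nper * overlap),
        detrend="constant",
        scaling="density",
    )
    return PsdResult(f=f, psd=p, window_s=window_s, overlap=overlap)


def moving_average(x, k: int = 5) -> np.ndarray:
    """Centered moving average with shrinking edge windows."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    half = k // 2
    for i in range(len(x)):
        h = min(half, i, len(x) - 1 - i)
        out[i] = x[i - h : i + h + 1].mean()
    return out


def _fit_dtof_series(series, rho, n_tissue, warm=None):
    """Fit a list of DTOFs with warm starts; returns (mua, musp, ok)."""
    mua = np.full(len(series), np.nan)
    musp = np.full(len(series), np.nan)
    ok = np.zeros(len(series), dtype=bool)
    start = warm
    for i, (d, irf) in enumerate(series):
        try:
            res = DtofModel(d, irf, rho=rho, n=n_tissue, min_counts=200).fit(start=start)
        except (ValueError, RuntimeError):
            continue
        mua[i], musp[i], ok[i] = res.mua, res.musp, res.success
        if res.success:
            start = {"mua": res.mua, "musp": res.musp, "t0": res.t0}
    return mua, musp, ok


def _fit_bfi_windows(curves, props, rho, warm_start=True):
    db = np.full(len(curves), np.nan)
    ok = np.zeros(len(curves), dtype=bool)
    start = None
    for i, c in enumerate(curves):
        try:
            res = G2Model(c, props, rho=rho).fit(start=start)
        except (ValueError, RuntimeError):
            continue
        db[i], ok[i] = res.DB, res.success
        if warm_start and res.success:
            start = {"DB": res.DB, "beta": res.beta}
    return db, ok


def run_occlusion_pipeline(
    ds,
    rhos=None,
    basis: ChromophoreBasis | None = None,
    dcs_props: OpticalProperties | None = None,
    correlator: CorrelatorConfig | None = None,
    smooth_k: int = 5,
    median_k: int = 5,
) -> dict:
    """Full stepped-occlusion analysis of an `OcclusionDataset`.

    Per sample and distance: TD NIRS fits at both wavelengths -> Beer's law
    inversion; DCS windowed correlation (window = one sample), channel
    averaging, `median_k`-sample running median across windows, g2 fit ->
    BFI.  A `smooth_k`-sample moving average is applied to all outputs.
    Non-converged fits propagate as flagged NaN gaps.

    Returns {rho: HemodynamicTrace}.
    """
    spec = ds.spec
    basis = basis or ds.basis
    rhos = tuple(rhos) if rhos is not None else spec.rhos
    fs = spec.fs
    out = {}
    for rho in rhos:
        lam_lo, lam_hi = basis.wavelengths
        mua_lo, musp_lo, ok_lo = _fit_dtof_series(
            [(d, ds.irf) for d in ds.dtofs[(lam_lo, rho)]], rho, spec.n_tissue
        )
        mua_hi, musp_hi, ok_hi = _fit_dtof_series(
            [(d, ds.irf) for d in ds.dtofs[(lam_hi, rho)]], rho, spec.n_tissue
        )
        n = len(mua_lo)
        hbo2 = np.full(n, np.nan)
        hhb = np.full(n, np.nan)
        thb = np.full(n, np.nan)
        sto2 = np.full(n, np.nan)
        for i in range(n):
            if ok_lo[i] and ok_hi[i]:
                try:
                    hbo2[i], hhb[i], thb[i], sto2[i] = beer_invert(mua_lo[i], mua_hi[i], basis)
                except ZeroDivisionError:
                    pass

        cfg = correlator or CorrelatorConfig(octaves=12, window=1.0 / fs)
        if cfg.window is None:
            cfg.window = 1.0 / fs
        per_ch = [windowed_g2(s, cfg) for s in ds.dcs_streams[rho]]
        n_win = min(len(c) for c in per_ch)
        merged = [average_curves([ch[w] for ch in per_ch]) for w in range(n_win)]
        merged = median_filter_curves(merged, k=median_k)
        if dcs_props is not None:
            props = dcs_props
        else:
            # assumed optics at the DCS wavelength from the TD NIRS channel:
            # median chromophores forwarded through Beer's law at 785 nm
            from tddcs.physics import beer_forward

            musp_mid = np.nanmedian(0.5 * (musp_lo + musp_hi))
            if not np.isfinite(musp_mid):
                musp_mid = 10.0
            if np.isfinite(np.nanmedian(hbo2)):
                b785 = ChromophoreBasis(wavelengths=(785.0,))
                mua_mid = float(
                    beer_forward(np.nanmedian(hbo2), np.nanmedian(hhb), b785)[0]
                )
            else:
                mua_mid, musp_mid = 0.15, 10.0
            props = OpticalProperties(
                mua=float(mua_mid), musp=float(musp_mid), n=spec.n_tissue, wavelength=785.0
            )
        bfi, ok_dcs = _fit_bfi_windows(merged, props, rho)
        m = min(n, len(bfi))

        trace = HemodynamicTrace(
            t=(np.arange(m) + 0.5) / fs,
            hbo2=moving_average(hbo2[:m], smooth_k),
            hhb=moving_average(hhb[:m], smooth_k),
            thb=moving_average(thb[:m], smooth_k),
            sto2=moving_average(sto2[:m], smooth_k),
            bfi=moving_average(bfi[:m], smooth_k),
            flags=(ok_lo[:m] & ok_hi[:m] & ok_dcs[:m]),
            rho=rho,
            fs=fs,
            mua={lam_lo: mua_lo[:m], lam_hi: mua_hi[:m]},
            musp={lam_lo: musp_lo[:m], lam_hi: musp_hi[:m]},
        )
        out[rho] = trace
    return out


def run_pulsatility_pipeline(
    streams,
    props: OpticalProperties,
    rho: float = 1.5,
    fs: float = 100.0 / 3.0,
    correlator: CorrelatorConfig | None = None,
    median_k: int = 5,
    psd_window_s: float = 20.0,
):
    """BFI time series and Welch PSD from fast windowed correlation.

    Returns (t, bfi, PsdResult).
    """
    cfg = correlator or CorrelatorConfig(octaves=8, window=1.0 / fs)
    per_ch = [windowed_g2(s, cfg) for s in streams]
    n_win = min(len(c) for c in per_ch)
    merged = [average_curves([ch[w] for ch in per_ch]) for w in range(n_win)]
    merged = median_filter_curves(merged, k=median_k)
    bfi, ok = _fit_bfi_windows(merged, props, rho)
    t = (np.arange(n_win) + 0.5) / fs
    good = np.isfinite(bfi)
    x = np.interp(t, t[good], bfi[good]) if good.any() and not good.all() else bfi
    psd = welch_psd(x, fs, window_s=psd_window_s)
    return t, bfi, psd


def tdnirs_noise_study(
    count_levels,
    props: OpticalProperties,
    irf,
    rho: float = 2.5,
    n_rep: int = 10,
    seed: int = 0,
) -> dict:
    """Repeated simulate-and-fit cycles per photon-count level.

    Returns {N_target: [NirsFitResult, ...]} ready for
    `protocols.medphot_noise_scan`.
    """
    from tddcs.synthetic import simulate_dtof

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(list(count_levels)) * n_rep)
    out = {}
    k = 0
    for N in count_levels:
        fits = []
        for _ in range(n_rep):
            d = simulate_dtof(props, rho, irf, N_target=N, seed=children[k])
            k += 1
            fits.append(DtofModel(d, irf, rho=rho, n=props.n).fit())
        out[N] = fits
    return out


def dcs_noise_study(
    rates_hz,
    props: OpticalProperties,
    dyn: DynamicsParams,
    rho: float = 2.5,
    wavelength: float = 785.0,
    n_windows: int = 100,
    window_s: float = 1.0,
    n_channels: int = 4,
    seed: int = 0,
    correlator: CorrelatorConfig | None = None,
    share_fields: bool = True,
) -> dict:
    """CV of fitted DB over repeated windows as a function of count rate.

    For each rate, `n_windows` windows of `window_s` seconds are generated
    on `n_channels` independent speckle channels, correlated, averaged
    across channels and fitted for DB.  With `share_fields` the same
    speckle-intensity realizations are thinned at every rate (common random
    numbers — the per-rate CVs stay unbiased while the rate-to-rate
    comparison smooths); otherwise fields are regenerated per rate.

    Returns {rate: array of fitted DB over windows}.
    """
    from scipy import fft as sp_fft

    from tddcs.correlator import PS_PER_S, PhotonTagStream
    from tddcs.synthetic import _tau_at

    cfg = correlator or CorrelatorConfig(octaves=12)
    rates = list(rates_hz)

    def g1f(tau):
        return g1_semi_infinite(tau, rho, props, dyn, wavelength)

    tau95 = _tau_at(g1f, 0.95)
    dt_field_ps = max(1, int(round(tau95 / 10.0 * PS_PER_S)))
    dt_s = dt_field_ps / PS_PER_S
    win_ps = int(round(window_s * PS_PER_S))
    n_total = win_ps // dt_field_ps
    n_seg = min(1 << 19, n_total)
    M = max(1, int(round(1.0 / dyn.beta)))

    k = np.minimum(np.arange(n_seg), n_seg - np.arange(n_seg))
    S = np.fft.fft(g1f(k * dt_s)).real
    amp = np.sqrt(np.clip(S, 0.0, None) * n_seg / 2.0).astype(np.float32)

    ss = np.random.SeedSequence(seed)
    db = {r: np.full(n_windows, np.nan) for r in rates}
    rate_children = {} if share_fields else {r: np.random.SeedSequence(seed + 1 + i) for i, r in enumerate(rates)}

    def one_pass(rate_subset, sseq):
        children = sseq.spawn(n_windows * n_channels)
        ci = 0
        for w in range(n_windows):
            curves = {r: [] for r in rate_subset}
            for ch in range(n_channels):
                rng = np.random.default_rng(children[ci])
                ci += 1
                # intensity for the full window, segment by segment
                lam_norm = np.empty(n_total, dtype=np.float64)
                start = 0
                while start < n_total:
                    nn = min(n_seg, n_total - start)
                    I = np.zeros(n_seg, dtype=np.float32)
                    for _ in range(M):
                        xi = rng.standard_normal(2 * n_seg, dtype=np.float32).view(np.complex64)
                        z = sp_fft.ifft(amp * xi)
                        I += z.real**2 + z.imag**2
                    lam_norm[start : start + nn] = I[:nn].astype(np.float64) / M
                    start += nn
                cs = np.cumsum(lam_norm)
                for r in rate_subset:
                    scale = r * dt_s
                    total = rng.poisson(cs[-1] * scale)
                    u = rng.random(total) * cs[-1]
                    idx = np.searchsorted(cs, u)
                    offs = rng.integers(0, dt_field_ps, size=total)
                    ts = np.sort(idx.astype(np.int64) * dt_field_ps + offs)
                    ts = ts[ts < win_ps]
                    stream = PhotonTagStream(timestamps=ts, channel=ch, duration=window_s)
                    curves[r].append(multitau_g2(stream, cfg))
            for r in rate_subset:
                avg = average_curves(curves[r])
                try:
                    res = G2Model(avg, props, rho=rho, wavelength=wavelength).fit()
                    if res.success:
                        db[r][w] = res.DB
                except (ValueError, RuntimeError):
                    pass

    if share_fields:
        one_pass(rates, ss)
    else:
        for r in rates:
            one_pass([r], rate_children[r])
    return db
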