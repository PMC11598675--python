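"""Photon-level synthetic instrument.

Generates every input the analysis stack consumes:

* IRFs (Gaussian core, SiPM-like double-exponential tail, flat
  signal-dependent background, optional secondary reflection peak),
* Poisson-sampled DTOFs from diffusion theory convolved with an IRF,
* Born-approximation perturbation datasets (movable absorbing inclusion,
  bilayer absorption changes) for contrast/selectivity protocols,
* DCS photon-tag streams whose g2 matches 1 + beta |g1|^2 for a prescribed
  field autocorrelation, via spectral synthesis of a complex Gaussian field
  and inhomogeneous-Poisson photon thinning,
* stepped-occlusion and pulsatile hemodynamic datasets with stored ground
  truth.

Every generator is deterministic for a fixed seed and spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.signal import fftconvolve

from tddcs.correlator import PS_PER_S, PhotonTagStream
from tddcs.dtof import DTOF, GateSpec, IRFRecord, gate_counts
from tddcs.physics import (
    ChromophoreBasis,
    DynamicsParams,
    OpticalProperties,
    beer_forward,
    boundary_coefficient,
    g1_semi_infinite,
    td_reflectance,
)

__all__ = [
    "IRFSpec",
    "make_irf",
    "simulate_dtof",
    "dtof_model_shape",
    "simulate_inclusion_scan",
    "layer_pathlength",
    "simulate_selectivity_dataset",
    "SpeckleSim",
    "simulate_speckle_tags",
    "OcclusionProtocolSpec",
    "OcclusionDataset",
    "simulate_occlusion_dataset",
    "simulate_pulsatile_bfi",
]


# ---------------------------------------------------------------------------
# IRF and DTOF generators


@dataclass
class IRFSpec:
    """Shape of a synthetic instrument response function.

    fwhm: FWHM of the Gaussian core, ps
    tail_taus / tail_weights: SiPM-like double-exponential tail (decay
        constants in ps; weights are the kernel area fractions routed into
        each exponential)
    background_ap: flat signal-dependent background, expressed as the
        afterpulsing ratio it produces (background counts spread uniformly
        over the laser period)
    reflection: optional secondary peak (delay ps, relative amplitude)
    t_peak: position of the Gaussian core, ps
    """

    fwhm: float = 200.0
    tail_taus: tuple = (150.0, 700.0)
    tail_weights: tuple = (0.20, 0.03)
    background_ap: float = 0.03
    reflection: tuple | None = None
    t_peak: float = 3000.0

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("FWHM must be > 0")
        if any(w < 0 for w in self.tail_weights):
            raise ValueError("tail weights must be >= 0")


def _irf_profile(spec: IRFSpec, t: np.ndarray, dt: float) -> np.ndarray:
    """Noiseless unit-area IRF profile on channel centers `t`."""
    sigma = spec.fwhm / 2.354820045
    core = np.exp(-0.5 * ((t - spec.t_peak) / sigma) ** 2)
    core /= core.sum()
    w_delta = 1.0 - sum(spec.tail_weights)
    kern = np.zeros_like(t)
    kern[0] = w_delta
    tk = np.arange(len(t)) * dt
    for tau_i, w_i in zip(spec.tail_taus, spec.tail_weights):
        e = np.exp(-tk / tau_i)
        kern += w_i * e / e.sum()
    prof = fftconvolve(core, kern)[: len(t)]
    if spec.reflection is not None:
        delay, amp = spec.reflection
        shift = int(round(delay / dt))
        sec = np.zeros_like(prof)
        if shift < len(prof):
            sec[shift:] = prof[: len(prof) - shift] * amp
        prof = prof + sec
    prof = np.clip(prof, 0.0, None)  # FFT convolution leaves ~1e-18 negatives
    return prof / prof.sum()


def make_irf(
    spec: IRFSpec,
    N_tot: float = 1e6,
    seed: int = 0,
    dt: float = 9.77,
    n_channels: int = 1250,
    T_rep: float = 12500.0,
    wavelength: float = 830.0,
) -> IRFRecord:
    """Poisson-sampled synthetic IRF measurement."""
    if N_tot <= 0:
        raise ValueError("N_tot must be > 0")
    rng = np.random.default_rng(seed)
    t = (np.arange(n_channels) + 0.5) * dt
    prof = _irf_profile(spec, t, dt)
    # flat background level producing the requested afterpulsing ratio
    bg_level = spec.background_ap * N_tot * dt / T_rep
    lam = N_tot * prof + bg_level
    counts = rng.poisson(lam)
    h = DTOF(counts=counts, dt=dt, T_rep=T_rep, wavelength=wavelength)
    return IRFRecord.from_histogram(h)


def dtof_model_shape(
    props: OpticalProperties,
    rho: float,
    irf: IRFRecord,
    t0: float = 0.0,
) -> np.ndarray:
    """Unit-area IRF-convolved reflectance on the IRF's channel grid."""
    h = irf.histogram
    kern = np.clip(h.counts.astype(float) - irf.background, 0.0, None)
    kern /= kern.sum()
    t = h.t - h.t0 - t0
    r = td_reflectance(rho, t, props)
    m = fftconvolve(kern, r)[: len(kern)]
    m = np.clip(m, 0.0, None)
    s = m.sum()
    if s <= 0:
        raise ValueError("degenerate model shape")
    return m / s


def simulate_dtof(
    props: OpticalProperties,
    rho: float,
    irf: IRFRecord,
    N_target: float = 5e5,
    background: float = 0.0,
    seed: int = 0,
    t0: float = 0.0,
    acq_time: float = 0.5,
) -> DTOF:
    """Poisson-sampled DTOF around the IRF-convolved diffusion model.

    The amplitude is set so the expected total (excluding the flat
    `background` counts/channel) equals `N_target`.
    """
    rng = np.random.default_rng(seed)
    shape = dtof_model_shape(props, rho, irf, t0=t0)
    lam = N_target * shape + background
    counts = rng.poisson(lam)
    h = irf.histogram
    return DTOF(
        counts=counts,
        dt=h.dt,
        t0=h.t0,
        T_rep=h.T_rep,
        acq_time=acq_time,
        wavelength=props.wavelength,
        rho=rho,
    )


# ---------------------------------------------------------------------------
# Born-approximation perturbation generators


def _gates_to_absolute(gates: GateSpec, ref_counts: np.ndarray, dt: float, t0: float) -> GateSpec:
    """Resolve peak-referenced gates once, against the reference curve, so
    the same absolute windows apply to perturbed and reference histograms."""
    if gates.reference == "absolute":
        return gates
    offset = t0 + int(np.argmax(ref_counts)) * dt
    return GateSpec([(a + offset, b + offset) for a, b in gates.gates], reference="absolute")


def _greens_product_conv(d1a, d2a, d1b, d2b, props, t, dt):
    """Time convolution of two image-source diffusion Green's functions.

    Each Green's function connects two points through direct distance d1*
    and image distance d2*; absorption factors cancel against the
    denominator and are left out.
    """
    Dv = props.D * props.v

    def G(dd1, dd2):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (4.0 * np.pi * Dv * t) ** -1.5 * (
                np.exp(-(dd1**2) / (4.0 * Dv * t)) - np.exp(-(dd2**2) / (4.0 * Dv * t))
            )
        return np.where(t > 0, f, 0.0)

    conv = fftconvolve(G(d1a, d2a), G(d1b, d2b))[: len(t)] * dt
    return conv


def simulate_inclusion_scan(
    props: OpticalProperties,
    rho: float,
    irf: IRFRecord,
    positions,
    scan: str = "z",
    fixed_depth: float = 1.5,
    dmua_v: float = 0.17,
    gates: GateSpec | None = None,
    N_target: float = 5e6,
    n_rep: int = 10,
    seed: int = 0,
    noiseless: bool = False,
):
    """Gate counts for a movable point absorber (first Born approximation).

    The absorber of strength `dmua_v` (cm^-1 cm^3) sits at depth z (scan
    'z', laterally at the source-detector midpoint) or at lateral position x
    and depth `fixed_depth` (scan 'x'; x = 0 is the midpoint).  The
    perturbation is built from the product of semi-infinite image-source
    Green's functions time-convolved along source -> inclusion -> detector,
    exponentiated to keep counts positive, and convolved with the IRF.

    Returns dict with 'positions' (cm), 'gate_counts' (n_pos, n_rep,
    n_gates), 'ref_counts' (n_rep, n_gates) and 'gates'.
    """
    if dmua_v > 1.0:
        import warnings

        warnings.warn("inclusion strength outside the perturbative regime")
    rng = np.random.default_rng(seed)
    h = irf.histogram
    dt = h.dt
    t = h.t - h.t0  # model time axis before IRF convolution
    z0 = 1.0 / props.musp
    zb = 2.0 * boundary_coefficient(props.n) * props.D
    xs, xd = -rho / 2.0, rho / 2.0
    gates = gates or GateSpec.uniform(0.0, 4000.0, 500.0, reference="peak")

    r0 = td_reflectance(rho, t, props)
    kern = np.clip(h.counts.astype(float) - irf.background, 0.0, None)
    kern /= kern.sum()

    def dist(p, q):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))

    # amplitude fixed on the unperturbed curve: constant injected power,
    # so perturbed measurements lose counts instead of being renormalized
    _ref_conv = np.clip(fftconvolve(kern, r0)[: len(t)], 0.0, None)
    amp = N_target / _ref_conv.sum()

    def counts_for(profile):
        m = amp * np.clip(fftconvolve(kern, profile)[: len(t)], 0.0, None)
        if noiseless:
            return np.stack([m] * n_rep)
        return rng.poisson(np.stack([m] * n_rep))

    # denominator: source->detector with both endpoints at depth z0
    src = (xs, 0.0, z0)
    det = (xd, 0.0, z0)
    det_img = (xd, 0.0, -z0 - 2.0 * zb)
    Dv = props.D * props.v
    d_sd = dist(src, det)
    d_sdi = dist(src, det_img)
    with np.errstate(divide="ignore", invalid="ignore"):
        g_sd = np.where(
            t > 0,
            (4.0 * np.pi * Dv * t) ** -1.5
            * (np.exp(-(d_sd**2) / (4 * Dv * t)) - np.exp(-(d_sdi**2) / (4 * Dv * t))),
            0.0,
        )

    positions = np.asarray(positions, dtype=float)
    ref = counts_for(r0)
    gates = _gates_to_absolute(gates, _ref_conv, dt, h.t0)
    out = np.empty((len(positions), n_rep, len(gates.gates)))
    ref_gc = np.stack([gate_counts(DTOF(ref[j], dt=dt, t0=h.t0, T_rep=h.T_rep), gates) for j in range(n_rep)])
    for i, pos in enumerate(positions):
        if scan == "z":
            rp = (0.0, 0.0, max(pos, 1e-3))
        elif scan == "x":
            rp = (pos, 0.0, fixed_depth)
        else:
            raise ValueError("scan must be 'z' or 'x'")
        rp_img = (rp[0], rp[1], -rp[2] - 2.0 * zb)
        conv = _greens_product_conv(
            dist(src, rp), dist(src, rp_img), dist(rp, det), dist(rp, det_img), props, t, dt
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            p_rel = np.where(g_sd > 0, conv / g_sd, 0.0)
        pert = r0 * np.exp(-dmua_v * props.v * np.clip(p_rel, 0.0, None))
        cc = counts_for(pert)
        for j in range(n_rep):
            out[i, j] = gate_counts(DTOF(cc[j], dt=dt, t0=h.t0, T_rep=h.T_rep), gates)
    return {"positions": positions, "gate_counts": out, "ref_counts": ref_gc, "gates": gates}


def layer_pathlength(
    z_lo: float,
    z_hi: float,
    t_ps,
    rho: float,
    props: OpticalProperties,
    n_theta: int = 48,
    n_z: int = 80,
) -> np.ndarray:
    """Time-resolved mean partial pathlength in the depth slab [z_lo, z_hi].

    Photons detected at time t have travelled a total path v*t; this returns
    the mean share spent between depths z_lo and z_hi (cm), from the
    normalized product of semi-infinite Green's functions (source and
    detector endpoints at one transport mean free path).  The transverse
    part cancels exactly, so the result is independent of rho.
    """
    t = np.asarray(t_ps, dtype=float)
    z0 = 1.0 / props.musp
    zb = 2.0 * boundary_coefficient(props.n) * props.D
    Dv = props.D * props.v

    # Gauss-Legendre nodes with the t' = t sin^2(theta) substitution
    xg, wg = np.polynomial.legendre.leggauss(n_theta)
    theta = 0.25 * np.pi * (xg + 1.0)
    wth = 0.25 * np.pi * wg
    zg, wz = np.polynomial.legendre.leggauss(n_z)
    z = 0.5 * (z_hi + z_lo) + 0.5 * (z_hi - z_lo) * zg
    wz = 0.5 * (z_hi - z_lo) * wz

    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    s2 = np.sin(theta) ** 2
    # shapes: (n_t, n_theta, n_z)
    t1 = tp[:, None, None] * s2[None, :, None]
    t2 = tp[:, None, None] - t1
    zz = z[None, None, :]

    def gz(tt, za, zb_src):
        # 1-D image-source kernel between depths za and zb_src (no absorption)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (4.0 * np.pi * Dv * tt) ** -0.5 * (
                np.exp(-((za - zb_src) ** 2) / (4.0 * Dv * tt))
                - np.exp(-((za + zb_src + 2.0 * zb) ** 2) / (4.0 * Dv * tt))
            )

    num = gz(t1, zz, z0) * gz(t2, zz, z0)
    # jacobian of the substitution: dt' = 2 t sin(theta) cos(theta) dtheta
    jac = 2.0 * tp[:, None] * np.sin(theta)[None, :] * np.cos(theta)[None, :]
    integ = np.einsum("ijk,k->ij", num, wz)
    integral = np.einsum("ij,ij,j->i", integ, jac, wth)
    den = (4.0 * np.pi * Dv * tp) ** -0.5 * (1.0 - np.exp(-((2 * z0 + 2 * zb) ** 2) / (4.0 * Dv * tp)))
    out[pos] = props.v * integral / den
    return out


def simulate_selectivity_dataset(
    props: OpticalProperties,
    rho: float,
    irf: IRFRecord,
    dmua_grid,
    top_thickness: float = 1.0,
    z_max: float = 10.0,
    gates: GateSpec | None = None,
    N_target: float = 5e6,
    n_rep: int = 10,
    seed: int = 0,
    noiseless: bool = False,
):
    """Bilayer absorption-change dataset for depth-selectivity analysis.

    Per time channel the counts are attenuated by exp(-dmua * L_layer(t))
    with the time-resolved mean partial pathlength of the perturbed layer
    (microscopic Beer-Lambert), then convolved with the IRF and Poisson
    sampled.  Returns gate counts for the unperturbed reference and for
    upper/lower-layer changes over `dmua_grid`.
    """
    rng = np.random.default_rng(seed)
    h = irf.histogram
    dt = h.dt
    t = h.t - h.t0
    gates = gates or GateSpec.uniform(0.0, 4000.0, 500.0, reference="peak")
    r0 = td_reflectance(rho, t, props)
    kern0 = np.clip(h.counts.astype(float) - irf.background, 0.0, None)
    gates = _gates_to_absolute(
        gates, np.clip(fftconvolve(kern0 / kern0.sum(), r0)[: len(t)], 0.0, None), dt, h.t0
    )
    L_up = layer_pathlength(0.0, top_thickness, t, rho, props)
    L_dn = layer_pathlength(top_thickness, z_max, t, rho, props)
    kern = np.clip(h.counts.astype(float) - irf.background, 0.0, None)
    kern /= kern.sum()

    _ref_conv = np.clip(fftconvolve(kern, r0)[: len(t)], 0.0, None)
    amp = N_target / _ref_conv.sum()

    def gated(profile):
        m = amp * np.clip(fftconvolve(kern, profile)[: len(t)], 0.0, None)
        reps = np.stack([m] * n_rep) if noiseless else rng.poisson(np.stack([m] * n_rep))
        return np.stack(
            [gate_counts(DTOF(reps[j], dt=dt, t0=h.t0, T_rep=h.T_rep), gates) for j in range(n_rep)]
        )

    dmua_grid = np.asarray(dmua_grid, dtype=float)
    ref = gated(r0)
    up = np.stack([gated(r0 * np.exp(-dm * L_up)) for dm in dmua_grid])
    dn = np.stack([gated(r0 * np.exp(-dm * L_dn)) for dm in dmua_grid])
    return {"dmua": dmua_grid, "ref": ref, "up": up, "down": dn, "gates": gates}


# ---------------------------------------------------------------------------
# DCS speckle-field photon-tag generator


@dataclass
class SpeckleSim:
    """Output of `simulate_speckle_tags`."""

    streams: list
    beta_eff: float
    dt_field_ps: int


def _tau_at(g1_func, level: float, hint: float = 1e-6) -> float:
    """Smallest tau (s) where g1 drops below `level`; inf for static media."""
    tau = np.logspace(-9, 0, 400)
    g = np.asarray(g1_func(tau), dtype=float)
    below = np.nonzero(g < level)[0]
    if not len(below):
        return np.inf
    i = below[0]
    if i == 0:
        return tau[0]
    return float(np.interp(level, [g[i], g[i - 1]], [tau[i], tau[i - 1]]))


def simulate_speckle_tags(
    g1_func,
    count_rate: float,
    duration: float,
    beta: float = 0.5,
    n_channels: int = 1,
    seed: int = 0,
    dt_field_ps: int | None = None,
    max_segment: int = 1 << 19,
) -> SpeckleSim:
    """Photon time-tag streams whose g2 follows 1 + beta_eff |g1|^2.

    A stationary complex Gaussian field with the prescribed autocorrelation
    is synthesized per segment by spectral coloring (the discrete PSD is the
    Fourier transform of the sampled g1), the coherence factor beta = 1/M is
    realized by summing M independent speckle intensities, and photons are
    drawn as an inhomogeneous Poisson process from the summed intensity.
    Segments are regenerated independently; lags used downstream must be
    much shorter than a segment.

    The field time step is tau(g1=0.95)/10 unless given.  Channels are
    statistically independent detectors viewing independent speckles.

    Returns streams with integer-ps timestamps plus the realized beta.
    """
    if not (0 < beta <= 1):
        raise ValueError("beta must be in (0, 1]")
    if count_rate * duration < 1e3:
        raise ValueError("need at least ~1e3 expected photons")
    M = max(1, int(round(1.0 / beta)))
    beta_eff = 1.0 / M

    tau95 = _tau_at(g1_func, 0.95)
    static = np.isinf(tau95)
    if dt_field_ps is None:
        if static:
            dt_field_ps = int(200e-9 * PS_PER_S)
        else:
            dt_field_ps = max(1, int(round(tau95 / 10.0 * PS_PER_S)))
    dt_s = dt_field_ps / PS_PER_S

    dur_ps = int(round(duration * PS_PER_S))
    n_total = dur_ps // dt_field_ps
    n_seg = min(int(max_segment), int(n_total)) if n_total else 0
    if n_seg < 2:
        raise ValueError("duration too short for the field time step")

    # discrete PSD of the sampled g1 (symmetric circular autocorrelation)
    k = np.minimum(np.arange(n_seg), n_seg - np.arange(n_seg))
    c = np.asarray(g1_func(k * dt_s), dtype=float)
    S = np.fft.fft(c).real
    # 1/2 compensates the unit variance of each quadrature of the white seed
    amp = np.sqrt(np.clip(S, 0.0, None) * n_seg / 2.0).astype(np.float32)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = ss.spawn(n_channels)
    streams = []
    for ch in range(n_channels):
        rng = np.random.default_rng(child[ch])
        ts_parts = []
        start = 0  # in field samples
        while start < n_total:
            nn = min(n_seg, n_total - start)
            if static:
                # no decay on any resolvable scale: the speckle intensity is
                # constant in time and the normalized g2 is 1 regardless of
                # its (random) level, so photons are homogeneous Poisson
                I = np.full(n_seg, float(M), dtype=np.float32)
            else:
                I = np.zeros(n_seg, dtype=np.float32)
                for _ in range(M):
                    xi = rng.standard_normal(2 * n_seg, dtype=np.float32).view(np.complex64)
                    z = sp_fft.ifft(amp * xi)  # stays complex64
                    I += z.real**2 + z.imag**2
            lam = I[:nn].astype(np.float64) * (count_rate * dt_s / M)
            total = rng.poisson(lam.sum())
            if total:
                cs = np.cumsum(lam)
                u = rng.random(total) * cs[-1]
                idx = np.searchsorted(cs, u)
                offs = rng.integers(0, dt_field_ps, size=total)
                ts = (start + idx).astype(np.int64) * dt_field_ps + offs
                ts_parts.append(ts)
            start += nn
        ts = np.sort(np.concatenate(ts_parts)) if ts_parts else np.empty(0, dtype=np.int64)
        ts = ts[ts < dur_ps]
        streams.append(PhotonTagStream(timestamps=ts, channel=ch, duration=duration))
    return SpeckleSim(streams=streams, beta_eff=beta_eff, dt_field_ps=dt_field_ps)


# ---------------------------------------------------------------------------
# Hemodynamic protocol generators


@dataclass
class OcclusionProtocolSpec:
    """Stepped-occlusion scenario: phase timing and hemodynamic targets.

    Defaults follow the standard cuff protocol (2 min baseline, 1 min light,
    1 min venous, 1 min arterial occlusion, 5 min recovery) on a forearm
    muscle; concentrations in uM, DB in cm^2/s.  Trajectories are
    piecewise-linear ramps smoothed with a `smooth_tau` s exponential;
    post-release hyperemia is a gamma-shaped overshoot.
    """

    phases: tuple = (("baseline", 120.0), ("light", 60.0), ("venous", 60.0), ("arterial", 60.0), ("recovery", 300.0))
    fs: float = 5.0  # Hz
    hbo2_0: float = 42.0
    hhb_0: float = 18.0
    db_0: float = 1e-8
    venous_thb_rise: float = 0.25  # fractional tHb rise during venous phase
    arterial_swap: float = 12.0  # uM moved from HbO2 to HHb during arterial
    venous_db_factor: float = 0.85
    arterial_db_factor: float = 0.15
    hyperemia_peak: float = 0.8  # fractional DB overshoot after release
    hyperemia_t_rise: float = 10.0  # s
    hyperemia_decay: float = 30.0  # s
    hbo2_overshoot: float = 8.0  # uM
    smooth_tau: float = 5.0  # s
    cardiac: tuple | None = None  # (rate Hz, relative amplitude, harmonics)
    musp: dict = field(default_factory=lambda: {685.0: 11.0, 830.0: 9.0})
    n_tissue: float = 1.4
    dtof_counts: float = 2e5  # expected counts per DTOF sample
    dcs_rate: float = 50e3  # detected rate per DCS channel, Hz
    dcs_channels: dict = field(default_factory=lambda: {1.5: 1, 2.5: 3})
    rhos: tuple = (1.5, 2.5)

    def __post_init__(self):
        if any(d <= 0 for _, d in self.phases):
            raise ValueError("phase durations must be > 0")
        if min(self.hbo2_0, self.hhb_0) < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.phases))


def _expsmooth(x: np.ndarray, tau: float, fs: float) -> np.ndarray:
    if tau <= 0:
        return x
    a = 1.0 - np.exp(-1.0 / (tau * fs))
    y = np.empty_like(x)
    acc = x[0]
    for i, v in enumerate(x):
        acc += a * (v - acc)
        y[i] = acc
    return y


def occlusion_ground_truth(spec: OcclusionProtocolSpec):
    """Per-sample ground-truth trajectories (HbO2, HHb, tHb, StO2, DB)."""
    fs = spec.fs
    n = int(round(spec.duration * fs))
    tt = (np.arange(n) + 0.5) / fs
    hbo2 = np.full(n, spec.hbo2_0)
    hhb = np.full(n, spec.hhb_0)
    db = np.full(n, spec.db_0)

    bounds = np.cumsum([0.0] + [d for _, d in spec.phases])
    names = [p for p, _ in spec.phases]
    for name, a, b in zip(names, bounds[:-1], bounds[1:]):
        sel = (tt >= a) & (tt < b)
        if not np.any(sel):
            continue
        frac = (tt[sel] - a) / (b - a)
        if name == "venous":
            ramp = 1.0 + spec.venous_thb_rise * frac
            hbo2[sel] = spec.hbo2_0 * ramp
            hhb[sel] = spec.hhb_0 * ramp
            db[sel] = spec.db_0 * (1.0 - (1.0 - spec.venous_db_factor) * frac)
        elif name == "arterial":
            ramp_end = 1.0 + spec.venous_thb_rise
            hbo2[sel] = spec.hbo2_0 * ramp_end - spec.arterial_swap * frac
            hhb[sel] = spec.hhb_0 * ramp_end + spec.arterial_swap * frac
            db[sel] = spec.db_0 * spec.arterial_db_factor
        elif name == "recovery":
            trec = tt[sel] - a
            rec = np.exp(-trec / spec.hyperemia_decay)
            hbo2_end = spec.hbo2_0 * (1.0 + spec.venous_thb_rise) - spec.arterial_swap
            hhb_end = spec.hhb_0 * (1.0 + spec.venous_thb_rise) + spec.arterial_swap
            gamma = (trec / spec.hyperemia_t_rise) * np.exp(1.0 - trec / spec.hyperemia_t_rise)
            hbo2[sel] = spec.hbo2_0 + (hbo2_end - spec.hbo2_0) * rec + spec.hbo2_overshoot * gamma
            hhb[sel] = spec.hhb_0 + (hhb_end - spec.hhb_0) * rec - 0.5 * spec.hbo2_overshoot * gamma
            db[sel] = spec.db_0 * (1.0 + spec.hyperemia_peak * gamma) - spec.db_0 * (
                1.0 - spec.arterial_db_factor
            ) * np.exp(-trec / 3.0)
        else:  # baseline and light occlusion: constants before any step
            hbo2[sel] = spec.hbo2_0
            hhb[sel] = spec.hhb_0
            db[sel] = spec.db_0

    hbo2 = _expsmooth(hbo2, spec.smooth_tau, fs)
    hhb = _expsmooth(hhb, spec.smooth_tau, fs)
    db = np.clip(_expsmooth(db, 1.0, fs), 1e-11, None)
    if spec.cardiac is not None:
        hr, amp, nharm = spec.cardiac
        mod = np.zeros(n)
        for i in range(1, int(nharm) + 1):
            mod += (amp / i) * np.cos(2 * np.pi * i * hr * tt)
        db = db * (1.0 + mod)
    thb = hbo2 + hhb
    sto2 = 100.0 * hbo2 / thb
    return {"t": tt, "HbO2": hbo2, "HHb": hhb, "tHb": thb, "StO2": sto2, "DB": db}


@dataclass
class OcclusionDataset:
    """Synthetic stepped-occlusion measurement with its ground truth."""

    spec: OcclusionProtocolSpec
    truth: dict
    irf: IRFRecord
    dtofs: dict  # (wavelength, rho) -> list[DTOF], one per sample
    dcs_streams: dict  # rho -> list[PhotonTagStream] (one per channel)
    basis: ChromophoreBasis


def simulate_occlusion_dataset(
    spec: OcclusionProtocolSpec | None = None,
    seed: int = 0,
    irf_spec: IRFSpec | None = None,
    basis: ChromophoreBasis | None = None,
) -> OcclusionDataset:
    """Synchronized TD NIRS DTOF series and DCS tag streams for the
    stepped-occlusion protocol, with stored ground truth.

    mua(lambda, t) follows Beer's law forward from the chromophore
    trajectories; DB(t) follows the phase profile.  DCS streams are
    generated per sample window with piecewise-constant dynamics.
    """
    spec = spec or OcclusionProtocolSpec()
    basis = basis or ChromophoreBasis()
    truth = occlusion_ground_truth(spec)
    ss = np.random.SeedSequence(seed)
    s_irf, s_td, s_dcs = ss.spawn(3)
    irf = make_irf(irf_spec or IRFSpec(), N_tot=2e6, seed=s_irf)

    n = len(truth["t"])
    mua = np.stack([beer_forward(truth["HbO2"][i], truth["HHb"][i], basis) for i in range(n)])
    td_children = s_td.spawn(n * len(basis.wavelengths) * len(spec.rhos))
    dtofs = {}
    ci = 0
    for wi, lam in enumerate(basis.wavelengths):
        for rho in spec.rhos:
            series = []
            for i in range(n):
                props = OpticalProperties(
                    mua=float(mua[i, wi]), musp=spec.musp[lam], n=spec.n_tissue, wavelength=lam
                )
                series.append(
                    simulate_dtof(
                        props,
                        rho,
                        irf,
                        N_target=spec.dtof_counts,
                        seed=td_children[ci],
                        acq_time=1.0 / spec.fs,
                    )
                )
                ci += 1
            dtofs[(lam, rho)] = series

    # DCS: per-sample windows with piecewise-constant DB, concatenated
    dcs_streams = {}
    win_s = 1.0 / spec.fs
    win_ps = int(round(win_s * PS_PER_S))
    dcs_children = s_dcs.spawn(len(spec.rhos) * n)
    kidx = 0
    for rho in spec.rhos:
        n_ch = spec.dcs_channels.get(rho, 1)
        parts = [[] for _ in range(n_ch)]
        basis785 = ChromophoreBasis(wavelengths=(785.0,))
        mua785 = float(beer_forward(spec.hbo2_0, spec.hhb_0, basis785)[0])
        props785 = OpticalProperties(mua=mua785, musp=10.0, n=spec.n_tissue, wavelength=785.0)
        for i in range(n):
            dbi = float(truth["DB"][i])
            sim = simulate_speckle_tags(
                lambda tau, dbi=dbi: g1_semi_infinite(
                    tau, rho, props785, DynamicsParams(DB=dbi, beta=0.5), 785.0
                ),
                count_rate=spec.dcs_rate,
                duration=win_s,
                beta=0.5,
                n_channels=n_ch,
                seed=dcs_children[kidx],
            )
            kidx += 1
            for ch in range(n_ch):
                parts[ch].append(sim.streams[ch].timestamps + i * win_ps)
        dcs_streams[rho] = [
            PhotonTagStream(
                timestamps=np.concatenate(p), channel=ch, duration=n * win_s
            )
            for ch, p in enumerate(parts)
        ]
    return OcclusionDataset(
        spec=spec, truth=truth, irf=irf, dtofs=dtofs, dcs_streams=dcs_streams, basis=basis
    )


def simulate_pulsatile_bfi(
    heart_rate: float = 1.2,
    amplitude: float = 0.3,
    harmonics: int = 2,
    fs: float = 100.0 / 3.0,
    duration: float = 60.0,
    db_0: float = 1e-8,
    rho: float = 1.5,
    props: OpticalProperties | None = None,
    count_rate: float = 100e3,
    n_channels: int = 1,
    seed: int = 0,
):
    """Photon-tag streams with a cardiac-modulated Brownian coefficient.

    DB(t) = db_0 (1 + sum_i (amplitude/i) cos(2 pi i HR t)); streams are
    generated per sample window (1/fs) with piecewise-constant DB.

    Returns (streams, truth dict with per-window t and DB).
    """
    if fs <= 2.0 * harmonics * heart_rate:
        raise ValueError("sampling rate violates the Nyquist limit for the requested harmonics")
    props = props or OpticalProperties(mua=0.15, musp=9.0, n=1.4, wavelength=785.0)
    n = int(round(duration * fs))
    win_s = 1.0 / fs
    win_ps = int(round(win_s * PS_PER_S))
    tt = (np.arange(n) + 0.5) * win_s
    mod = np.zeros(n)
    for i in range(1, harmonics + 1):
        mod += (amplitude / i) * np.cos(2 * np.pi * i * heart_rate * tt)
    db_t = np.clip(db_0 * (1.0 + mod), 1e-11, None)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    parts = [[] for _ in range(n_channels)]
    for i in range(n):
        dbi = float(db_t[i])
        sim = simulate_speckle_tags(
            lambda tau, dbi=dbi: g1_semi_infinite(
                tau, rho, props, DynamicsParams(DB=dbi, beta=0.5), 785.0
            ),
            count_rate=count_rate,
            duration=win_s,
            beta=0.5,
            n_channels=n_channels,
            seed=children[i],
        )
        for ch in range(n_channels):
            parts[ch].append(sim.streams[ch].timestamps + i * win_ps)
    streams = [
        PhotonTagStream(timestamps=np.concatenate(p), channel=ch, duration=n * win_s)
        for ch, p in enumerate(parts)
    ]
    return streams, {"t": tt, "DB": db_t}
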