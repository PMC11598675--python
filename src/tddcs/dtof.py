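"""DTOF/IRF containers, TCSPC performance descriptors and time gating.

The DTOF (distribution of times of flight) is the TCSPC histogram of photon
arrival delays on a fixed channel grid (default width 9.77 ps).  This module
holds the histogram containers, their CSV round-trip I/O, and the
basic-instrument-performance descriptors: detection responsivity,
afterpulsing ratio, IRF background / center of mass / FWHM, differential
nonlinearity, and gate-count extraction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.constants as const

__all__ = [
    "DTOF",
    "IRFRecord",
    "GateSpec",
    "RadiometricMeasurement",
    "responsivity",
    "radiance_photons",
    "afterpulsing_ratio",
    "irf_descriptors",
    "dnl_curve",
    "apply_dnl_correction",
    "gate_counts",
    "read_dtof_csv",
    "write_dtof_csv",
]


@dataclass
class DTOF:
    """TCSPC histogram: photon counts per time channel.

    counts: non-negative per-channel counts
    dt: channel width, ps
    t0: time of the leading edge of channel 0, ps
    T_rep: laser repetition period, ps
    acq_time: acquisition (integration) time, s
    wavelength: nm
    rho: source-detector distance, cm
    """

    counts: np.ndarray
    dt: float = 9.77
    t0: float = 0.0
    T_rep: float = 12500.0
    acq_time: float = 1.0
    wavelength: float = 830.0
    rho: float = 2.5

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if len(self.counts) * self.dt > self.T_rep + 1e-9:
            raise ValueError("histogram span exceeds the laser period")

    @property
    def t(self) -> np.ndarray:
        """Channel-center times, ps."""
        return self.t0 + (np.arange(len(self.counts)) + 0.5) * self.dt

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def count_rate(self) -> float:
        """Detected photon rate, Hz."""
        return self.total / self.acq_time

    def copy(self, **changes) -> "DTOF":
        out = replace(self, **changes)
        out.counts = np.array(out.counts)
        return out


@dataclass
class IRFRecord:
    """Measured instrument response function plus its shape descriptors."""

    histogram: DTOF
    background: float = 0.0  # counts/channel
    center_of_mass: float = 0.0  # ps
    fwhm: float = 0.0  # ps

    @classmethod
    def from_histogram(cls, h: DTOF, **kwargs) -> "IRFRecord":
        bg, com, fwhm = irf_descriptors(h, **kwargs)
        return cls(histogram=h, background=bg, center_of_mass=com, fwhm=fwhm)


@dataclass
class GateSpec:
    """Half-open time gates [start, stop) in ps.

    `reference` is 'absolute' (relative to the histogram time axis) or
    'peak' (relative to the DTOF peak channel center).
    """

    gates: list
    reference: str = "absolute"

    def __post_init__(self):
        for a, b in self.gates:
            if not a < b:
                raise ValueError(f"gate start must be < stop, got ({a}, {b})")
        if self.reference not in ("absolute", "peak"):
            raise ValueError("reference must be 'absolute' or 'peak'")

    @classmethod
    def uniform(cls, start: float, stop: float, width: float, reference: str = "peak"):
        edges = np.arange(start, stop + 0.5 * width, width)
        return cls([(a, b) for a, b in zip(edges[:-1], edges[1:])], reference=reference)


@dataclass
class RadiometricMeasurement:
    """Inputs of the responsivity measurement on a calibrated phantom."""

    N_tot: float  # total detected counts
    t_meas: float  # s
    P_in: float  # W
    kappa: float  # diffuse transmittance factor of the phantom, 1/(m^2 sr)
    wavelength: float = 830.0  # nm

    def __post_init__(self):
        if min(self.N_tot, self.t_meas, self.P_in, self.kappa) <= 0:
            raise ValueError("all radiometric inputs must be positive")


def radiance_photons(P_in: float, kappa: float, wavelength_nm: float) -> float:
    """Radiance behind the calibrated phantom, photons s^-1 m^-2 sr^-1.

    L = P_in * kappa converted from watts to photons/s at the given
    wavelength (photon energy h c / lambda).
    """
    e_photon = const.h * const.c / (wavelength_nm * 1e-9)
    return P_in * kappa / e_photon


def responsivity(m: RadiometricMeasurement, L_photons: float | None = None) -> float:
    """Detection-system responsivity s = N_tot / (t_meas * L), m^2 sr.

    `L_photons` (photons s^-1 m^-2 sr^-1) overrides the radiance computed
    from the calibrated-phantom transmittance.
    """
    L = radiance_photons(m.P_in, m.kappa, m.wavelength) if L_photons is None else L_photons
    return m.N_tot / (m.t_meas * L)


def irf_descriptors(
    h: DTOF,
    bg_window_frac: float = 0.10,
    support_frac: float = 0.01,
):
    """IRF shape descriptors: (background, center of mass, FWHM).

    background : mean counts/channel over a pre-peak window (the first
        `bg_window_frac` of the channels before the rising edge).
    center of mass : first moment of the background-subtracted counts over
        the support where they exceed `support_frac` of the peak.
    FWHM : linear interpolation between the channels crossing half maximum.
    """
    c = h.counts.astype(float)
    n = len(c)
    ipk = int(np.argmax(c))
    # rising edge: last pre-peak channel below 10% of peak
    pre = np.nonzero(c[:ipk] < 0.1 * c[ipk])[0]
    edge = int(pre[-1]) + 1 if len(pre) else 0
    win = max(1, min(int(bg_window_frac * n), edge))
    bg = float(c[:win].mean()) if edge > 0 else 0.0
    cs = np.clip(c - bg, 0.0, None)
    peak = cs[ipk]
    if peak <= 0:
        raise ValueError("no peak above background")
    t = h.t
    # contiguous support around the peak above the threshold
    thr = support_frac * peak
    lo = ipk
    while lo > 0 and cs[lo - 1] >= thr:
        lo -= 1
    hi = ipk
    while hi < n - 1 and cs[hi + 1] >= thr:
        hi += 1
    support = np.arange(lo, hi + 1)
    com = float(np.sum(t[support] * cs[support]) / np.sum(cs[support]))

    half = 0.5 * peak
    # rising crossing
    i = ipk
    while i > 0 and cs[i - 1] >= half:
        i -= 1
    if i == 0:
        raise ValueError("half maximum not crossed on the rising edge")
    t_rise = np.interp(half, [cs[i - 1], cs[i]], [t[i - 1], t[i]])
    j = ipk
    while j < n - 1 and cs[j + 1] >= half:
        j += 1
    if j == n - 1:
        raise ValueError("half maximum not crossed on the falling edge")
    t_fall = np.interp(half, [cs[j + 1], cs[j]], [t[j + 1], t[j]])
    return bg, com, float(t_fall - t_rise)


def afterpulsing_ratio(irf: IRFRecord, dark: DTOF | float = 0.0) -> float:
    """Afterpulsing ratio R_AP = (N_bkg - N_dark) T / (N_tot dt).

    N_bkg and N_dark are per-channel background levels of the IRF and of a
    source-off ("dark") measurement; T is the laser period; N_tot the total
    IRF counts after background subtraction.  Dimensionless (multiply by 100
    for %).
    """
    h = irf.histogram
    if isinstance(dark, DTOF):
        if abs(dark.dt - h.dt) > 1e-9:
            raise ValueError("IRF and dark histograms must share dt")
        n_dark = float(dark.counts.mean())
    else:
        n_dark = float(dark)
    n_bkg = irf.background
    n_tot = float(np.clip(h.counts - n_bkg, 0, None).sum())
    if n_tot == 0:
        raise ZeroDivisionError("IRF has no counts above background")
    return (n_bkg - n_dark) * h.T_rep / (n_tot * h.dt)


def dnl_curve(cw_hist: DTOF):
    """Differential nonlinearity from a constant-illumination histogram.

    Returns (dnl, metric): per-channel counts normalized to their mean
    (exactly mean 1) and the peak deviation max|dnl - 1|.
    """
    c = cw_hist.counts.astype(float)
    if len(c) == 0 or c.sum() == 0:
        raise ValueError("empty histogram")
    dnl = c / c.mean()
    return dnl, float(np.max(np.abs(dnl - 1.0)))


def apply_dnl_correction(h: DTOF, dnl: np.ndarray) -> DTOF:
    """Divide a histogram by a measured DNL curve (channel-width nonuniformity).

    Off by default throughout the package: DNL structure typically falls
    outside the span of a DTOF, so correction is rarely needed.  Counts are
    rounded back to integers.
    """
    dnl = np.asarray(dnl, dtype=float)
    if len(dnl) != len(h.counts):
        raise ValueError("DNL curve length must match the histogram")
    if np.any(dnl <= 0):
        raise ValueError("DNL values must be > 0")
    return h.copy(counts=np.rint(h.counts / dnl).astype(np.int64))


def gate_counts(h: DTOF, gates: GateSpec) -> np.ndarray:
    """Photon counts per time gate.

    Gate boundaries snap to the nearest channel edge; intervals are
    half-open [start, stop), so gates that partition the axis conserve the
    total count.
    """
    n = len(h.counts)
    offset = h.t[np.argmax(h.counts)] - 0.5 * h.dt if gates.reference == "peak" else 0.0
    out = []
    for a, b in gates.gates:
        ia = int(round((a + offset - h.t0) / h.dt))
        ib = int(round((b + offset - h.t0) / h.dt))
        if ia < 0 or ib > n:
            raise ValueError(f"gate ({a}, {b}) outside histogram support")
        out.append(h.counts[ia:ib].sum())
    return np.asarray(out)


# ---------------------------------------------------------------------------
# CSV I/O: '#key=value' metadata header + one counts column

_META_FIELDS = {
    "dt_ps": ("dt", float),
    "t0_ps": ("t0", float),
    "T_rep_ps": ("T_rep", float),
    "wavelength_nm": ("wavelength", float),
    "rho_cm": ("rho", float),
    "acq_time_s": ("acq_time", float),
}


def write_dtof_csv(h: DTOF, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#dt_ps={h.dt!r}\n#t0_ps={h.t0!r}\n#T_rep_ps={h.T_rep!r}\n")
        fh.write(f"#wavelength_nm={h.wavelength!r}\n#rho_cm={h.rho!r}\n#acq_time_s={h.acq_time!r}\n")
        fh.write("counts\n")
        np.savetxt(fh, h.counts, fmt="%d")


def read_dtof_csv(path) -> DTOF:
    meta = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, v = line[1:].strip().split("=", 1)
                meta[k] = v
            elif line.strip() and line.strip() != "counts":
                body.write(line)
    body.seek(0)
    counts = np.loadtxt(body, dtype=np.int64, ndmin=1)
    kwargs = {attr: typ(meta[key]) for key, (attr, typ) in _META_FIELDS.items() if key in meta}
    return DTOF(counts=counts, **kwargs)
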