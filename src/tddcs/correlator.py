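"""Software correlator over photon time tags.

Computes the intensity autocorrelation g2(tau) of a detected photon stream
on a quasi-logarithmic (multi-tau) lag grid: the first octave holds `m`
linearly spaced lags at the base bin width, every further octave doubles the
bin width and adds the upper half of the lag ladder.  Symmetric
normalization (the mean rates of the two shifted halves of the window) is
used to suppress finite-window bias.

Timestamps are 64-bit integer picoseconds end to end; binning is integer
division, so the correlator is exactly reproducible.

Also provides windowed correlation for fast (e.g. 30 ms) acquisition,
multi-detector curve averaging, the running median filter applied to curve
sequences before fitting, and the variance-sum noise statistic of repeated
curves.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhotonTagStream",
    "CorrelatorConfig",
    "CorrelationCurve",
    "multitau_g2",
    "windowed_g2",
    "average_curves",
    "median_filter_curves",
    "g2_variance_stat",
    "read_ttg1",
    "write_ttg1",
    "read_tags_csv",
    "write_tags_csv",
]

PS_PER_S = 1_000_000_000_000


@dataclass
class PhotonTagStream:
    """Ordered photon arrival times of one detection channel.

    timestamps: strictly increasing arrival times, integer ps
    channel: detector id
    duration: measurement duration, s
    """

    timestamps: np.ndarray
    channel: int = 0
    duration: float = 0.0

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=np.int64)
        if np.any(np.diff(ts) < 0):
            raise ValueError("timestamps must be sorted")
        if self.duration <= 0 and len(ts):
            self.duration = float(ts[-1]) / PS_PER_S
        if len(ts) and (ts[0] < 0 or ts[-1] > self.duration * PS_PER_S + 0.5):
            raise ValueError("timestamps outside [0, duration]")
        self.timestamps = ts

    @property
    def count_rate(self) -> float:
        """Mean detected count rate, Hz."""
        return len(self.timestamps) / self.duration if self.duration else 0.0


@dataclass
class CorrelatorConfig:
    """Multi-tau correlator settings.

    base_bin: finest bin width, s (default 200 ns)
    m: lags per octave (even, >= 2)
    octaves: number of bin-doubling octaves
    normalization: 'symmetric' or 'plain'
    window: window length for `windowed_g2`, s (None = full stream)
    """

    base_bin: float = 200e-9
    m: int = 16
    octaves: int = 20
    normalization: str = "symmetric"
    window: float | None = None

    def __post_init__(self):
        if self.base_bin < 1e-12:
            raise ValueError("base bin must be >= 1 ps")
        if self.m < 2 or self.m % 2:
            raise ValueError("m must be even and >= 2")
        if self.normalization not in ("symmetric", "plain"):
            raise ValueError("unknown normalization scheme")

    @property
    def base_bin_ps(self) -> int:
        return max(1, int(round(self.base_bin * PS_PER_S)))


@dataclass
class CorrelationCurve:
    """Intensity autocorrelation on a multi-tau lag grid."""

    lags: np.ndarray  # s, strictly increasing
    g2: np.ndarray
    count_rate: float = 0.0  # Hz
    window_start: float = 0.0  # s
    window_length: float = 0.0  # s
    channels: tuple = (0,)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if len(self.lags) != len(self.g2):
            raise ValueError("lags and g2 must have the same length")


def _multitau_counts(counts: np.ndarray, bin_ps: int, m: int, octaves: int, normalization: str):
    """Multi-tau g2 from pre-binned counts; returns (lags_ps, g2)."""
    c = counts.astype(np.float64)
    lags, g2 = [], []
    width = bin_ps
    for o in range(octaves):
        ks = range(1, m + 1) if o == 0 else range(m // 2 + 1, m + 1)
        n = len(c)
        csum = np.cumsum(c)  # prefix sums give both shifted means in O(1)
        total = csum[-1]
        for k in ks:
            if n - k < 8:  # not enough products for a meaningful estimate
                break
            num = np.dot(c[: n - k], c[k:]) / (n - k)
            if normalization == "symmetric":
                den = (csum[n - k - 1] / (n - k)) * ((total - csum[k - 1]) / (n - k))
            else:
                mu = total / n
                den = mu * mu
            lags.append(k * width)
            g2.append(num / den if den > 0 else np.nan)
        if len(c) // 2 < m + 8:
            break
        c = c[: 2 * (len(c) // 2)].reshape(-1, 2).sum(axis=1)
        width *= 2
    return np.asarray(lags, dtype=float), np.asarray(g2, dtype=float)


def _bin_window(ts: np.ndarray, start_ps: int, length_ps: int, bin_ps: int) -> np.ndarray:
    n_bins = length_ps // bin_ps
    rel = ts - start_ps
    idx = rel // bin_ps
    idx = idx[(idx >= 0) & (idx < n_bins)]
    return np.bincount(idx.astype(np.int64), minlength=int(n_bins))


def multitau_g2(s: PhotonTagStream, cfg: CorrelatorConfig | None = None) -> CorrelationCurve:
    """Multi-tau intensity autocorrelation of a full photon stream.

    g2(tau) = <n(t) n(t+tau)> / (<n(t)><n(t+tau)>) with the means restricted
    to the overlapping parts of the window (symmetric normalization).
    """
    cfg = cfg or CorrelatorConfig()
    if len(s.timestamps) == 0:
        raise ValueError("empty photon stream")
    dur_ps = int(round(s.duration * PS_PER_S))
    counts = _bin_window(s.timestamps, 0, dur_ps, cfg.base_bin_ps)
    lags_ps, g2 = _multitau_counts(counts, cfg.base_bin_ps, cfg.m, cfg.octaves, cfg.normalization)
    return CorrelationCurve(
        lags=lags_ps / PS_PER_S,
        g2=g2,
        count_rate=s.count_rate,
        window_start=0.0,
        window_length=s.duration,
        channels=(s.channel,),
    )


def windowed_g2(s: PhotonTagStream, cfg: CorrelatorConfig) -> list:
    """One correlation curve per contiguous, non-overlapping window.

    Photons on a window boundary belong to the window containing their
    timestamp (half-open windows).  Windows that would extend past the end
    of the stream are dropped.
    """
    if cfg.window is None:
        raise ValueError("CorrelatorConfig.window must be set for windowed_g2")
    if cfg.window > s.duration + 1e-12:
        raise ValueError("window longer than the stream")
    win_ps = int(round(cfg.window * PS_PER_S))
    n_win = int(round(s.duration * PS_PER_S)) // win_ps
    curves = []
    ts = s.timestamps
    for w in range(n_win):
        a = w * win_ps
        lo, hi = np.searchsorted(ts, [a, a + win_ps])
        counts = _bin_window(ts[lo:hi], a, win_ps, cfg.base_bin_ps)
        lags_ps, g2 = _multitau_counts(counts, cfg.base_bin_ps, cfg.m, cfg.octaves, cfg.normalization)
        curves.append(
            CorrelationCurve(
                lags=lags_ps / PS_PER_S,
                g2=g2,
                count_rate=(hi - lo) / cfg.window,
                window_start=a / PS_PER_S,
                window_length=cfg.window,
                channels=(s.channel,),
            )
        )
    return curves


def average_curves(curves) -> CorrelationCurve:
    """Count-rate-weighted average of curves from several detectors.

    The curves must share the lag grid; g2 - 1 is averaged with weights
    proportional to the count rate and re-offset to g2.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if len(c.lags) != len(lags) or not np.allclose(c.lags, lags):
            raise ValueError("curves have mismatched lag grids")
    w = np.array([c.count_rate for c in curves], dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(curves))
    w = w / w.sum()
    g2m1 = np.sum([wi * (c.g2 - 1.0) for wi, c in zip(w, curves)], axis=0)
    return CorrelationCurve(
        lags=lags,
        g2=1.0 + g2m1,
        count_rate=float(np.sum([c.count_rate for c in curves])),
        window_start=curves[0].window_start,
        window_length=curves[0].window_length,
        channels=tuple(ch for c in curves for ch in c.channels),
    )


def median_filter_curves(curves, k: int = 5) -> list:
    """Running median over `k` consecutive curves, pointwise in lag.

    Edge windows shrink symmetrically.  Applied to curve sequences before
    fitting to reject transient outliers.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    curves = list(curves)
    n = len(curves)
    if n == 0:
        return []
    stack = np.stack([c.g2 for c in curves])
    half = k // 2
    out = []
    for i in range(n):
        h = min(half, i, n - 1 - i)
        med = np.median(stack[i - h : i + h + 1], axis=0)
        c = curves[i]
        out.append(
            CorrelationCurve(
                lags=c.lags,
                g2=med,
                count_rate=c.count_rate,
                window_start=c.window_start,
                window_length=c.window_length,
                channels=c.channels,
            )
        )
    return out


def g2_variance_stat(curves) -> float:
    """sqrt of the summed per-lag variance of repeated g2 curves.

    A raw-signal noise figure: sqrt( sum_lags Var_repetitions[g2(tau)] ),
    with sample (n-1) variances.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    stack = np.stack([c.g2 for c in curves])
    return float(np.sqrt(np.var(stack, axis=0, ddof=1).sum()))


# ---------------------------------------------------------------------------
# Time-tag I/O: binary "TTG1" and CSV

_TTG1_MAGIC = b"TTG1"
_REC = np.dtype([("channel", "u1"), ("time_ps", "<u8")])


def write_ttg1(path, streams) -> None:
    """Write photon tag streams to the TTG1 binary format.

    16-byte header: magic 'TTG1', version u16, channel count u16, reserved
    u64; then (u8 channel, u64 LE picoseconds) records in global time order.
    """
    streams = list(streams)
    recs = np.concatenate(
        [
            np.rec.fromarrays(
                [np.full(len(s.timestamps), s.channel, dtype="u1"), s.timestamps.astype("<u8")],
                dtype=_REC,
            )
            for s in streams
        ]
    )
    recs = recs[np.argsort(recs["time_ps"], kind="stable")]
    with open(path, "wb") as fh:
        fh.write(_TTG1_MAGIC + struct.pack("<HHQ", 1, len(streams), 0))
        recs.tofile(fh)


def read_ttg1(path, duration: float | None = None) -> list:
    """Read a TTG1 file back into per-channel PhotonTagStream objects."""
    with open(path, "rb") as fh:
        head = fh.read(16)
        if head[:4] != _TTG1_MAGIC:
            raise ValueError("not a TTG1 file")
        version, n_ch, _ = struct.unpack("<HHQ", head[4:])
        if version != 1:
            raise ValueError(f"unsupported TTG1 version {version}")
        recs = np.fromfile(fh, dtype=_REC)
    streams = []
    for ch in sorted(set(recs["channel"].tolist())):
        ts = recs["time_ps"][recs["channel"] == ch].astype(np.int64)
        if np.any(np.diff(ts) < 0):
            raise ValueError(f"non-monotone timestamps on channel {ch}")
        streams.append(PhotonTagStream(timestamps=ts, channel=int(ch), duration=duration or 0.0))
    return streams


def write_tags_csv(path, streams) -> None:
    streams = list(streams)
    recs = np.concatenate(
        [np.stack([np.full(len(s.timestamps), s.channel), s.timestamps], axis=1) for s in streams]
    )
    recs = recs[np.argsort(recs[:, 1], kind="stable")]
    np.savetxt(path, recs, fmt="%d", delimiter=",", header="channel,time_ps", comments="")


def read_tags_csv(path, duration: float | None = None) -> list:
    data = np.loadtxt(path, dtype=np.int64, delimiter=",", skiprows=1, ndmin=2)
    streams = []
    for ch in sorted(set(data[:, 0].tolist())):
        ts = data[data[:, 0] == ch, 1]
        streams.append(PhotonTagStream(timestamps=ts, channel=int(ch), duration=duration or 0.0))
    return streams
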