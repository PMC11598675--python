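"""Performance-assessment protocol statistics.

Implements the standardized characterization figures for TD diffuse-optics
and DCS instruments computed from repeated measurement sets:

* gated perturbation contrast C_k = -log(N_k / N_k,ref), contrast-to-noise
  ratio CNR_k = C_k / sigma[log N_k], depth selectivity S_k = C_UP/C_DOWN
  and the longitudinal resolution (FWHM of the contrast bell curve),
* noise scans: coefficient of variation of fitted parameters vs photon
  counts (TD NIRS) or vs count rate / duration / channel count (DCS), with
  log-log slopes and threshold interpolation,
* stability (warm-up detection, post-warm-up CV), day-to-day
  reproducibility, and linearity/accuracy/coupling analysis over a phantom
  grid.

All statistics use sample (n-1) standard deviations and natural logarithms
unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "neuropt_contrast",
    "neuropt_cnr",
    "neuropt_selectivity",
    "scan_fwhm",
    "ContrastScan",
    "analyze_inclusion_scan",
    "SelectivityResult",
    "analyze_selectivity",
    "NoiseScanResult",
    "medphot_noise_scan",
    "dcs_noise_scan",
    "StabilityResult",
    "stability_metrics",
    "reproducibility_cv",
    "medphot_linearity",
]


def _log(x, base: str):
    return np.log(x) if base == "e" else np.log10(x)


def neuropt_contrast(N_k, N_k_ref, base: str = "e"):
    """Perturbation contrast C_k = -log(N_k / N_k,ref).

    Natural logarithm by default (`base='10'` switches).  Positive for an
    absorbing perturbation (N_k < N_k,ref).
    """
    N_k = np.asarray(N_k, dtype=float)
    N_k_ref = np.asarray(N_k_ref, dtype=float)
    if np.any(N_k <= 0) or np.any(N_k_ref <= 0):
        raise ValueError("counts must be > 0")
    return -_log(N_k / N_k_ref, base)


def neuropt_cnr(C_k, log_counts_reps, axis: int = 0):
    """Contrast-to-noise ratio CNR_k = C_k / sigma[log N_k].

    `log_counts_reps` holds log N_k per repetition along `axis`; the sample
    (n-1) standard deviation across repetitions is the noise term.
    """
    log_counts_reps = np.asarray(log_counts_reps, dtype=float)
    if log_counts_reps.shape[axis] < 2:
        raise ValueError("need >= 2 repetitions")
    sigma = np.std(log_counts_reps, axis=axis, ddof=1)
    if np.any(sigma == 0):
        raise ZeroDivisionError("zero repetition variance: CNR undefined")
    return np.asarray(C_k, dtype=float) / sigma


def neuropt_selectivity(C_up, C_down):
    """Depth selectivity per gate and absorption step.

    Ratio of the deep-layer to the superficial-layer contrast,
    S_k = C_DOWN / C_UP: the figure of merit for rejecting extracerebral
    (superficial) absorption changes.  Late gates and larger
    source-detector distances give higher S.  S = 1 when the two contrasts
    are equal.
    """
    C_up = np.asarray(C_up, dtype=float)
    if np.any(C_up == 0):
        raise ZeroDivisionError("zero upper-layer contrast: selectivity undefined")
    return np.asarray(C_down, dtype=float) / C_up


def scan_fwhm(x, contrast):
    """FWHM (same units as `x`) of a single-peaked contrast profile,
    with linear interpolation between the half-maximum crossings."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(contrast, dtype=float)
    ipk = int(np.argmax(c))
    peak = c[ipk]
    if peak <= 0 or ipk == 0 or ipk == len(c) - 1:
        raise ValueError("no interior peak in the profile")
    half = 0.5 * peak
    i = ipk
    while i > 0 and c[i - 1] >= half:
        i -= 1
    if i == 0:
        raise ValueError("half maximum not crossed on the left")
    xl = np.interp(half, [c[i - 1], c[i]], [x[i - 1], x[i]])
    j = ipk
    while j < len(c) - 1 and c[j + 1] >= half:
        j += 1
    if j == len(c) - 1:
        raise ValueError("half maximum not crossed on the right")
    xr = np.interp(half, [c[j + 1], c[j]], [x[j + 1], x[j]])
    return float(xr - xl)


@dataclass
class ContrastScan:
    """Per-gate contrast/CNR along a spatial scan coordinate."""

    positions: np.ndarray  # cm
    contrast: np.ndarray  # (n_pos, n_gates)
    cnr: np.ndarray  # (n_pos, n_gates)
    sigma_log: np.ndarray  # (n_pos, n_gates)
    gates: object


def analyze_inclusion_scan(sim: dict, base: str = "e") -> ContrastScan:
    """Contrast and CNR from a `simulate_inclusion_scan` output.

    Contrast uses gate counts summed over repetitions; the CNR denominator
    is the per-repetition standard deviation of log N_k.
    """
    gc = sim["gate_counts"]  # (n_pos, n_rep, n_gates)
    ref = sim["ref_counts"]  # (n_rep, n_gates)
    N = gc.sum(axis=1)
    N_ref = ref.sum(axis=0)[None, :]
    C = neuropt_contrast(N, N_ref, base=base)
    logs = _log(np.clip(gc, 1, None).astype(float), base)
    sigma = np.std(logs, axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        cnr = np.where(sigma > 0, C / sigma, np.inf)
    return ContrastScan(
        positions=sim["positions"], contrast=C, cnr=cnr, sigma_log=sigma, gates=sim["gates"]
    )


@dataclass
class SelectivityResult:
    """Depth selectivity vs absorption change, per gate."""

    dmua: np.ndarray  # 1/cm
    C_up: np.ndarray  # (n_dmua, n_gates)
    C_down: np.ndarray
    S: np.ndarray
    gates: object


def analyze_selectivity(sim: dict, base: str = "e") -> SelectivityResult:
    """Selectivity from a `simulate_selectivity_dataset` output."""
    ref = sim["ref"].sum(axis=0)[None, :]
    C_up = neuropt_contrast(sim["up"].sum(axis=1), ref, base=base)
    C_dn = neuropt_contrast(sim["down"].sum(axis=1), ref, base=base)
    return SelectivityResult(
        dmua=sim["dmua"], C_up=C_up, C_down=C_dn, S=neuropt_selectivity(C_up, C_dn), gates=sim["gates"]
    )


@dataclass
class NoiseScanResult:
    """CV of a fitted quantity vs an acquisition variable, log-log fitted."""

    levels: np.ndarray  # count levels / rates / durations
    cv_percent: np.ndarray
    slope: float
    slope_stderr: float
    intercept: float
    r_squared: float

    def level_at_cv(self, cv_percent: float, method: str = "fit") -> float:
        """Acquisition level at which the CV crosses `cv_percent`.

        'fit' inverts the fitted log-log line; 'interp' interpolates
        piecewise-linearly in log-log space between measured levels.
        """
        if method == "fit":
            return float(10.0 ** ((np.log10(cv_percent) - self.intercept) / self.slope))
        order = np.argsort(self.cv_percent)
        return float(
            10.0
            ** np.interp(
                np.log10(cv_percent),
                np.log10(self.cv_percent[order]),
                np.log10(self.levels[order]),
            )
        )


def _cv_scan(levels, values_by_level, min_levels: int) -> NoiseScanResult:
    levels = np.asarray(levels, dtype=float)
    cvs = []
    for vals in values_by_level:
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            cvs.append(np.nan)
        else:
            cvs.append(100.0 * np.std(vals, ddof=1) / np.mean(vals))
    cvs = np.asarray(cvs)
    ok = np.isfinite(cvs) & (cvs > 0)
    if ok.sum() < min_levels:
        raise ValueError(f"need >= {min_levels} valid levels for the log-log fit")
    reg = stats.linregress(np.log10(levels[ok]), np.log10(cvs[ok]))
    return NoiseScanResult(
        levels=levels,
        cv_percent=cvs,
        slope=float(reg.slope),
        slope_stderr=float(reg.stderr),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
    )


def medphot_noise_scan(results_by_counts: dict, param: str = "mua") -> NoiseScanResult:
    """CV of a fitted optical parameter vs total DTOF counts.

    `results_by_counts` maps the target photon count to a sequence of fit
    results (objects exposing `param`, e.g. `NirsFitResult`) or plain
    values; needs >= 3 levels with >= 5 repetitions each.
    """
    levels = sorted(results_by_counts)
    values = []
    for lev in levels:
        seq = results_by_counts[lev]
        vals = [getattr(r, param, r) for r in seq]
        if len(vals) < 5:
            raise ValueError("need >= 5 repetitions per count level")
        values.append(np.asarray(vals, dtype=float))
    if len(levels) < 3:
        raise ValueError("need >= 3 count levels")
    return _cv_scan(levels, values, min_levels=2)


def dcs_noise_scan(db_by_level: dict, min_windows: int = 10) -> NoiseScanResult:
    """CV of fitted DB vs a swept acquisition factor (count rate, duration
    or number of averaged channels).

    `db_by_level` maps the factor level to the fitted DB per analysis
    window; each level needs >= `min_windows` windows.
    """
    levels = sorted(db_by_level)
    if len(levels) < 3:
        raise ValueError("need >= 3 levels of the swept factor")
    values = []
    for lev in levels:
        vals = np.asarray(db_by_level[lev], dtype=float)
        if len(vals) < min_windows:
            raise ValueError(f"need >= {min_windows} windows per level")
        values.append(vals)
    return _cv_scan(levels, values, min_levels=2)


@dataclass
class StabilityResult:
    """Warm-up time and post-warm-up stability of a monitored quantity."""

    warmup_s: float
    cv_percent: float
    stabilized: bool
    reference: float


def stability_metrics(
    series, fs: float, band_percent: float = 1.0, ref_frac: float = 0.10
) -> StabilityResult:
    """Warm-up detection on a long stability measurement.

    The reference is the mean of the final `ref_frac` of the series; the
    warm-up time is the first instant after which the series stays within
    +/- `band_percent` % of the reference for the rest of the measurement.
    The CV is computed on the post-warm-up samples.
    """
    x = np.asarray(series, dtype=float)
    n_ref = max(2, int(round(ref_frac * len(x))))
    if len(x) <= n_ref:
        raise ValueError("series shorter than the trailing reference window")
    ref = float(x[-n_ref:].mean())
    inside = np.abs(x - ref) <= abs(ref) * band_percent / 100.0
    # last index where the series is outside the band
    outside = np.nonzero(~inside)[0]
    if len(outside) == 0:
        i0 = 0
    elif outside[-1] == len(x) - 1:
        return StabilityResult(warmup_s=len(x) / fs, cv_percent=np.nan, stabilized=False, reference=ref)
    else:
        i0 = int(outside[-1]) + 1
    post = x[i0:]
    cv = 100.0 * np.std(post, ddof=1) / np.mean(post) if len(post) > 1 else 0.0
    return StabilityResult(warmup_s=i0 / fs, cv_percent=float(cv), stabilized=True, reference=ref)


def reproducibility_cv(per_day_values) -> float:
    """Inter-day reproducibility: CV (%) across per-day mean estimates."""
    v = np.asarray(per_day_values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 days")
    return float(100.0 * np.std(v, ddof=1) / np.mean(v))


def medphot_linearity(df):
    """Linearity / accuracy / coupling over a phantom grid.

    `df` is a DataFrame with columns mua_conv, musp_conv, mua_meas,
    musp_meas (conventional = reference values).  Returns a dict with:

    - 'mua_slope', 'musp_slope': regression slopes of measured on
      conventional, pooled over the grid (1 = perfect linearity);
    - 'mua_rel_err', 'musp_rel_err': mean absolute relative errors;
    - 'coupling_musp_on_mua': slope of measured musp vs conventional mua
      (normalized by the series-mean musp, per musp series, averaged);
    - 'coupling_mua_on_musp': the reverse coupling.
    """
    need = {"mua_conv", "musp_conv", "mua_meas", "musp_meas"}
    if not need <= set(df.columns):
        raise ValueError(f"missing columns: {need - set(df.columns)}")
    if df["mua_conv"].nunique() < 3 or df["musp_conv"].nunique() < 3:
        raise ValueError("need >= 3 phantoms per series")

    out = {}
    nz = df[df["mua_conv"] > 0]
    out["mua_slope"] = float(stats.linregress(df["mua_conv"], df["mua_meas"]).slope)
    out["musp_slope"] = float(stats.linregress(df["musp_conv"], df["musp_meas"]).slope)
    out["mua_rel_err"] = float(np.mean(np.abs(nz["mua_meas"] / nz["mua_conv"] - 1.0)))
    out["musp_rel_err"] = float(np.mean(np.abs(df["musp_meas"] / df["musp_conv"] - 1.0)))

    coup_sm = []
    for _, grp in df.groupby("musp_conv"):
        if grp["mua_conv"].nunique() >= 3:
            sl = stats.linregress(grp["mua_conv"], grp["musp_meas"]).slope
            coup_sm.append(sl / grp["musp_meas"].mean())
    coup_ms = []
    for _, grp in df.groupby("mua_conv"):
        if grp["musp_conv"].nunique() >= 3 and grp["mua_meas"].mean() != 0:
            sl = stats.linregress(grp["musp_conv"], grp["mua_meas"]).slope
            coup_ms.append(sl / max(grp["mua_meas"].mean(), 1e-12))
    out["coupling_musp_on_mua"] = float(np.mean(coup_sm)) if coup_sm else np.nan
    out["coupling_mua_on_musp"] = float(np.mean(coup_ms)) if coup_ms else np.nan
    return out
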