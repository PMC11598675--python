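"""Standard characterization figures.

Thin matplotlib helpers for the protocol reports: gated contrast vs depth,
CV vs counts on log-log axes, and depth selectivity vs absorption change.
Each returns the Axes for further styling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_contrast_scan", "plot_noise_scan", "plot_selectivity"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_contrast_scan(scan, gate_labels=None, ax=None):
    """Per-gate contrast along the scan coordinate (depth or lateral)."""
    ax = _ax(ax)
    labels = gate_labels or [f"gate {k}" for k in range(scan.contrast.shape[1])]
    for k, lab in enumerate(labels):
        ax.plot(scan.positions * 10.0, scan.contrast[:, k], label=lab)
    ax.set_xlabel("position [mm]")
    ax.set_ylabel("contrast C")
    ax.legend()
    return ax


def plot_noise_scan(res, cv_threshold=None, ax=None, xlabel="total counts"):
    """CV vs acquisition level on log-log axes with the fitted line."""
    ax = _ax(ax)
    ax.loglog(res.levels, res.cv_percent, "o")
    xx = np.logspace(np.log10(res.levels.min()), np.log10(res.levels.max()), 50)
    ax.loglog(xx, 10.0**res.intercept * xx**res.slope, "--", label=f"slope {res.slope:.2f}")
    if cv_threshold is not None:
        ax.axhline(cv_threshold, color="gray", lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("CV [%]")
    ax.legend()
    return ax


def plot_selectivity(sel, gate_labels=None, ax=None):
    """Depth selectivity vs absorption change, one line per gate."""
    ax = _ax(ax)
    labels = gate_labels or [f"gate {k}" for k in range(sel.S.shape[1])]
    for k, lab in enumerate(labels):
        ax.plot(sel.dmua, sel.S[:, k], label=lab)
    ax.set_xlabel("absorption change [1/cm]")
    ax.set_ylabel("selectivity S")
    ax.legend()
    return ax
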