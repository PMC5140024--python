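"""Matplotlib/seaborn renderers for the standard chronobiology figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .circadian import Periodogram
from .profiles import ClusterResult, DailyProfile

__all__ = ["plot_actogram", "plot_periodogram", "plot_daily_profile",
           "plot_cluster_heatmap", "plot_bland_altman"]


def plot_actogram(matrix: np.ndarray, bin_s: int, ax=None, title: str = ""):
    """Raster actogram from an (optionally double-plotted) day x bin matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2, 0.25 * matrix.shape[0])))
    days, cols = matrix.shape
    for d in range(days):
        row = np.nan_to_num(matrix[d], nan=0.0)
        ax.bar(np.arange(cols), row / max(row.max(), 1e-9) * 0.9,
               bottom=days - 1 - d, width=1.0, color="black", align="edge")
    hours = cols * bin_s / 3600
    ticks = np.arange(0, cols + 1, max(1, int(6 * 3600 / bin_s)))
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"{int(t * bin_s / 3600) % 24}" for t in ticks])
    ax.set_xlim(0, cols)
    ax.set_ylim(0, days)
    ax.set_ylabel("day")
    ax.set_xlabel(f"time (h, {hours:.0f} h per row)")
    if title:
        ax.set_title(title)
    return ax


def plot_periodogram(pg: Periodogram, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    h = pg.periods_s / 3600.0
    ax.plot(h, pg.qp, color="black", label="Qp")
    ax.plot(h, pg.significance_line, color="red", lw=0.8,
            label=f"chi-sq p={pg.alpha:g}")
    if pg.peak_period_s is not None:
        ax.axvline(pg.peak_period_h, color="grey", ls=":")
    ax.set_xlabel("period (h)")
    ax.set_ylabel("Qp")
    ax.legend(frameon=False)
    return ax


def plot_daily_profile(profile: DailyProfile, ax=None, color="C0", label=""):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    t = np.arange(profile.n_bins) * profile.bin_s / 3600.0
    ax.plot(t, profile.mean, color=color, label=label)
    ax.fill_between(t, profile.mean - profile.sem, profile.mean + profile.sem,
                    color=color, alpha=0.3, lw=0)
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel("mean activity")
    ax.set_xlim(0, 24)
    return ax


def plot_cluster_heatmap(result: ClusterResult, ax=None):
    """Leaf-ordered profile heatmap (dendrogram ordering already applied)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.3 * len(result.order) + 1))
    sns.heatmap(result.matrix, yticklabels=result.ordered_labels,
                cmap="viridis", cbar_kws={"label": "z-scored activity"
                                          if result.normalise else "activity"},
                ax=ax)
    ax.set_xlabel("time-of-day bin")
    return ax


def plot_bland_altman(pir, eeg, ax=None):
    from .agreement import bland_altman
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    pir = np.asarray(pir, dtype=float)
    eeg = np.asarray(eeg, dtype=float)
    ba = bland_altman(pir, eeg)
    ax.scatter((pir + eeg) / 2.0, pir - eeg, s=8, alpha=0.5)
    for y, ls in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="red", ls=ls, lw=0.8)
    ax.set_xlabel("mean of methods (min)")
    ax.set_ylabel("PIR - EEG (min)")
    return ax
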