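"""Circadian rhythm analysis: chi-squared periodogram, actograms, light
schedules, activity onsets, and nonparametric stability statistics.

The chi-squared periodogram (Sokolove & Bushell) folds a binned activity
series at each candidate period P (an integer number of bins), forming K
complete rows of P columns, and computes

    Qp = K * N * sum_h (M_h - Mbar)^2 / sum_i (x_i - Mbar)^2

over the N = K*P bins used, where M_h are the column means and Mbar the grand
mean.  Under the null (no rhythm at P), Qp is approximately chi-square with
P - 1 degrees of freedom, giving a per-period significance line at the
(1 - alpha) quantile.  The statistic is invariant to affine rescaling of the
activity values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RhythmError, ScheduleError

__all__ = [
    "Periodogram", "chi_squared_periodogram",
    "actogram_matrix",
    "LightSchedule", "infer_light_schedule",
    "activity_onset", "activity_onsets",
    "interdaily_stability", "intradaily_variability",
]

LIGHT, DARK = "LIGHT", "DARK"


# --------------------------------------------------------------------------
# chi-squared periodogram

@dataclass
class Periodogram:
    """Qp per candidate period, with its chi-square significance line."""

    periods_s: np.ndarray
    qp: np.ndarray
    df: np.ndarray
    significance_line: np.ndarray
    alpha: float
    bin_s: int
    peak_period_s: float | None

    @property
    def peak_period_h(self) -> float | None:
        return None if self.peak_period_s is None else self.peak_period_s / 3600.0

    def summary(self) -> str:
        lines = [f"Chi-squared periodogram ({len(self.periods_s)} candidate "
                 f"periods, {self.bin_s} s bins, alpha={self.alpha:g})"]
        if self.peak_period_s is None:
            lines.append("no candidate period exceeds the significance line")
        else:
            i = int(np.argmax(self.qp - self.significance_line))
            lines.append(f"peak period: {self.peak_period_h:.3f} h "
                         f"(Qp={self.qp[i]:.1f}, threshold={self.significance_line[i]:.1f})")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period_h": self.periods_s / 3600.0, "qp": self.qp,
                             "df": self.df, "threshold": self.significance_line})


def chi_squared_periodogram(values: np.ndarray, bin_s: int,
                            period_range_s: tuple[float, float] = (20 * 3600, 28 * 3600),
                            alpha: float = 0.001) -> Periodogram:
    """Sokolove-Bushell periodogram of a binned activity vector.

    Candidate periods run over every integer bin count in ``period_range_s``
    (default 20-28 h, i.e. one-bin resolution; 10 min with the conventional
    binning).  Requires at least two complete cycles of the longest candidate.
    A constant input has no rhythm by definition and raises
    :class:`RhythmError` rather than returning NaN.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("input contains missing bins; fill or drop gaps first")
    pmin = max(2, int(math.ceil(period_range_s[0] / bin_s)))
    pmax = int(math.floor(period_range_s[1] / bin_s))
    if pmax < pmin:
        raise ValueError("empty candidate period range")
    if len(x) < 2 * pmax:
        raise RhythmError(f"need >= 2 complete cycles of the longest candidate "
                          f"period ({2 * pmax} bins), got {len(x)}")
    if np.ptp(x) == 0:
        raise RhythmError("constant input: no rhythm detectable")

    periods = np.arange(pmin, pmax + 1)
    qp = np.empty(len(periods))
    for j, p in enumerate(periods):
        k = len(x) // p
        n = k * p
        xs = x[:n]
        grand = xs.mean()
        col_means = xs.reshape(k, p).mean(axis=0)
        denom = ((xs - grand) ** 2).sum()
        qp[j] = k * n * ((col_means - grand) ** 2).sum() / denom
    df = periods - 1
    line = stats.chi2.ppf(1.0 - alpha, df)
    excess = qp - line
    peak = None
    if np.any(excess > 0):
        peak = float(periods[int(np.argmax(excess))] * bin_s)
    return Periodogram(periods_s=periods.astype(float) * bin_s, qp=qp,
                       df=df, significance_line=line, alpha=alpha,
                       bin_s=bin_s, peak_period_s=peak)


# --------------------------------------------------------------------------
# actograms

def actogram_matrix(values: np.ndarray, bin_s: int, period_s: float = 86400,
                    double_plot: bool = True) -> np.ndarray:
    """Fold a binned series into an actogram raster.

    Row d holds day d (``period_s`` worth of bins); with ``double_plot`` each
    row concatenates day d and day d+1 (the standard double-plotted layout),
    so the matrix is ``[days, 2*bins_per_day]`` with the final row's right
    half missing.  Incomplete trailing bins are NaN-padded.
    """
    x = np.asarray(values, dtype=float)
    cols = period_s / bin_s
    if cols != int(cols):
        raise ValueError(f"period_s={period_s} is not a whole number of {bin_s}s bins")
    cols = int(cols)
    days = -(-len(x) // cols)
    padded = np.full(days * cols, np.nan)
    padded[:len(x)] = x
    single = padded.reshape(days, cols)
    if not double_plot:
        return single
    nxt = np.vstack([single[1:], np.full((1, cols), np.nan)])
    return np.hstack([single, nxt])


# --------------------------------------------------------------------------
# light schedule

@dataclass
class LightSchedule:
    """Ordered LIGHT/DARK intervals tiling a recording, plus the regime."""

    intervals: list[tuple[pd.Timestamp, pd.Timestamp, str]]
    regime: str  # LD | DD | LL | irregular
    period_s: float | None = None
    threshold: float | None = None

    def phase_at(self, times: pd.DatetimeIndex | pd.Timestamp) -> np.ndarray:
        """LIGHT/DARK label for each instant (by the interval containing it)."""
        if isinstance(times, pd.Timestamp):
            times = pd.DatetimeIndex([times])
        starts = pd.DatetimeIndex([iv[0] for iv in self.intervals])
        idx = starts.searchsorted(times, side="right") - 1
        idx = np.clip(idx, 0, len(self.intervals) - 1)
        return np.array([self.intervals[i][2] for i in idx], dtype=object)

    @property
    def transitions(self) -> list[pd.Timestamp]:
        return [iv[0] for iv in self.intervals[1:]]


def _two_means(values: np.ndarray) -> tuple[float, float, float]:
    """1-D 2-means split; returns (low centre, high centre, midpoint threshold)."""
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(values.reshape(-1, 1))
    lo, hi = sorted(km.cluster_centers_.ravel())
    return float(lo), float(hi), float((lo + hi) / 2.0)


def infer_light_schedule(light: np.ndarray, epoch_s: int,
                         threshold: float | str = "auto",
                         start_time: pd.Timestamp | None = None,
                         debounce_s: float = 600.0,
                         period_cv_tol: float = 0.05) -> LightSchedule:
    """Infer LIGHT/DARK intervals from the raw light-sensor channel.

    With ``threshold="auto"`` the cut is the midpoint of the two modes found
    by 2-means on the light values; a channel without two separated modes
    raises :class:`ScheduleError` suggesting an explicit value.  Phase runs
    shorter than ``debounce_s`` (default 10 min) are treated as sensor noise
    and absorbed into the surrounding phase.  The regime is LD when both
    phases alternate with a stable period (cycle-length CV below
    ``period_cv_tol``), DD/LL when the trace is uniformly dark/light, else
    irregular.
    """
    x = np.asarray(light, dtype=float)
    x = np.where(np.isnan(x), 0.0, x)
    if start_time is None:
        start_time = pd.Timestamp(0, tz="UTC")
    if threshold == "auto":
        if np.ptp(x) == 0:
            if x[0] == 0:
                thr = 0.5  # uniformly zero: unambiguous darkness
            else:
                raise ScheduleError(
                    "constant nonzero light channel: cannot infer a threshold "
                    "automatically; pass an explicit value")
        else:
            lo, hi, thr = _two_means(x)
            pooled = np.sqrt(np.mean((x - np.where(x > thr, hi, lo)) ** 2))
            if hi - lo < 2.0 * max(pooled, 1e-12):
                raise ScheduleError(
                    "light histogram is not bimodal: cannot infer a threshold "
                    "automatically; pass an explicit value")
    else:
        thr = float(threshold)

    is_light = x > thr
    # debounce: drop phase runs shorter than debounce_s
    min_run = max(1, int(round(debounce_s / epoch_s)))
    runs = []
    i = 0
    for j in range(1, len(is_light) + 1):
        if j == len(is_light) or is_light[j] != is_light[i]:
            runs.append([i, j, bool(is_light[i])])
            i = j
    merged: list[list] = []
    for run in runs:
        if merged and (run[1] - run[0] < min_run) and len(merged) >= 1:
            merged[-1][1] = run[1]  # absorb into the preceding phase
        elif merged and merged[-1][2] == run[2]:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    # a leading glitch run shorter than min_run merges forward
    if len(merged) >= 2 and merged[0][1] - merged[0][0] < min_run:
        merged[1][0] = merged[0][0]
        merged = merged[1:]

    td = pd.Timedelta
    intervals = [(start_time + td(seconds=a * epoch_s),
                  start_time + td(seconds=b * epoch_s),
                  LIGHT if lit else DARK) for a, b, lit in merged]
    phases = {iv[2] for iv in intervals}
    period_s: float | None = None
    if phases == {DARK}:
        regime = "DD"
    elif phases == {LIGHT}:
        regime = "LL"
    else:
        on_times = [iv[0] for iv in intervals if iv[2] == LIGHT]
        if len(on_times) >= 2:
            cycles = np.diff([t.value / 1e9 for t in on_times])
            if cycles.std() <= period_cv_tol * cycles.mean():
                regime, period_s = "LD", float(cycles.mean())
            else:
                regime = "irregular"
        else:
            # a single light/dark alternation: call it LD, period unknown
            regime = "LD"
    return LightSchedule(intervals=intervals, regime=regime,
                         period_s=period_s, threshold=thr)


# --------------------------------------------------------------------------
# activity onset

def activity_onset(profile: np.ndarray, bin_s: int,
                   quiescent_window_s: float = 6 * 3600, k: float = 2.0,
                   sustain_s: float = 1800.0) -> float | None:
    """Detect the activity onset within one period of binned activity.

    Onset is the start of the first bin whose activity exceeds
    mean + k*sd of the preceding quiescent window (circularly, default 6 h)
    and stays above that threshold for at least ``sustain_s`` (default
    30 min).  Returns the onset as seconds from the start of the period, or
    None when no bin qualifies (e.g. a flat profile) — an absent onset is a
    result, not an error.
    """
    x = np.asarray(profile, dtype=float)
    n = len(x)
    w = max(1, int(round(quiescent_window_s / bin_s)))
    m = max(1, int(round(sustain_s / bin_s)))
    if n == 0:
        return None
    for i in range(n):
        window = x[(np.arange(i - w, i)) % n]
        if np.isnan(window).any():
            continue
        thr = window.mean() + k * window.std(ddof=0)
        seg = x[np.arange(i, i + m) % n]
        if np.all(seg > thr):
            return float(i * bin_s)
    return None


def activity_onsets(values: np.ndarray, bin_s: int, period_s: float = 86400,
                    **kwargs) -> list[float | None]:
    """Per-day onsets: fold at ``period_s`` and detect an onset in each row."""
    mat = actogram_matrix(values, bin_s, period_s, double_plot=False)
    out = []
    for row in mat:
        valid = row[~np.isnan(row)]
        if len(valid) < len(row):  # incomplete day
            out.append(None)
            continue
        out.append(activity_onset(row, bin_s, **kwargs))
    return out


# --------------------------------------------------------------------------
# nonparametric stability statistics

def interdaily_stability(values: np.ndarray, bin_s: int,
                         period_s: float = 86400) -> float:
    """Interdaily stability IS in [0, 1].

    IS = (n * sum_h (xbar_h - xbar)^2) / (p * sum_i (x_i - xbar)^2), where
    xbar_h are the p period-bin means over days and n the total number of
    bins.  IS = 1 for a perfectly repeating daily pattern; ~0 for noise.
    """
    x = np.asarray(values, dtype=float)
    p = period_s / bin_s
    if p != int(p):
        raise ValueError("period_s is not a whole number of bins")
    p = int(p)
    if len(x) < 2 * p:
        raise ValueError("need at least two complete days")
    n = len(x)
    xbar = x.mean()
    denom = ((x - xbar) ** 2).sum()
    if denom == 0:
        raise RhythmError("zero-variance input: IS undefined")
    hour_means = np.array([x[h::p].mean() for h in range(p)])
    return float(n * ((hour_means - xbar) ** 2).sum() / (p * denom))


def intradaily_variability(values: np.ndarray) -> float:
    """Intradaily variability IV >= 0 (rhythm fragmentation).

    IV = n * sum (x_i - x_{i-1})^2 / ((n-1) * sum (x_i - xbar)^2).  Smooth
    sinusoidal rhythms give IV near 0; white noise gives IV near 2.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two bins")
    denom = ((x - x.mean()) ** 2).sum()
    if denom == 0:
        raise RhythmError("zero-variance input: IV undefined")
    return float(n * (np.diff(x) ** 2).sum() / ((n - 1) * denom))
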