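"""Immobility-defined sleep scoring.

In mice, extended immobility (>= 40 s with no detected movement) is a
well-validated behavioural proxy for sleep.  With activity recorded as % PIR
activation per 10 s epoch, 40 s of immobility is four consecutive zero bins,
which the acquisition community usually computes as a rolling sum over the
last 4 bins (the spreadsheet one-liner ``=IF(SUM(A1:A4)=0,1,0)``).

Two scoring conventions exist and differ by ``threshold_bins - 1`` epochs per
qualifying immobile period:

``run`` (default)
    every epoch inside a maximal zero-activity run of length >=
    ``threshold_bins`` is scored asleep — the convention of the video-scoring
    validation literature, where the whole immobile period counts as sleep.

``window``
    epoch *i* is scored asleep iff the window of ``threshold_bins`` epochs
    ending at *i* is all zero — the literal rolling-sum formula, which misses
    the first ``threshold_bins - 1`` epochs of every bout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ActivityTrace, _check_bin

__all__ = ["SleepSeries", "SleepBout", "score_sleep", "score_trace",
           "sleep_bouts", "sleep_minutes_per_bin"]


@dataclass
class SleepSeries:
    """Per-epoch binary sleep flags aligned to the source activity vector."""

    epoch_s: int
    flags: np.ndarray  # uint8, 1 = asleep
    threshold_bins: int = 4
    mode: str = "run"
    start_time: pd.Timestamp | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.flags)

    @property
    def total_sleep_s(self) -> float:
        return float(self.flags.sum() * self.epoch_s)


@dataclass(frozen=True)
class SleepBout:
    """One maximal run of sleep-scored epochs."""

    onset_epoch: int
    n_epochs: int
    epoch_s: int
    onset_time: pd.Timestamp | None = None

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s


def _zero_runs(immobile: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of every maximal True-run."""
    padded = np.concatenate(([False], immobile, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def score_sleep(activity: np.ndarray, threshold_bins: int = 4,
                mode: str = "run", floor: float = 0.0, epoch_s: int = 10,
                missing_breaks: bool = True,
                start_time: pd.Timestamp | None = None) -> SleepSeries:
    """Score sleep from a per-epoch activity vector.

    Parameters
    ----------
    activity : % activation per epoch (>= 0; NaN marks a missing epoch).
    threshold_bins : minimum immobile run length, in epochs (4 x 10 s = 40 s).
    mode : ``"run"`` or ``"window"`` (see module docstring).
    floor : activity at or below this level still counts as immobile
        (default 0: any nonzero activation breaks immobility).
    missing_breaks : if True (default), missing epochs break immobility runs
        and are never scored asleep; if False they are treated as immobile.
    """
    activity = np.asarray(activity, dtype=float)
    if mode not in ("run", "window"):
        raise ValueError(f"mode must be 'run' or 'window', got {mode!r}")
    if threshold_bins < 1:
        raise ValueError("threshold_bins must be >= 1")
    with np.errstate(invalid="ignore"):
        if np.any(activity < 0):
            raise ValueError("negative activity values")
    nan = np.isnan(activity)
    immobile = (activity <= floor) & ~nan
    if not missing_breaks:
        immobile |= nan

    flags = np.zeros(len(activity), dtype=np.uint8)
    if len(activity) < threshold_bins:
        warnings.warn("trace shorter than the immobility threshold; no sleep scored",
                      stacklevel=2)
        return SleepSeries(epoch_s, flags, threshold_bins, mode, start_time)

    if mode == "run":
        for start, length in _zero_runs(immobile):
            if length >= threshold_bins:
                flags[start:start + length] = 1
    else:
        # rolling sum of mobile epochs over the trailing window == 0
        mobile = (~immobile).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(mobile)))
        wsum = csum[threshold_bins:] - csum[:-threshold_bins]
        flags[threshold_bins - 1:] = (wsum == 0).astype(np.uint8)
    return SleepSeries(epoch_s, flags, threshold_bins, mode, start_time)


def score_trace(trace: ActivityTrace, threshold_s: float = 40.0,
                mode: str = "run", floor: float = 0.0,
                missing_breaks: bool = True) -> dict[str, SleepSeries]:
    """Score every cage of a trace; threshold given in seconds."""
    if threshold_s % trace.epoch_s != 0:
        raise ValueError(f"threshold_s={threshold_s} is not a multiple of the "
                         f"{trace.epoch_s}s epoch")
    tb = int(threshold_s // trace.epoch_s)
    return {c: score_sleep(trace.cage(c), tb, mode, floor, trace.epoch_s,
                           missing_breaks, trace.start_time)
            for c in trace.cages}


def sleep_bouts(series: SleepSeries) -> list[SleepBout]:
    """Maximal runs of sleep-flagged epochs, in order."""
    bouts = []
    for start, length in _zero_runs(series.flags.astype(bool)):
        onset = (series.start_time + pd.Timedelta(seconds=start * series.epoch_s)
                 if series.start_time is not None else None)
        bouts.append(SleepBout(start, length, series.epoch_s, onset))
    return bouts


def sleep_minutes_per_bin(series: SleepSeries, bin_s: int = 1800) -> pd.Series:
    """Minutes asleep per half-open bin (default 30 min).

    Returns a Series indexed by bin start time when the series carries one,
    else by bin index.  A partial trailing bin is included (it can only score
    fewer minutes than a full bin).
    """
    k = _check_bin(bin_s, series.epoch_s)
    n = series.n_epochs
    n_bins = -(-n // k)
    padded = np.zeros(n_bins * k, dtype=np.int64)
    padded[:n] = series.flags
    minutes = padded.reshape(n_bins, k).sum(axis=1) * series.epoch_s / 60.0
    if series.start_time is not None:
        idx = pd.date_range(series.start_time, periods=n_bins,
                            freq=pd.Timedelta(seconds=bin_s))
        return pd.Series(minutes, index=idx, name="sleep_min")
    return pd.Series(minutes, name="sleep_min")
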