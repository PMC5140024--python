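"""Reading, writing and resampling of home-cage PIR activity recordings.

The acquisition system emits one CSV row per 10 s epoch: an ISO8601 UTC
timestamp, one "% of 100 ms polls active" column per cage (0-100), and a raw
light-dependent-resistor reading.  The canonical dialect written by
:func:`write_pir_csv` is::

    timestamp,cage_A,cage_B,light
    2016-01-01T00:00:00Z,0,37,512

Column names, delimiter and timestamp format are configurable through
:class:`DialectConfig` so that files from other loggers can be ingested.

Missing epochs (logger restarts, USB dropouts) are kept as explicit NaN rows
on a uniform time grid, never silently dropped: every downstream operation
must decide whether it skips or fails on gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

__all__ = [
    "ActivityTrace",
    "DialectConfig",
    "Hypnogram",
    "read_pir_csv",
    "write_pir_csv",
    "read_hypnogram_csv",
    "resample_activity",
]

#: Canonical vigilance-state labels, in conventional order.
VIGILANCE_STATES = ("WAKE", "NREM", "REM")


@dataclass(frozen=True)
class DialectConfig:
    """How to interpret a PIR CSV file.

    Parameters
    ----------
    delimiter : field separator.
    timestamp_col : name of the timestamp column.
    light_col : name of the light column, or None if the file has none.
    cage_prefix : columns starting with this prefix are cage activity columns
        (ignored when ``cage_cols`` is given).
    cage_cols : explicit list of activity column names, overriding the prefix.
    timestamp_format : strftime pattern; None means flexible ISO8601 parsing.
    clamp : clamp activity into [0, 100] instead of raising IntegrityError.
    gap_tolerance_s : slack allowed on the epoch spacing before a pair of
        consecutive rows is treated as a gap (or, if not a clean multiple of
        the epoch, an error).
    """

    delimiter: str = ","
    timestamp_col: str = "timestamp"
    light_col: str | None = "light"
    cage_prefix: str = "cage_"
    cage_cols: tuple[str, ...] | None = None
    timestamp_format: str | None = None
    clamp: bool = False
    gap_tolerance_s: float = 1.0


@dataclass
class ActivityTrace:
    """A uniformly sampled multi-cage PIR recording.

    ``activity`` is an ``(n_epochs, n_cages)`` float array of % sensor
    activation in [0, 100]; missing epochs are NaN rows.  ``light`` is the
    per-epoch raw light reading (NaN where missing).  Epochs are labelled by
    their *start* time and all intervals are half-open ``[start, start+epoch_s)``.
    """

    start_time: pd.Timestamp
    epoch_s: int
    cages: tuple[str, ...]
    activity: np.ndarray
    light: np.ndarray
    partial_last: bool = False

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim == 1:
            self.activity = self.activity[:, None]
        self.light = np.asarray(self.light, dtype=float)
        self.cages = tuple(self.cages)
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.tz_localize("UTC")
        if self.activity.shape[1] != len(self.cages):
            raise ValueError("activity has %d columns for %d cages"
                             % (self.activity.shape[1], len(self.cages)))
        if len(self.light) != len(self.activity):
            raise ValueError("light vector length %d != %d epochs"
                             % (len(self.light), len(self.activity)))
        with np.errstate(invalid="ignore"):
            bad = (self.activity < 0) | (self.activity > 100)
        if np.any(bad):
            raise IntegrityError("activity values outside [0, 100]")

    @property
    def n_epochs(self) -> int:
        return self.activity.shape[0]

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_epochs,
                             freq=pd.Timedelta(seconds=self.epoch_s))

    @property
    def duration_s(self) -> int:
        return self.n_epochs * self.epoch_s

    def cage(self, name_or_index: str | int) -> np.ndarray:
        """Activity vector for one cage."""
        if isinstance(name_or_index, str):
            name_or_index = self.cages.index(name_or_index)
        return self.activity[:, name_or_index]

    def has_gaps(self) -> bool:
        return bool(np.isnan(self.activity).any())

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per epoch, cage columns plus ``light``."""
        df = pd.DataFrame(self.activity, index=self.times, columns=list(self.cages))
        df["light"] = self.light
        df.index.name = "timestamp"
        return df


@dataclass
class Hypnogram:
    """Per-epoch vigilance states scored from EEG/EMG, the reference standard."""

    start_time: pd.Timestamp
    epoch_s: int
    states: np.ndarray  # array of canonical labels from VIGILANCE_STATES

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.tz_localize("UTC")
        unknown = set(np.unique(self.states)) - set(VIGILANCE_STATES)
        if unknown:
            raise IntegrityError(f"non-canonical vigilance states: {sorted(unknown)}")

    @property
    def n_epochs(self) -> int:
        return len(self.states)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_epochs,
                             freq=pd.Timedelta(seconds=self.epoch_s))

    @property
    def sleep_flags(self) -> np.ndarray:
        """1 where the animal is asleep (NREM or REM), else 0."""
        return np.isin(self.states, ("NREM", "REM")).astype(np.uint8)


def _open(source) -> IO[str]:
    if isinstance(source, (str,)):
        return open(source, "r", encoding="utf-8", newline="")
    return source


def read_pir_csv(source, dialect: DialectConfig = DialectConfig(),
                 epoch_s: int | None = None) -> ActivityTrace:
    """Parse a PIR activity CSV into an :class:`ActivityTrace`.

    Timestamps are parsed as UTC; rows whose timestamp cannot be parsed raise
    :class:`FormatError` naming their line numbers.  Non-monotone timestamps
    raise :class:`IntegrityError` listing the offending lines.  Consecutive
    timestamps further apart than one epoch (beyond ``gap_tolerance_s``) become
    explicit NaN gaps if the spacing is a clean multiple of the epoch,
    otherwise an error.  ``epoch_s`` defaults to the smallest observed spacing.
    """
    fh = _open(source)
    try:
        df = pd.read_csv(fh, sep=dialect.delimiter)
    except pd.errors.EmptyDataError:
        raise FormatError("empty PIR file") from None
    if df.empty:
        raise FormatError("PIR file has a header but no data rows")
    if dialect.timestamp_col not in df.columns:
        raise FormatError(f"no timestamp column {dialect.timestamp_col!r} in header "
                          f"{list(df.columns)}")

    ts = pd.to_datetime(df[dialect.timestamp_col], utc=True, errors="coerce",
                        format=dialect.timestamp_format)
    if ts.isna().any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in np.flatnonzero(ts.isna().to_numpy())]
        raise FormatError(f"unparseable timestamps at lines {lines[:10]}")

    if dialect.cage_cols is not None:
        cages = list(dialect.cage_cols)
        missing = [c for c in cages if c not in df.columns]
        if missing:
            raise FormatError(f"cage columns not found: {missing}")
    else:
        cages = [c for c in df.columns if c.startswith(dialect.cage_prefix)]
        if not cages:
            cages = [c for c in df.columns
                     if c not in (dialect.timestamp_col, dialect.light_col)]
    if not cages:
        raise FormatError("no activity columns found")

    tvals = ts.astype("int64").to_numpy() / 1e9
    diffs = np.diff(tvals)
    if np.any(diffs <= 0):
        lines = [int(i) + 3 for i in np.flatnonzero(diffs <= 0)]
        raise IntegrityError(f"timestamps not strictly increasing at lines {lines[:10]}")

    if epoch_s is None:
        epoch_s = int(round(diffs.min())) if len(diffs) else 10
    tol = dialect.gap_tolerance_s

    activity = df[cages].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (activity < 0) | (activity > 100)
    if bad.any():
        if dialect.clamp:
            activity = np.clip(activity, 0.0, 100.0)
        else:
            lines = sorted({int(i) + 2 for i in np.flatnonzero(bad.any(axis=1))})
            raise IntegrityError(f"activity outside [0,100] at lines {lines[:10]}")
    if dialect.light_col is not None and dialect.light_col in df.columns:
        light = df[dialect.light_col].to_numpy(dtype=float)
    else:
        light = np.full(len(df), np.nan)

    # Map rows onto a uniform epoch grid; anything off-grid is an error.
    offsets = tvals - tvals[0]
    slots = offsets / epoch_s
    slot_idx = np.round(slots).astype(np.int64)
    if np.any(np.abs(offsets - slot_idx * epoch_s) > tol):
        lines = [int(i) + 2
                 for i in np.flatnonzero(np.abs(offsets - slot_idx * epoch_s) > tol)]
        raise IntegrityError(
            f"timestamp spacing is not a multiple of {epoch_s}s at lines {lines[:10]}")

    n = int(slot_idx[-1]) + 1
    full_act = np.full((n, len(cages)), np.nan)
    full_light = np.full(n, np.nan)
    full_act[slot_idx] = activity
    full_light[slot_idx] = light

    return ActivityTrace(start_time=ts.iloc[0], epoch_s=epoch_s,
                         cages=tuple(cages), activity=full_act, light=full_light)


def write_pir_csv(trace: ActivityTrace, sink) -> None:
    """Write a trace in the canonical dialect; gap (NaN) rows are omitted so
    that ``read_pir_csv(write_pir_csv(t)) == t`` including the gap structure."""
    if not trace.cages:
        raise ValueError("refusing to write a trace with no cages")
    df = trace.to_frame()
    keep = ~df[list(trace.cages)].isna().all(axis=1)
    df = df.loc[keep].reset_index()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")

    def _fmt(x: float) -> str:
        if isinstance(x, float) and math.isnan(x):
            return ""
        return repr(int(x)) if float(x).is_integer() else repr(float(x))

    close = False
    if isinstance(sink, str):
        sink = open(sink, "w", encoding="utf-8", newline="")
        close = True
    try:
        sink.write(",".join(["timestamp", *trace.cages, "light"]) + "\n")
        for row in df.itertuples(index=False):
            vals = [row.timestamp] + [_fmt(getattr(row, c)) for c in trace.cages]
            vals.append(_fmt(row.light))
            sink.write(",".join(vals) + "\n")
    finally:
        if close:
            sink.close()


def read_hypnogram_csv(source, label_map: Mapping[str, str],
                       epoch_s: int = 10,
                       start_time: pd.Timestamp | str | None = None,
                       state_col: str | int = 0,
                       timestamp_col: str | None = None,
                       delimiter: str = ",") -> Hypnogram:
    """Parse an EEG/EMG hypnogram CSV (one vigilance-state token per epoch row).

    ``label_map`` maps raw file tokens (e.g. ``"W"``, ``"NR"``, ``"R"``) onto
    the canonical labels WAKE/NREM/REM.  A token absent from the map raises
    :class:`FormatError` naming the token and line — unknown states are never
    silently scored as wake.
    """
    for target in label_map.values():
        if target not in VIGILANCE_STATES:
            raise ValueError(f"label_map target {target!r} is not one of {VIGILANCE_STATES}")
    fh = _open(source)
    try:
        df = pd.read_csv(fh, sep=delimiter)
    except pd.errors.EmptyDataError:
        raise FormatError("empty hypnogram file") from None
    if df.empty:
        raise FormatError("hypnogram file has a header but no data rows")
    col = df.columns[state_col] if isinstance(state_col, int) else state_col
    tokens = df[col].astype(str).str.strip()
    mapped = tokens.map(label_map)
    if mapped.isna().any():
        i = int(np.flatnonzero(mapped.isna().to_numpy())[0])
        raise FormatError(f"unknown vigilance token {tokens.iloc[i]!r} at line {i + 2}")
    if timestamp_col is not None:
        start = pd.to_datetime(df[timestamp_col].iloc[0], utc=True)
    elif start_time is not None:
        start = pd.Timestamp(start_time)
        if start.tzinfo is None:
            start = start.tz_localize("UTC")
    else:
        start = pd.Timestamp(0, tz="UTC")
    return Hypnogram(start_time=start, epoch_s=epoch_s,
                     states=mapped.to_numpy(dtype=object))


def _check_bin(bin_s: int, epoch_s: int) -> int:
    if bin_s % epoch_s != 0:
        raise ValueError(f"bin_s={bin_s} is not a multiple of epoch_s={epoch_s}")
    return bin_s // epoch_s


def resample_activity(trace: ActivityTrace, bin_s: int,
                      statistic: str = "mean") -> ActivityTrace:
    """Aggregate a trace into coarser bins (the analysis resolution).

    Each output bin covers exactly ``bin_s/epoch_s`` source epochs, is labelled
    by its start time, and is half-open.  A partial trailing bin is aggregated
    over the epochs present and flagged via ``partial_last``.  Bins containing
    a gap epoch propagate NaN (strict policy; callers that want to skip gaps
    must fill them first).  The light channel is aggregated with the mean.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError(f"statistic must be 'mean' or 'sum', got {statistic!r}")
    k = _check_bin(bin_s, trace.epoch_s)
    n = trace.n_epochs
    n_bins = math.ceil(n / k)
    pad = n_bins * k - n
    act = np.pad(trace.activity, ((0, pad), (0, 0)), constant_values=np.nan)
    lig = np.pad(trace.light, (0, pad), constant_values=np.nan)
    act = act.reshape(n_bins, k, -1)
    lig = lig.reshape(n_bins, k)
    agg = act.mean(axis=1) if statistic == "mean" else act.sum(axis=1)
    light_out = lig.mean(axis=1)
    if pad:
        # trailing partial bin: aggregate over the epochs actually present
        tail = act[-1, : k - pad]
        agg[-1] = tail.mean(axis=0) if statistic == "mean" else tail.sum(axis=0)
        light_out[-1] = lig[-1, : k - pad].mean()
    if statistic == "mean":
        return ActivityTrace(start_time=trace.start_time, epoch_s=bin_s,
                             cages=trace.cages, activity=agg,
                             light=light_out, partial_last=bool(pad))
    return BinnedSums(start_time=trace.start_time, epoch_s=bin_s,
                      cages=trace.cages, values=agg, light=light_out,
                      partial_last=bool(pad))


@dataclass
class BinnedSums:
    """Sum-aggregated bins (may exceed 100, so not an ActivityTrace)."""

    start_time: pd.Timestamp
    epoch_s: int
    cages: tuple[str, ...]
    values: np.ndarray
    light: np.ndarray
    partial_last: bool = False

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_epochs,
                             freq=pd.Timedelta(seconds=self.epoch_s))
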