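"""Validation of PIR-scored sleep against EEG-scored sleep.

Both methods are summarised as minutes of sleep per 30 min bin, paired on
their overlapping time range, and compared with Pearson correlation and a
Bland-Altman analysis: per-bin differences d = PIR - EEG, bias = mean(d),
and limits of agreement bias +/- 1.96 * sd(d) (sample sd, n-1).  When a
light schedule is available the analysis is repeated separately for the
light and dark phases, since reduced movement during the rest (light) phase
inflates immobility-defined sleep relative to EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .circadian import DARK, LIGHT, LightSchedule
from .io import Hypnogram, _check_bin

__all__ = ["hypnogram_sleep_minutes", "align_pairs", "pearson_r",
           "bland_altman", "BlandAltman", "AgreementReport", "agreement_report"]


def hypnogram_sleep_minutes(h: Hypnogram, bin_s: int = 1800) -> pd.Series:
    """Minutes asleep (NREM + REM epochs) per half-open bin."""
    k = _check_bin(bin_s, h.epoch_s)
    flags = h.sleep_flags.astype(np.int64)
    n_bins = -(-len(flags) // k)
    padded = np.zeros(n_bins * k, dtype=np.int64)
    padded[:len(flags)] = flags
    minutes = padded.reshape(n_bins, k).sum(axis=1) * h.epoch_s / 60.0
    idx = pd.date_range(h.start_time, periods=n_bins,
                        freq=pd.Timedelta(seconds=bin_s))
    return pd.Series(minutes, index=idx, name="eeg_sleep_min")


def align_pairs(pir: pd.Series, eeg: pd.Series) -> tuple[pd.DataFrame, int]:
    """Pair two binned series on their common bins.

    Both must use the same bin width; pairs are restricted to the
    intersection of the two time indexes.  Returns the paired frame (columns
    ``pir``, ``eeg``) and the number of bins dropped from either side.
    Disjoint ranges are an error.
    """
    if len(pir.index) > 1 and len(eeg.index) > 1:
        step_p = pir.index[1] - pir.index[0]
        step_e = eeg.index[1] - eeg.index[0]
        if step_p != step_e:
            raise ValueError(f"bin widths differ: {step_p} vs {step_e}")
    common = pir.index.intersection(eeg.index)
    if len(common) == 0:
        raise ValueError("no overlapping bins between the two series")
    dropped = (len(pir) - len(common)) + (len(eeg) - len(common))
    out = pd.DataFrame({"pir": pir.loc[common], "eeg": eeg.loc[common]})
    return out, int(dropped)


def pearson_r(x, y) -> float:
    """Product-moment correlation; constant input is an error, not NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(_sstats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class BlandAltman:
    """Bias and 95% limits of agreement for one set of paired differences."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n_bins: int

    def swapped(self) -> "BlandAltman":
        """The same comparison with the method order reversed."""
        return BlandAltman(-self.bias, -self.loa_high, -self.loa_low,
                           self.sd, self.n_bins)


def bland_altman(pir, eeg) -> BlandAltman:
    """Bland-Altman statistics for PIR - EEG paired differences."""
    d = np.asarray(pir, dtype=float) - np.asarray(eeg, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, sd=sd, n_bins=len(d))


@dataclass
class AgreementReport:
    """Agreement between PIR- and EEG-scored sleep for one or more animals.

    The paper-style headline numbers: per-animal Pearson r on minutes of
    sleep per bin, and pooled Bland-Altman bias/limits overall and split by
    light phase.  Limits are reported as limits of agreement
    (bias +/- 1.96 sd of the differences).
    """

    bin_s: int
    pearson: dict[str, float]
    overall: BlandAltman
    by_phase: dict[str, BlandAltman] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"PIR vs EEG sleep agreement ({self.bin_s // 60} min bins)"]
        for animal, r in self.pearson.items():
            lines.append(f"  Pearson r [{animal}]: {r:.3f}")
        ba = self.overall

        def _fmt(tag: str, b: BlandAltman) -> str:
            return (f"  Bland-Altman {tag}: bias {b.bias:+.1f} min, "
                    f"LoA {b.loa_low:+.1f} to {b.loa_high:+.1f} min (n={b.n_bins})")
        lines.append(_fmt("overall", ba))
        for phase, b in self.by_phase.items():
            lines.append(_fmt(phase.lower(), b))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def _d(b: BlandAltman) -> dict:
            return {"bias_min": b.bias, "loa_low_min": b.loa_low,
                    "loa_high_min": b.loa_high, "n_bins": b.n_bins}
        return {"bin_s": self.bin_s,
                "pearson_r": dict(self.pearson),
                "bland_altman": {"overall": _d(self.overall),
                                 **{k.lower(): _d(v) for k, v in self.by_phase.items()}}}


def agreement_report(pir_minutes: dict[str, pd.Series],
                     eeg_minutes: dict[str, pd.Series],
                     bin_s: int = 1800,
                     schedule: LightSchedule | None = None) -> AgreementReport:
    """Build the full agreement report over a set of animals.

    Bland-Altman statistics pool the per-bin differences across animals (the
    per-animal statistics are recoverable by passing a single animal).  With
    a schedule, bins are assigned to LIGHT or DARK by their start time.
    """
    if set(pir_minutes) != set(eeg_minutes):
        raise ValueError("animal sets differ between PIR and EEG inputs")
    pearson: dict[str, float] = {}
    diffs: list[np.ndarray] = []
    pooled_pir: list[np.ndarray] = []
    pooled_eeg: list[np.ndarray] = []
    phases: list[np.ndarray] = []
    for animal in pir_minutes:
        pairs, _ = align_pairs(pir_minutes[animal], eeg_minutes[animal])
        pearson[animal] = pearson_r(pairs["pir"], pairs["eeg"])
        pooled_pir.append(pairs["pir"].to_numpy())
        pooled_eeg.append(pairs["eeg"].to_numpy())
        if schedule is not None:
            phases.append(schedule.phase_at(pairs.index))
    pir_all = np.concatenate(pooled_pir)
    eeg_all = np.concatenate(pooled_eeg)
    overall = bland_altman(pir_all, eeg_all)
    by_phase: dict[str, BlandAltman] = {}
    if schedule is not None:
        phase_all = np.concatenate(phases)
        for phase in (LIGHT, DARK):
            sel = phase_all == phase
            if sel.sum() >= 2:
                by_phase[phase] = bland_altman(pir_all[sel], eeg_all[sel])
    return AgreementReport(bin_s=bin_s, pearson=pearson,
                           overall=overall, by_phase=by_phase)
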