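"""Synthetic home-cage cohorts with known ground truth.

A mouse is modelled as a semi-Markov process over three behavioural states —
ACTIVE, QUIET_WAKE, SLEEP — with exponentially distributed dwell times whose
means and entry weights depend on circadian phase.  Phase is driven by the
light cycle under LD and free-runs at an intrinsic period tau under constant
conditions (tau < 24 h in DD, > 24 h in LL, the classic C57BL/6J pattern).
Nocturnality arises from a dark-phase multiplier on the ACTIVE dwell time and
phase-dependent state entry weights.

Each state emits per-epoch % PIR activation:

* ACTIVE: clamped Normal(mu_a, sigma_a) in [0, 100];
* QUIET_WAKE: movement with probability ``quiet_move_prob`` per epoch
  (clamped Normal(mu_q, sigma_q)), else 0 — the quiet-wakefulness confound
  that makes immobility-based scoring overestimate sleep;
* SLEEP: 0, except a movement artifact with probability ``artifact_prob``.

The simulator returns the PIR trace, the true state sequence, a matched
hypnogram (SLEEP -> NREM, otherwise WAKE) and the light schedule, so that
scoring, rhythm and agreement analyses can be validated against ground
truth.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .circadian import DARK, LIGHT, LightSchedule
from .io import ActivityTrace, Hypnogram

__all__ = ["SimConfig", "SimOutput", "simulate_mouse", "simulate_cohort"]

ACTIVE, QUIET_WAKE, SLEEP = 0, 1, 2
STATE_NAMES = ("ACTIVE", "QUIET_WAKE", "SLEEP")


class SimConfig(BaseModel):
    """Parameters of one simulated animal.  All times in seconds."""

    duration_days: float = Field(14.0, gt=0)
    epoch_s: int = Field(10, gt=0)
    start_time: str = "2016-01-01T00:00:00Z"

    # light environment
    regime: Literal["LD", "DD", "LL"] = "LD"
    light_period_s: float = Field(86400.0, gt=0)
    light_fraction: float = Field(0.5, ge=0, le=1)   # 12 h : 12 h
    light_on_value: float = Field(600.0, ge=0)       # raw LDR units
    light_off_value: float = Field(0.0, ge=0)

    # intrinsic clock (free-running period under constant conditions)
    tau_dd_s: float = Field(23.7 * 3600, gt=0)
    tau_ll_s: float = Field(24.6 * 3600, gt=0)
    phase_shift_s: float = 0.0   # shifts subjective night, e.g. phenotypes

    # state dwell means (exponential), seconds
    active_dwell_s: float = Field(180.0, gt=0)
    active_dark_multiplier: float = Field(3.0, gt=0)
    quiet_dwell_s: float = Field(60.0, gt=0)
    sleep_dwell_s: float = Field(240.0, gt=0)
    sleep_min_s: float = Field(0.0, ge=0)   # floor on sleep bout length

    # state entry weights (relative), per phase; a zero weight makes the
    # state unreachable in that phase
    active_weight_light: float = Field(0.25, ge=0)
    active_weight_dark: float = Field(0.75, ge=0)
    quiet_weight_light: float = Field(0.10, ge=0)
    quiet_weight_dark: float = Field(0.10, ge=0)
    sleep_weight_light: float = Field(0.65, ge=0)
    sleep_weight_dark: float = Field(0.15, ge=0)

    # emission model
    active_mu: float = Field(60.0, ge=0, le=100)
    active_sigma: float = Field(20.0, ge=0)
    quiet_move_prob: float = Field(0.2, ge=0, le=1)   # q: movement during quiet wake
    quiet_mu: float = Field(5.0, ge=0, le=100)
    quiet_sigma: float = Field(2.0, ge=0)
    artifact_prob: float = Field(0.0, ge=0, le=1)     # epsilon: movement during sleep

    # optional ultradian modulation of the ACTIVE dwell time
    ultradian_period_s: float | None = Field(None, gt=0)
    ultradian_depth: float = Field(0.5, ge=0, le=1)

    seed: int = 0

    @model_validator(mode="after")
    def _check_weights(self) -> "SimConfig":
        for phase in ("light", "dark"):
            total = sum(getattr(self, f"{s}_weight_{phase}")
                        for s in ("active", "quiet", "sleep"))
            if total <= 0:
                raise ValueError(f"all {phase}-phase state weights are zero")
        return self

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_days * 86400 / self.epoch_s))


@dataclass
class SimOutput:
    """Ground truth plus the PIR recording it induces."""

    trace: ActivityTrace
    truth_states: np.ndarray   # int codes, see STATE_NAMES
    hypnogram: Hypnogram
    schedule: LightSchedule
    config: SimConfig

    @property
    def state_names(self) -> np.ndarray:
        return np.array(STATE_NAMES, dtype=object)[self.truth_states]


def _is_subjective_dark(cfg: SimConfig, t_s: np.ndarray) -> np.ndarray:
    """Dark / subjective-night indicator at each time (drives behaviour)."""
    if cfg.regime == "LD":
        # behavioural phase may lead/lag the light cycle (chronotype)
        phase = ((t_s + cfg.phase_shift_s) % cfg.light_period_s) / cfg.light_period_s
        return phase >= cfg.light_fraction
    tau = cfg.tau_dd_s if cfg.regime == "DD" else cfg.tau_ll_s
    phase = ((t_s + cfg.phase_shift_s) % tau) / tau
    return phase >= 0.5


def _light_vector(cfg: SimConfig, n: int) -> np.ndarray:
    t = np.arange(n) * cfg.epoch_s
    if cfg.regime == "DD":
        return np.full(n, cfg.light_off_value)
    if cfg.regime == "LL":
        return np.full(n, cfg.light_on_value)
    phase = (t % cfg.light_period_s) / cfg.light_period_s
    return np.where(phase < cfg.light_fraction, cfg.light_on_value,
                    cfg.light_off_value)


def _schedule(cfg: SimConfig, start: pd.Timestamp) -> LightSchedule:
    td = pd.Timedelta
    end = start + td(seconds=cfg.n_epochs * cfg.epoch_s)
    if cfg.regime in ("DD", "LL"):
        phase = DARK if cfg.regime == "DD" else LIGHT
        return LightSchedule(intervals=[(start, end, phase)], regime=cfg.regime,
                             period_s=None)
    intervals = []
    half_on = cfg.light_period_s * cfg.light_fraction
    t = start
    while t < end:
        on_end = min(t + td(seconds=half_on), end)
        intervals.append((t, on_end, LIGHT))
        if on_end >= end:
            break
        cyc_end = min(t + td(seconds=cfg.light_period_s), end)
        intervals.append((on_end, cyc_end, DARK))
        t = t + td(seconds=cfg.light_period_s)
    return LightSchedule(intervals=intervals, regime="LD",
                         period_s=cfg.light_period_s)


def _sample_states(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Semi-Markov state sequence, one code per epoch."""
    n = cfg.n_epochs
    states = np.empty(n, dtype=np.int8)
    dwell_means = np.array([cfg.active_dwell_s, cfg.quiet_dwell_s,
                            cfg.sleep_dwell_s])
    weights = {
        False: np.array([cfg.active_weight_light, cfg.quiet_weight_light,
                         cfg.sleep_weight_light]),
        True: np.array([cfg.active_weight_dark, cfg.quiet_weight_dark,
                        cfg.sleep_weight_dark]),
    }

    def pick(current: int | None, dark: bool) -> int:
        w = weights[dark].copy()
        if current is not None:
            w[current] = 0.0   # a bout always ends in a different state
        if w.sum() <= 0:
            w = weights[dark].copy()   # only the current state is allowed
        return int(rng.choice(3, p=w / w.sum()))

    i = 0
    state: int | None = None
    while i < n:
        t = i * cfg.epoch_s
        dark = bool(_is_subjective_dark(cfg, np.array([t]))[0])
        state = pick(state, dark)
        mean = dwell_means[state]
        if state == ACTIVE:
            if dark:
                mean *= cfg.active_dark_multiplier
            if cfg.ultradian_period_s:
                mean *= 1.0 + cfg.ultradian_depth * np.sin(
                    2 * np.pi * t / cfg.ultradian_period_s)
                mean = max(mean, cfg.epoch_s)
        dwell = rng.exponential(mean)
        if state == SLEEP and dwell < cfg.sleep_min_s:
            dwell = cfg.sleep_min_s
        n_ep = max(1, int(round(dwell / cfg.epoch_s)))
        states[i:i + n_ep] = state
        i += n_ep
    return states


def _emit(cfg: SimConfig, states: np.ndarray,
          rng: np.random.Generator) -> np.ndarray:
    n = len(states)
    act = np.zeros(n)
    idx_a = np.flatnonzero(states == ACTIVE)
    if len(idx_a):
        act[idx_a] = np.clip(rng.normal(cfg.active_mu, cfg.active_sigma,
                                        len(idx_a)), 0.0, 100.0)
    idx_q = np.flatnonzero(states == QUIET_WAKE)
    if len(idx_q):
        move = rng.random(len(idx_q)) < cfg.quiet_move_prob
        vals = np.clip(rng.normal(cfg.quiet_mu, cfg.quiet_sigma, len(idx_q)),
                       0.0, 100.0)
        act[idx_q] = np.where(move, vals, 0.0)
    idx_s = np.flatnonzero(states == SLEEP)
    if len(idx_s) and cfg.artifact_prob > 0:
        artifact = rng.random(len(idx_s)) < cfg.artifact_prob
        vals = np.clip(rng.normal(cfg.quiet_mu, cfg.quiet_sigma, len(idx_s)),
                       0.0, 100.0)
        act[idx_s] = np.where(artifact, vals, 0.0)
    return act


def simulate_mouse(config: SimConfig,
                   rng: np.random.Generator | int | None = None,
                   cage: str = "cage_sim") -> SimOutput:
    """Simulate one animal under ``config``.

    ``rng`` may be a seed or Generator; by default ``config.seed`` is used.
    The same config and seed always produce bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    start = pd.Timestamp(config.start_time)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")

    states = _sample_states(config, rng)
    activity = _emit(config, states, rng)
    light = _light_vector(config, config.n_epochs)
    trace = ActivityTrace(start_time=start, epoch_s=config.epoch_s,
                          cages=(cage,), activity=activity[:, None],
                          light=light)
    hyp_states = np.where(states == SLEEP, "NREM", "WAKE").astype(object)
    hyp = Hypnogram(start_time=start, epoch_s=config.epoch_s, states=hyp_states)
    return SimOutput(trace=trace, truth_states=states.astype(np.int8),
                     hypnogram=hyp, schedule=_schedule(config, start),
                     config=config)


def simulate_cohort(config: SimConfig, n_animals: int, seed: int = 0,
                    jitter: dict[str, float] | None = None,
                    per_animal: list[dict] | None = None) -> list[SimOutput]:
    """Simulate a cohort sharing a template config.

    Per-animal randomness comes from child seeds spawned deterministically
    from ``seed``.  ``jitter`` maps config field names to Gaussian standard
    deviations applied around the template value (positive fields are kept
    positive); ``per_animal`` supplies explicit per-animal field overrides
    (e.g. phase-shifted phenotypes) and must have length ``n_animals``.
    """
    if per_animal is not None and len(per_animal) != n_animals:
        raise ValueError("per_animal must have one entry per animal")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_animals)
    out = []
    for i in range(n_animals):
        rng = np.random.default_rng(children[i])
        fields = config.model_dump()
        if jitter:
            for name, sd in jitter.items():
                if name not in fields:
                    raise ValueError(f"unknown config field {name!r}")
                val = fields[name] + rng.normal(0.0, sd)
                if isinstance(fields[name], (int, float)) and fields[name] > 0:
                    val = max(val, 1e-9)
                fields[name] = val
        if per_animal is not None:
            fields.update(per_animal[i])
        cfg = SimConfig(**fields)
        out.append(simulate_mouse(cfg, rng, cage=f"cage_{i:02d}"))
    return out
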