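import numpy as np
import pandas as pd
import pytest

from compass import ActivityTrace, SimConfig


@pytest.fixture
def start():
    return pd.Timestamp("2016-01-01T00:00:00Z")


@pytest.fixture
def small_trace(start):
    """100 epochs, two cages, with a light square wave."""
    rng = np.random.default_rng(11)
    act = rng.integers(0, 101, size=(100, 2)).astype(float)
    light = np.where(np.arange(100) < 50, 600.0, 0.0)
    return ActivityTrace(start_time=start, epoch_s=10,
                         cages=("cage_A", "cage_B"), activity=act, light=light)


def perfect_sensor_config(seed: int, days: float = 2.0) -> SimConfig:
    """A sensor-faithful scenario: no quiet wakefulness, no sleep-movement
    artifacts, every sleep bout at least 40 s, and active emissions that
    effectively never clamp to 0% (mu=60, sigma=10)."""
    return SimConfig(duration_days=days, seed=seed,
                     quiet_weight_light=0.0, quiet_weight_dark=0.0,
                     quiet_move_prob=0.0, artifact_prob=0.0,
                     sleep_min_s=40.0, active_sigma=10.0)


def clear_onset_config(seed: int, **overrides) -> SimConfig:
    """Strongly nocturnal animal with zero rest-phase movement, giving the
    sharp activity onsets used by onset/actogram-alignment checks."""
    fields = dict(duration_days=8, regime="DD", tau_dd_s=23.7 * 3600,
                  active_weight_light=0.0, quiet_weight_light=0.2,
                  sleep_weight_light=0.8, active_weight_dark=0.85,
                  quiet_weight_dark=0.05, sleep_weight_dark=0.10,
                  quiet_move_prob=0.0, artifact_prob=0.0,
                  active_dark_multiplier=4.0, seed=seed)
    fields.update(overrides)
    return SimConfig(**fields)
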