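import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compass import score_sleep, score_trace, sleep_bouts, sleep_minutes_per_bin


def oracle_run_flags(activity, threshold_bins):
    """Brute-force enumeration of maximal zero runs (independent of the
    vectorised implementation)."""
    flags = [0] * len(activity)
    i = 0
    for is_zero, grp in itertools.groupby(activity, key=lambda v: v == 0):
        n = len(list(grp))
        if is_zero and n >= threshold_bins:
            for j in range(i, i + n):
                flags[j] = 1
        i += n
    return flags


def oracle_window_flags(activity, threshold_bins):
    """Literal trailing-window rule: epoch i sleeps iff the last
    threshold_bins epochs (ending at i) are all zero."""
    return [1 if i + 1 >= threshold_bins
            and all(v == 0 for v in activity[i + 1 - threshold_bins: i + 1])
            else 0
            for i in range(len(activity))]


class TestScoreSleep:
    def test_sixty_seconds_immobile_run_vs_window(self):
        zeros = np.zeros(6)
        assert score_sleep(zeros, mode="run").flags.sum() == 6
        # the rolling-sum formula only fires once 4 bins have accumulated
        np.testing.assert_array_equal(score_sleep(zeros, mode="window").flags,
                                      [0, 0, 0, 1, 1, 1])

    def test_thirty_seconds_is_below_the_40s_threshold(self):
        zeros = np.zeros(3)
        with pytest.warns(UserWarning):
            assert score_sleep(zeros, mode="run").flags.sum() == 0
        with pytest.warns(UserWarning):
            assert score_sleep(zeros, mode="window").flags.sum() == 0

    def test_interrupted_immobility_flags_both_runs(self):
        act = np.array([0, 0, 0, 0, 5, 0, 0, 0, 0], dtype=float)
        np.testing.assert_array_equal(score_sleep(act).flags,
                                      [1, 1, 1, 1, 0, 1, 1, 1, 1])

    def test_any_nonzero_activity_breaks_immobility(self):
        act = np.array([0, 0, 1.0, 0, 0, 0, 0, 0])
        np.testing.assert_array_equal(score_sleep(act).flags,
                                      [0, 0, 0, 1, 1, 1, 1, 1])

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            score_sleep(np.array([0.0, -1.0, 0.0, 0.0]))

    def test_missing_epochs_break_runs_by_default(self):
        act = np.array([0, 0, np.nan, 0, 0, 0, 0, 0])
        assert score_sleep(act).flags.sum() == 5
        assert score_sleep(act, missing_breaks=False).flags.sum() == 8

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0, 0, 0, 7]), min_size=0, max_size=60),
           st.integers(min_value=1, max_value=6))
    def test_matches_brute_force_oracle(self, activity, threshold):
        import warnings
        act = np.asarray(activity, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short traces warn
            run = score_sleep(act, threshold, "run").flags
            win = score_sleep(act, threshold, "window").flags
        assert list(run) == oracle_run_flags(activity, threshold)
        assert list(win) == oracle_window_flags(activity, threshold)
        # run - window totals differ by (threshold-1) epochs per qualifying run
        n_runs = sum(1 for z, g in itertools.groupby(activity, lambda v: v == 0)
                     if z and len(list(g)) >= threshold)
        assert run.sum() - win.sum() == (threshold - 1) * n_runs

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([0, 0, 0, 7]), min_size=8, max_size=80))
    def test_monotone_in_threshold_and_bounded_by_immobility(self, activity):
        act = np.asarray(activity, dtype=float)
        totals = [score_sleep(act, tb).flags.sum() for tb in (1, 2, 4, 6)]
        assert totals == sorted(totals, reverse=True)
        # sleep is a subset of immobility
        assert score_sleep(act, 4).flags.sum() <= (act == 0).sum()


class TestBouts:
    def test_two_40s_bouts(self):
        s = score_sleep(np.array([0, 0, 0, 0, 5, 0, 0, 0, 0], dtype=float))
        bouts = sleep_bouts(s)
        assert [(b.onset_epoch, b.duration_s) for b in bouts] == [(0, 40), (5, 40)]

    def test_no_sleep_means_no_bouts(self):
        s = score_sleep(np.full(10, 50.0))
        assert sleep_bouts(s) == []

    def test_hour_long_bout(self):
        s = score_sleep(np.zeros(360))
        bouts = sleep_bouts(s)
        assert len(bouts) == 1 and bouts[0].duration_s == 3600


class TestMinutesPerBin:
    def test_fully_asleep_bin_scores_30_minutes(self):
        s = score_sleep(np.zeros(180))
        assert sleep_minutes_per_bin(s).iloc[0] == 30.0

    def test_twelve_flagged_epochs_are_two_minutes(self):
        act = np.full(180, 50.0)
        act[:12] = 0.0
        s = score_sleep(act)
        assert sleep_minutes_per_bin(s).iloc[0] == 2.0

    def test_empty_bin_is_zero(self):
        s = score_sleep(np.full(360, 50.0))
        assert (sleep_minutes_per_bin(s) == 0).all()


def test_score_trace_scores_every_cage(small_trace):
    out = score_trace(small_trace, threshold_s=40)
    assert set(out) == {"cage_A", "cage_B"}
    with pytest.raises(ValueError):
        score_trace(small_trace, threshold_s=45)
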