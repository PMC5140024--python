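import numpy as np
import pytest

from compass import (RhythmError, ScheduleError, activity_onset,
                     activity_onsets, actogram_matrix,
                     chi_squared_periodogram, infer_light_schedule,
                     interdaily_stability, intradaily_variability,
                     resample_activity, simulate_mouse)
from conftest import clear_onset_config

BIN = 600  # the conventional 10 min analysis bin


def oracle_qp(x, period_bins):
    """Independent fold-and-variance evaluation of the periodogram statistic."""
    k = len(x) // period_bins
    xs = x[: k * period_bins]
    grand = sum(xs) / len(xs)
    col_means = [sum(xs[c::period_bins]) / k for c in range(period_bins)]
    num = k * len(xs) * sum((m - grand) ** 2 for m in col_means)
    den = sum((v - grand) ** 2 for v in xs)
    return num / den


class TestPeriodogram:
    def test_pure_24h_square_wave_peaks_at_24h(self):
        t = np.arange(10 * 144) * BIN
        x = ((t % 86400) >= 43200).astype(float) * 80
        pg = chi_squared_periodogram(x, BIN)
        assert pg.peak_period_h == pytest.approx(24.0)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.random(3 * 144) * 60
        pg = chi_squared_periodogram(x, BIN, (20 * 3600, 24 * 3600))
        for p_s, qp in zip(pg.periods_s, pg.qp):
            assert qp == pytest.approx(oracle_qp(list(x), int(p_s // BIN)),
                                       rel=1e-9)

    def test_white_noise_rarely_crosses_the_significance_line(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pg = chi_squared_periodogram(rng.random(10 * 144) * 50, BIN)
            hits += pg.peak_period_s is not None
        assert hits / 200 <= 0.05

    def test_qp_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(6)
        x = rng.random(5 * 144) * 40
        a = chi_squared_periodogram(x, BIN)
        b = chi_squared_periodogram(3.5 * x + 7.0, BIN)
        np.testing.assert_allclose(a.qp, b.qp, rtol=1e-9)

    def test_constant_input_is_an_explicit_error(self):
        with pytest.raises(RhythmError, match="no rhythm"):
            chi_squared_periodogram(np.full(2000, 5.0), BIN)

    def test_fewer_than_two_cycles_rejected(self):
        with pytest.raises(RhythmError):
            chi_squared_periodogram(np.random.default_rng(0).random(200), BIN)


class TestActogram:
    def test_two_days_single_plot_shape(self):
        mat = actogram_matrix(np.arange(288.0), BIN, double_plot=False)
        assert mat.shape == (2, 144)

    def test_double_plot_repeats_next_day_and_pads_last_row(self):
        mat = actogram_matrix(np.arange(288.0), BIN)
        assert mat.shape == (2, 288)
        np.testing.assert_array_equal(mat[0, 144:], mat[1, :144])
        assert np.isnan(mat[1, 144:]).all()

    def test_row_sums_conserve_daily_totals(self):
        rng = np.random.default_rng(2)
        x = rng.random(3 * 144) * 30
        mat = actogram_matrix(x, BIN, double_plot=False)
        np.testing.assert_allclose(mat.sum(axis=1), x.reshape(3, 144).sum(axis=1))

    def test_folding_at_simulated_tau_aligns_onsets_vertically(self):
        cfg = clear_onset_config(seed=3)
        out = simulate_mouse(cfg)
        binned = resample_activity(out.trace, 1080, "mean")  # 18 min divides tau
        mat = actogram_matrix(binned.cage(0), 1080, cfg.tau_dd_s,
                              double_plot=False)
        cols = []
        for row in mat:
            if np.isnan(row).any():
                continue
            onset = activity_onset(row, 1080)
            assert onset is not None
            cols.append(onset / 1080)
        assert max(cols) - min(cols) <= 2  # constant column +/- 1 bin


class TestLightSchedule:
    def _square(self, n_days=2):
        t = np.arange(n_days * 8640) * 10
        return np.where((t % 86400) < 43200, 600.0, 0.0)

    def test_12h12h_square_wave_is_LD_with_24h_period(self, start):
        sch = infer_light_schedule(self._square(), 10, start_time=start)
        assert sch.regime == "LD"
        assert sch.period_s == pytest.approx(86400)
        # transitions at the true switch times
        trans = [(t - start).total_seconds() for t in sch.transitions]
        assert trans == [43200, 86400, 129600]

    def test_all_zero_light_is_DD(self):
        assert infer_light_schedule(np.zeros(1000), 10).regime == "DD"

    def test_single_epoch_spike_is_debounced(self, start):
        light = self._square()
        clean = infer_light_schedule(light, 10, start_time=start)
        light[5000] = 600.0  # one bright epoch inside the dark phase
        spiked = infer_light_schedule(light, 10, start_time=start)
        assert [iv[2] for iv in spiked.intervals] == [iv[2] for iv in clean.intervals]
        assert spiked.regime == "LD"

    def test_constant_nonzero_light_needs_explicit_threshold(self):
        with pytest.raises(ScheduleError):
            infer_light_schedule(np.full(1000, 300.0), 10)
        sch = infer_light_schedule(np.full(1000, 300.0), 10, threshold=100.0)
        assert sch.regime == "LL"

    def test_phase_at_assigns_bins_by_start_time(self, start):
        import pandas as pd
        sch = infer_light_schedule(self._square(), 10, start_time=start)
        times = pd.DatetimeIndex([start, start + pd.Timedelta(hours=13)])
        np.testing.assert_array_equal(sch.phase_at(times), ["LIGHT", "DARK"])


class TestOnset:
    def test_step_profile_onset_at_the_step(self):
        prof = np.concatenate([np.zeros(72), np.full(72, 50.0)])
        assert activity_onset(prof, BIN) == 72 * BIN

    def test_flat_profile_has_no_onset(self):
        assert activity_onset(np.full(144, 10.0), BIN) is None

    def test_simulated_cohort_median_onset_near_lights_off(self):
        onsets = []
        for seed in range(8):
            cfg = clear_onset_config(seed, regime="LD", duration_days=4)
            out = simulate_mouse(cfg)
            binned = resample_activity(out.trace, BIN, "mean")
            onsets += [o for o in activity_onsets(binned.cage(0), BIN)
                       if o is not None]
        lights_off = 43200
        assert abs(np.median(onsets) - lights_off) <= 20 * 60


class TestStability:
    def test_identical_repeated_days_give_IS_of_one(self):
        day = np.sin(np.linspace(0, 2 * np.pi, 48, endpoint=False)) + 1
        assert interdaily_stability(np.tile(day, 7), 1800) == pytest.approx(1.0)

    def test_shuffling_days_preserves_IS_but_within_day_shuffle_destroys_it(self):
        rng = np.random.default_rng(9)
        day = np.sin(np.linspace(0, 2 * np.pi, 48, endpoint=False)) + 1
        x = (np.tile(day, 6) + rng.normal(0, 0.1, 6 * 48)).clip(min=0)
        base = interdaily_stability(x, 1800)
        days = x.reshape(6, 48)[rng.permutation(6)]
        assert interdaily_stability(days.ravel(), 1800) == pytest.approx(base)
        within = np.array([rng.permutation(d) for d in x.reshape(6, 48)]).ravel()
        assert interdaily_stability(within, 1800) < base / 2

    def test_IV_near_two_for_white_noise_and_small_for_sine(self):
        rng = np.random.default_rng(3)
        ivs = [intradaily_variability(rng.random(1000)) for _ in range(50)]
        assert np.mean(ivs) == pytest.approx(2.0, abs=0.1)
        sine = np.sin(np.linspace(0, 14 * np.pi, 7 * 48))
        assert intradaily_variability(sine) < 0.1

    def test_zero_variance_is_an_error(self):
        with pytest.raises(RhythmError):
            interdaily_stability(np.full(96, 3.0), 1800)
        with pytest.raises(RhythmError):
            intradaily_variability(np.full(96, 3.0))
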