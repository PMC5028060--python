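"""Descriptive summaries, state contrasts, day-level series, completion."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_series

from esmnet.core import SYMPTOMS, EsmSeries, InsufficientDataError
from esmnet.descriptives import (
    _oneway_anova,
    beeps_per_day_anova,
    compare_states,
    completion_stats,
    day_level_series,
    day_sd_by_state_anova,
    state_summary,
)


def _ratings(down):
    return [down, 1, 3, 5, 4]


class TestStateSummary:
    def test_hand_computed_mean_and_sample_sd(self):
        series = make_series([
            (1, 350, [_ratings(2), _ratings(2), _ratings(5)]),
        ])
        table = state_summary(series).table.set_index(["state", "symptom"])
        row = table.loc[("stable", "down")]
        assert row["n"] == 3
        assert row["mean"] == pytest.approx(3.0)
        assert row["sd"] == pytest.approx(1.7320508, abs=1e-6)

    def test_single_observation_has_undefined_sd(self):
        series = make_series([(1, 350, [_ratings(4)])])
        table = state_summary(series).table.set_index(["state", "symptom"])
        assert np.isnan(table.loc[("stable", "down"), "sd"])

    def test_absent_states_undefined_not_zero(self):
        series = make_series([(1, 350, [_ratings(2)])])
        table = state_summary(series).table.set_index(["state", "symptom"])
        assert np.isnan(table.loc[("full_relapse", "down"), "mean"])
        assert table.loc[("full_relapse", "down"), "n"] == 0

    def test_pooled_mean_is_weighted_state_mean(self, sim_series):
        summary = state_summary(sim_series)
        t = summary.table
        for s in SYMPTOMS:
            rows = t[(t["symptom"] == s) & (t["n"] > 0)]
            pooled = (rows["mean"] * rows["n"]).sum() / rows["n"].sum()
            direct = sim_series.answered()[s].dropna().astype(float).mean()
            assert pooled == pytest.approx(direct)


class TestCompareStates:
    def _two_state_series(self, rng, n_a=300, n_b=100, shift=1.0):
        days = []
        cal = 1
        for n, dose, loc in ((n_a, 350, 2.0), (n_b, 450, 2.0 + shift)):
            for _ in range(0, n, 5):
                vals = np.clip(np.rint(rng.normal(loc, 1.0, size=5)), 1, 7)
                days.append((cal, dose, [_ratings(int(v)) for v in vals]))
                cal += 1
        return make_series(days)

    def test_identical_samples_give_t0_p1(self):
        series = make_series([
            (1, 350, [_ratings(3), _ratings(3)]),
            (2, 450, [_ratings(3), _ratings(3)]),
        ])
        c = compare_states(series, "down", "stable", "full_relapse")
        assert c.statistic == 0.0 and c.p_value == 1.0

    def test_detects_one_point_shift(self, rng):
        series = self._two_state_series(rng)
        c = compare_states(series, "down", "stable", "full_relapse")
        assert c.p_value < 1e-3
        assert c.direction == "b>a"

    def test_swapping_states_flips_sign_same_p(self, rng):
        series = self._two_state_series(rng)
        ab = compare_states(series, "down", "stable", "full_relapse")
        ba = compare_states(series, "down", "full_relapse", "stable")
        assert ab.statistic == pytest.approx(-ba.statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_insufficient_observations_raise(self):
        series = make_series([(1, 350, [_ratings(3)]),
                              (2, 450, [_ratings(3), _ratings(4)])])
        with pytest.raises(InsufficientDataError):
            compare_states(series, "down", "stable", "full_relapse")


class TestDayLevel:
    def test_hand_computed_day_mean(self):
        series = make_series([(1, 350, [_ratings(7), _ratings(7), _ratings(3)])])
        day = day_level_series(series)
        assert day.loc[1, "down"] == pytest.approx(5.6667, abs=1e-3)
        assert day.loc[1, "n_answered"] == 3

    def test_unanswered_day_is_undefined(self):
        series = make_series([(1, 350, [_ratings(4)]), (2, 350, [None, None])])
        day = day_level_series(series)
        assert np.isnan(day.loc[2, "down"])
        assert day.loc[2, "n_answered"] == 0

    def test_constant_series_constant_day_means(self):
        series = make_series([(d, 350, [_ratings(4), _ratings(4)])
                              for d in range(1, 5)])
        day = day_level_series(series)
        assert (day["down"] == 4.0).all()


class TestDaySdAnova:
    def test_state_dependent_noise_is_detected(self):
        rng = np.random.default_rng(42)
        days = []
        for d in range(1, 201):
            dose = 350 if d <= 100 else 450
            sd = 0.8 if dose == 350 else 1.6
            vals = np.clip(np.rint(rng.normal(4.0, sd, size=6)), 1, 7)
            days.append((d, dose, [_ratings(int(v)) for v in vals]))
        result = day_sd_by_state_anova(make_series(days))
        assert result.loc["down", "p_value"] < 0.05

    def test_two_groups_equal_squared_t(self):
        rng = np.random.default_rng(1)
        days = []
        for d in range(1, 41):
            dose = 350 if d <= 20 else 450
            vals = np.clip(np.rint(rng.normal(4.0, 1.2, size=5)), 1, 7)
            days.append((d, dose, [_ratings(int(v)) for v in vals]))
        series = make_series(days)
        result = day_sd_by_state_anova(series)
        # recompute the classical (equal-variance) t on the same day sds
        from scipy import stats
        af = series.answered()
        sds = af.groupby("calendar_day")["down"].std(ddof=1)
        day_state = af.drop_duplicates("calendar_day").set_index("calendar_day")["state"]
        a = sds[day_state == "stable"]
        b = sds[day_state == "full_relapse"]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert result.loc["down", "F"] == pytest.approx(t**2)
        assert result.loc["down", "p_value"] == pytest.approx(p)

    def test_insufficient_states_raise(self):
        days = [(d, 350, [_ratings(3), _ratings(4)]) for d in range(1, 5)]
        with pytest.raises(InsufficientDataError):
            day_sd_by_state_anova(make_series(days))


class TestBeepsPerDayAnova:
    def _counts_series(self, rng, p_by_dose, n_days=100):
        days = []
        cal = 1
        for dose, p in p_by_dose.items():
            for _ in range(n_days):
                answered = rng.random(10) < p
                beeps = [_ratings(3) if a else None for a in answered]
                if not answered.any():
                    beeps[0] = _ratings(3)  # keep the day observed
                days.append((cal, dose, beeps))
                cal += 1
        return make_series(days, gap=90)

    def test_unequal_completion_is_detected(self, rng):
        series = self._counts_series(rng, {350: 0.3, 450: 0.7})
        result = beeps_per_day_anova(series)
        assert result.p_value < 1e-3
        assert result.by_state.loc["stable", "mean"] < \
            result.by_state.loc["full_relapse", "mean"]

    def test_single_state_f_undefined(self):
        days = [(d, 350, [_ratings(3), _ratings(4)]) for d in range(1, 5)]
        result = beeps_per_day_anova(make_series(days))
        assert np.isnan(result.F) and np.isnan(result.p_value)
        assert result.by_state.loc["stable", "n_days"] == 4

    def test_type_i_error_calibrated_under_equal_completion(self):
        # same completion in all three groups: p < 0.05 in ~5% of replicates
        rng = np.random.default_rng(7)
        hits = 0
        reps = 400
        for _ in range(reps):
            groups = [rng.binomial(10, 943 / 2010, size=67).astype(float)
                      for _ in range(3)]
            _, p = _oneway_anova(groups)
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07


class TestCompletionStats:
    def test_arithmetic_on_known_counts(self):
        series = make_series([
            (1, 350, [_ratings(3), None, _ratings(4), None]),
            (2, 350, [_ratings(2), _ratings(2), _ratings(2), _ratings(2)]),
        ])
        cs = completion_stats(series)
        assert cs.n_answered == 6 and cs.n_scheduled == 8
        assert cs.fraction == pytest.approx(0.75)
        assert cs.mean_per_day == pytest.approx(3.0)
        assert (cs.min_per_day, cs.max_per_day) == (2, 4)

    def test_full_completion_fraction_one(self):
        series = make_series([(1, 350, [_ratings(3), _ratings(4)])])
        assert completion_stats(series).fraction == 1.0

    def test_simulated_fraction_consistent(self, sim_series):
        cs = completion_stats(sim_series)
        assert cs.n_scheduled == 201 * 10
        assert cs.fraction == pytest.approx(sim_series.n_answered / 2010)
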