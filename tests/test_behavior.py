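"""Learner criterion, avoidance rates, sigmoid generalization, ANOVA/Tukey."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sleepgate import stats, synth
from sleepgate.stats import (
    anova_tukey,
    avoidance_by_sound,
    classify_learner,
    fit_sigmoid,
    tukey_hsd_pvalue,
)


def _trials(day2_avoid_frac, n_day2, n_day1=10):
    rows = [
        {"animal_id": "m01", "day": 1, "trial_index": i + 1, "avoided": True}
        for i in range(n_day1)
    ]
    n_avoid = int(round(day2_avoid_frac * n_day2))
    for i in range(n_day2):
        rows.append(
            {
                "animal_id": "m01",
                "day": 2,
                "trial_index": i + 1,
                "avoided": i < n_avoid,
            }
        )
    return pd.DataFrame(rows)


class TestLearnerCriterion:
    def test_high_avoidance_enough_trials_is_learner(self):
        assert classify_learner(_trials(0.85, 20)) == "learner"

    def test_too_few_cumulative_trials_is_nonlearner(self):
        assert classify_learner(_trials(0.85, 10, n_day1=4)) == "nonlearner"

    def test_exactly_80_percent_is_nonlearner(self):
        assert classify_learner(_trials(0.80, 20)) == "nonlearner"

    def test_missing_day2_is_unknown(self):
        t = _trials(0.9, 20)
        assert classify_learner(t[t["day"] == 1]) == "unknown"

    @given(
        frac=st.floats(min_value=0.0, max_value=1.0),
        extra_frac=st.floats(min_value=0.0, max_value=0.2),
        n=st.integers(min_value=5, max_value=40),
        extra_n=st.integers(min_value=0, max_value=20),
    )
    def test_monotone_in_avoidance_and_trial_count(self, frac, extra_frac, n, extra_n):
        base = classify_learner(_trials(frac, n))
        better = classify_learner(_trials(min(frac + extra_frac, 1.0), n + extra_n))
        assert not (base == "learner" and better == "nonlearner")

    def test_simulated_cohort_splits_as_configured(self):
        trials = synth.simulate_terrace_trials(n_animals=9, n_learners=6, seed=4)
        cohorts = stats.classify_learners(trials)
        assert (cohorts == "learner").sum() >= 5
        assert (cohorts.iloc[6:] == "nonlearner").all()


class TestAvoidance:
    def _visits(self):
        rows = []
        for day, sound, pokes in [(1, "cond", 3), (2, "cond", 3), (5, "cond", 1),
                                  (1, "safe", 8), (2, "safe", 9), (5, "safe", 8)]:
            for i in range(10):
                rows.append(
                    {
                        "animal_id": "m01",
                        "day": day,
                        "visit_time": day * 1000 + i,
                        "sound": sound,
                        "nosepoked": i < pokes,
                    }
                )
        return pd.DataFrame(rows)

    def test_simple_percentage_arithmetic(self):
        out = avoidance_by_sound(self._visits(), "early")
        cond = out[out["sound"] == "cond"].iloc[0]
        assert cond["avoidance_pct"] == pytest.approx(70.0)

    def test_early_late_split_uses_first_and_last_days(self):
        early = avoidance_by_sound(self._visits(), "early")
        late = avoidance_by_sound(self._visits(), "late")
        # late keeps days {2, 5}: cond avoidance (7 + 9) / 20
        cond_late = late[late["sound"] == "cond"].iloc[0]
        assert cond_late["avoidance_pct"] == pytest.approx(80.0)
        assert early[early["sound"] == "cond"].iloc[0]["n_visits"] == 20

    def test_invalid_phase_rejected(self):
        with pytest.raises(ValueError):
            avoidance_by_sound(self._visits(), "middle")

    def test_simulated_audiobox_meets_stability_targets(self):
        visits = synth.simulate_audiobox_visits(seed=5)
        late = avoidance_by_sound(visits, "late")
        safe = late[late["sound"] == "safe"]["avoidance_pct"]
        cond = late[late["sound"] == "cond"]["avoidance_pct"]
        assert (100.0 - safe > 50.0).all()  # poke in >50% of safe visits
        assert (cond > 80.0).all()  # avoid >80% of conditioned visits


class TestSigmoid:
    def test_step_data_midpoint_between_ranks(self):
        fit = fit_sigmoid([1, 2, 3, 4], [0, 0, 100, 100])
        assert fit.converged
        assert fit.midpoint == pytest.approx(2.5, abs=0.2)

    def test_constant_data_flat_fit(self):
        fit = fit_sigmoid([1, 2, 3, 4, 5], [40, 40, 40, 40, 40])
        assert abs(fit.ceiling - fit.floor) * abs(fit.slope) < 1.0
        assert np.allclose(fit.fitted, 40, atol=1.0)

    def test_parameter_recovery_from_noisy_4pl(self):
        rng = np.random.default_rng(2)
        x = np.linspace(1, 5, 25)
        true = stats._four_pl(x, 10, 90, 3.0, 2.5)
        fit = fit_sigmoid(x, true + rng.normal(0, 2, x.size))
        assert fit.midpoint == pytest.approx(3.0, abs=0.3)
        assert fit.floor == pytest.approx(10, abs=8)
        assert fit.ceiling == pytest.approx(90, abs=8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([1, 2, 3], [0, 50, 100])


class TestAnovaTukey:
    def _table(self, means, n=8, sd=5.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for sound, mu in means.items():
            for i in range(n):
                rows.append(
                    {
                        "animal_id": f"m{i}",
                        "sound": sound,
                        "avoidance_pct": rng.normal(mu, sd),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_means_not_significant(self):
        res = anova_tukey(self._table({"a": 50, "b": 50, "c": 50}, seed=1))
        assert res.p_value > 0.05
        assert not res.tukey["reject"].any()

    def test_graded_means_give_main_effect_of_sound(self):
        res = anova_tukey(
            self._table({"safe": 30, "novel": 60, "cond": 90}, seed=2)
        )
        assert res.p_value < 0.001
        assert res.tukey["reject"].any()

    def test_equal_n_matches_studentized_range_oracle(self):
        table = self._table({"a": 40, "b": 55, "c": 70}, n=6, seed=3)
        res = anova_tukey(table)
        groups = {k: g["avoidance_pct"].to_numpy() for k, g in table.groupby("sound")}
        k, n = 3, 6
        mse = np.mean([np.var(v, ddof=1) for v in groups.values()])
        df_within = k * (n - 1)
        for _, row in res.tukey.iterrows():
            expected = tukey_hsd_pvalue(
                np.mean(groups[row["group1"]]),
                np.mean(groups[row["group2"]]),
                mse, n, k, df_within,
            )
            assert float(row["p_adj"]) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_tukey_p_at_least_unadjusted_pairwise(self, seed):
        """Studentized-range adjustment never undercuts the pooled-MSE
        pairwise t test on the same contrast."""
        from scipy import stats as sp_stats

        table = self._table({"a": 45, "b": 52, "c": 60, "d": 50}, n=5, seed=seed)
        res = anova_tukey(table)
        groups = {k: g["avoidance_pct"].to_numpy() for k, g in table.groupby("sound")}
        k, n = 4, 5
        mse = np.mean([np.var(v, ddof=1) for v in groups.values()])
        df_within = k * (n - 1)
        for _, row in res.tukey.iterrows():
            diff = np.mean(groups[row["group2"]]) - np.mean(groups[row["group1"]])
            t_stat = abs(diff) / np.sqrt(mse * 2 / n)
            t_p = 2 * sp_stats.t.sf(t_stat, df_within)
            assert float(row["p_adj"]) >= t_p - 1e-9

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey(self._table({"only": 50}))
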