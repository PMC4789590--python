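"""Oracle checks for the hand-built survival estimators.

Each estimator is compared against (a) hand-worked small fixtures and
(b) an established independent implementation (lifelines, statsmodels,
scipy) on the same data — the implementations under test never call those
libraries themselves.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methclock import (
    ConvergenceError,
    SimulationConfig,
    bh_adjust,
    cox_fit,
    km_estimate,
    logrank_test,
    prepare_survival,
    quartile_stratify,
    simulate_cohort,
    spearman_corr,
)


def _cox_table(times, events, **covs):
    return pd.DataFrame({"surv_time": times, "event": events, **covs})


class TestPrepareSurvival:
    @staticmethod
    def _ann():
        return pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "age": [79.0, 79.5, 80.0, 78.5],
                "sex": ["male", "female", "male", "female"],
                "surv_time": [1.5, 1.5, 3.0, 2.0],
                "event": [1, 0, 1, 1],
            }
        )

    def test_early_death_removed_censored_retained(self):
        table = prepare_survival(self._ann(), np.array([1.0, 2.0, 3.0, 4.0]))
        # death at 1.5y removed; censored at 1.5y retained; death at exactly 2.0 kept
        assert list(table["sample_id"]) == ["b", "c", "d"]

    def test_zero_exclusion_keeps_everyone(self):
        table = prepare_survival(self._ann(), np.zeros(4), exclude_years=0.0)
        assert len(table) == 4

    def test_per_five_year_scaling(self):
        table = prepare_survival(self._ann(), np.array([10.0, 0.0, -5.0, 2.5]))
        assert table.loc[table["sample_id"] == "c", "delta_scaled"].iloc[0] == -1.0
        got = table.set_index("sample_id")["delta_scaled"]
        assert got["d"] == pytest.approx(0.5)

    def test_all_events_excluded_is_an_error(self):
        ann = self._ann()
        ann["surv_time"] = [0.5, 1.0, 1.5, 1.0]
        with pytest.raises(ValueError, match="no events remain"):
            prepare_survival(ann, np.zeros(4))


class TestCoxFit:
    def test_matches_brute_force_partial_likelihood(self):
        # 4 subjects, no ties: grid-maximize the written-out partial likelihood
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 1])
        x = np.array([0.5, -0.3, 0.2, -0.1])
        table = _cox_table(times, events, x=x)
        fitted = cox_fit(table, ["x"]).coef("x")

        def pl(b):
            total = 0.0
            for i in range(4):
                if events[i]:
                    risk = [j for j in range(4) if times[j] >= times[i]]
                    total += b * x[i] - math.log(sum(math.exp(b * x[j]) for j in risk))
            return total

        grid = np.arange(-5.0, 5.0, 1e-4)
        brute = grid[np.argmax([pl(b) for b in grid])]
        assert fitted == pytest.approx(brute, abs=1e-3)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(1)
        n = 150
        table = _cox_table(
            rng.integers(1, 10, n).astype(float),
            (rng.random(n) < 0.7).astype(int),
            x1=rng.normal(size=n),
            x2=rng.normal(size=n),
        )
        ours = cox_fit(table, ["x1", "x2"], ties="efron")
        from lifelines import CoxPHFitter

        ll = CoxPHFitter().fit(table, "surv_time", "event")
        np.testing.assert_allclose(
            ours.summary["coef"].to_numpy(), ll.params_.to_numpy(), atol=1e-5
        )
        np.testing.assert_allclose(
            ours.summary["se"].to_numpy(), ll.standard_errors_.to_numpy(), atol=1e-5
        )

    def test_breslow_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        n = 120
        table = _cox_table(
            rng.integers(1, 8, n).astype(float),
            (rng.random(n) < 0.6).astype(int),
            x=rng.normal(size=n),
        )
        ours = cox_fit(table, ["x"], ties="breslow")
        import statsmodels.api as sm

        ph = sm.PHReg(
            table["surv_time"], table[["x"]], status=table["event"], ties="breslow"
        ).fit()
        assert ours.coef("x") == pytest.approx(ph.params[0], abs=1e-6)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(3)
        n = 60
        table = _cox_table(
            rng.uniform(0.1, 20.0, n),  # continuous: no ties
            (rng.random(n) < 0.7).astype(int),
            x=rng.normal(size=n),
        )
        assert cox_fit(table, ["x"], ties="efron").coef("x") == pytest.approx(
            cox_fit(table, ["x"], ties="breslow").coef("x"), abs=1e-12
        )

    def test_null_covariate_recovered_as_hr_one(self):
        rng = np.random.default_rng(4)
        n = 1500
        table = _cox_table(
            rng.exponential(10.0, n),
            np.ones(n, dtype=int),
            x=rng.normal(size=n),
        )
        res = cox_fit(table, ["x"])
        assert abs(res.coef("x")) < 3 * res.summary.loc["x", "se"]

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        n = 50
        table = _cox_table(
            rng.exponential(5.0, n), np.ones(n, dtype=int),
            x=rng.normal(size=n), const=np.full(n, 2.0),
        )
        with pytest.warns(RuntimeWarning, match="constant covariate"):
            res = cox_fit(table, ["x", "const"])
        assert list(res.summary.index) == ["x"]

    def test_two_group_parameter_recovery_hr2(self):
        rng = np.random.default_rng(6)
        n = 1000
        group = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.1 * np.exp(math.log(2.0) * group)))
        table = _cox_table(np.minimum(t, 15.0), (t <= 15.0).astype(int), group=group)
        res = cox_fit(table, ["group"])
        assert abs(res.coef("group") - math.log(2.0)) < 3 * res.summary.loc["group", "se"]

    def test_scaling_invariance_per5yr_equals_peryear_power5(self):
        rng = np.random.default_rng(7)
        n = 400
        delta = rng.normal(0, 8, n)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.02 * delta)))
        table = _cox_table(
            np.minimum(t, 12.0), (t <= 12.0).astype(int),
            delta=delta, delta5=delta / 5.0,
        )
        hr_year = cox_fit(table, ["delta"]).hazard_ratio("delta")
        hr_5yr = cox_fit(table, ["delta5"]).hazard_ratio("delta5")
        assert hr_5yr == pytest.approx(hr_year**5, abs=1e-8)

    def test_sex_recoding_leaves_delta_hr_unchanged(self):
        rng = np.random.default_rng(8)
        n = 300
        delta5 = rng.normal(0, 1.6, n)
        sex = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.1 * delta5 + 0.4 * sex)))
        table = _cox_table(
            np.minimum(t, 12.0), (t <= 12.0).astype(int),
            delta5=delta5, sex=sex, sex_flipped=1 - sex,
        )
        a = cox_fit(table, ["delta5", "sex"]).coef("delta5")
        b = cox_fit(table, ["delta5", "sex_flipped"]).coef("delta5")
        assert a == pytest.approx(b, abs=1e-8)

    def test_ci_definition(self):
        rng = np.random.default_rng(9)
        n = 200
        table = _cox_table(
            rng.exponential(5.0, n), np.ones(n, dtype=int), x=rng.normal(size=n)
        )
        res = cox_fit(table, ["x"])
        row = res.summary.loc["x"]
        assert row["ci_low"] == pytest.approx(math.exp(row["coef"] - 1.96 * row["se"]))
        assert row["ci_high"] == pytest.approx(math.exp(row["coef"] + 1.96 * row["se"]))

    def test_perfect_separation_raises(self):
        # all events in the low-x half, observed strictly earlier: monotone likelihood
        x = np.array([0.0] * 10 + [1.0] * 10)
        times = np.concatenate([np.arange(1, 11), np.arange(20, 30)]).astype(float)
        events = np.array([1] * 10 + [0] * 10)
        with pytest.raises(ConvergenceError):
            cox_fit(_cox_table(times, events, x=x), ["x"])

    def test_no_events_rejected(self):
        table = _cox_table([1.0, 2.0], [0, 0], x=[0.1, 0.2])
        with pytest.raises(ValueError, match="no events"):
            cox_fit(table, ["x"])


class TestKaplanMeier:
    def test_manual_product_limit_all_events(self):
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [0.8, 0.6, 0.4, 0.2, 0.0], atol=1e-12)
        np.testing.assert_array_equal(km.at_risk, [5, 4, 3, 2, 1])

    def test_no_events_flat_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at(0.0) == 1.0
        assert km.survival_at(10.0) == 1.0

    def test_single_subject_drops_to_zero(self):
        km = km_estimate([1.0], [1])
        assert km.survival_at(1.0) == 0.0
        assert km.survival_at(0.99) == 1.0

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(10)
        times = rng.exponential(5.0, 200)
        km = km_estimate(times, np.ones(200, dtype=int))
        grid = np.quantile(times, [0.1, 0.25, 0.5, 0.75, 0.9])
        empirical = [(times > t).mean() for t in grid]
        np.testing.assert_allclose(km.survival_at(grid), empirical, atol=1e-12)

    def test_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(5.0, 100)
        e = (rng.random(100) < 0.6).astype(int)
        km = km_estimate(t, e)
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(t, e)
        theirs = kmf.survival_function_at_times(km.times).to_numpy()
        np.testing.assert_allclose(km.survival, theirs, atol=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])

    @given(
        st.lists(
            st.tuples(st.floats(0.1, 50.0), st.booleans()), min_size=1, max_size=60
        )
    )
    def test_curve_is_a_survival_function(self, subjects):
        times = [t for t, _ in subjects]
        events = [int(e) for _, e in subjects]
        km = km_estimate(times, events)
        assert ((km.survival >= -1e-12) & (km.survival <= 1 + 1e-12)).all()
        assert (np.diff(km.survival) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_give_null(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 1, 0, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        chi2, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_worked_fixture(self):
        # A: death@1, death@3, censored@5 ; B: death@2, death@4, death@6
        # observed-minus-expected bookkeeping gives chi2 = 32/433 exactly
        times = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        events = [1, 1, 0, 1, 1, 1]
        groups = ["A", "A", "A", "B", "B", "B"]
        chi2, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(32.0 / 433.0, abs=1e-10)
        from scipy import stats

        assert p == pytest.approx(stats.chi2.sf(32.0 / 433.0, 1), abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(12)
        n = 120
        g = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.7 * g)))
        e = (t <= 10).astype(int)
        t = np.minimum(t, 10)
        chi2, p = logrank_test(t, e, g)
        from lifelines.statistics import logrank_test as ll_logrank

        ll = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ll.test_statistic, abs=1e-8)
        assert p == pytest.approx(ll.p_value, abs=1e-10)

    def test_power_against_strong_effect(self):
        hits = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            n = 500
            g = rng.integers(0, 2, n)
            t = rng.exponential(1.0 / (0.1 * np.exp(math.log(3.0) * g)))
            e = (t <= 15).astype(int)
            _, p = logrank_test(np.minimum(t, 15), e, g)
            hits += p < 0.001
        assert hits >= int(0.95 * reps)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


class TestQuartiles:
    def test_eight_distinct_values(self):
        q = quartile_stratify(pd.Series([1, 2, 3, 4, 5, 6, 7, 8]))
        assert list(q[:2]) == ["Q1", "Q1"]
        assert list(q[6:]) == ["Q4", "Q4"]

    def test_all_ties_is_deterministic_and_balanced(self):
        q1 = quartile_stratify(np.zeros(10))
        q2 = quartile_stratify(np.zeros(10))
        assert (q1 == q2).all()
        sizes = q1.value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_cohort_sized_partition(self):
        q = quartile_stratify(np.random.default_rng(13).normal(size=446))
        sizes = q.value_counts()
        assert sizes["Q1"] in (111, 112) and sizes["Q4"] in (111, 112)
        assert sizes.sum() == 446

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 4"):
            quartile_stratify([1.0, 2.0, 3.0])

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=200))
    def test_sizes_differ_by_at_most_one(self, values):
        sizes = quartile_stratify(np.array(values)).value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert set(sizes.index) == {"Q1", "Q2", "Q3", "Q4"}


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(14)
        p = rng.random(200)
        from statsmodels.stats.multitest import multipletests

        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm, atol=1e-12)

    def test_nan_entries_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert math.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=100))
    def test_definitional_properties(self, p):
        p = np.array(p)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empirical_fdr_control_on_uniform_nulls(self):
        rng = np.random.default_rng(15)
        false_hits = 0
        reps = 200
        for _ in range(reps):
            false_hits += (bh_adjust(rng.random(100)) < 0.05).sum() > 0
        # under the global null, FDR = P(any discovery) <= 0.05
        assert false_hits / reps <= 0.08


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        assert spearman_corr(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        assert spearman_corr([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(-1.0)

    def test_eight_pair_tied_fixture_hand_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 6.0])
        # average ranks assigned by hand
        rx = [1.0, 2.5, 2.5, 4.0, 5.0, 7.0, 7.0, 7.0]
        ry = [2.0, 1.0, 3.5, 3.5, 6.0, 5.0, 7.5, 7.5]
        mx, my = sum(rx) / 8, sum(ry) / 8
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
        )
        assert spearman_corr(x, y) == pytest.approx(num / den, abs=1e-12)
        from scipy import stats

        assert spearman_corr(x, y) == pytest.approx(
            stats.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning, match="zero variance"):
            assert math.isnan(spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestNullLogrankOnSimulatedCohorts:
    def test_no_acceleration_effect_means_no_group_difference(self):
        # hazard independent of acceleration: high/low-acceleration halves
        # should rarely differ at alpha = 0.01
        nonsig = 0
        reps = 30
        for r in range(reps):
            cohort = simulate_cohort(
                SimulationConfig(
                    n_samples=200, n_age_cpgs=5, n_null_cpgs=0,
                    log_hr_per_5yr=0.0, seed=1000 + r,
                )
            )
            accel = cohort.truth.acceleration.to_numpy()
            groups = (accel > np.median(accel)).astype(int)
            _, p = logrank_test(
                cohort.annotation["surv_time"].to_numpy(),
                cohort.annotation["event"].to_numpy(),
                groups,
            )
            nonsig += p >= 0.01
        assert nonsig >= int(0.9 * reps)
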