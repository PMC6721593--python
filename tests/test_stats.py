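import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as stx
from scipy import stats as sps

import adipoct as a
from adipoct.errors import DegenerateDataError, ValidationError
from adipoct.stats import round_half_up
from ._oracles import (
    cox_grid_coefficient,
    fisher_exact_two_sided,
    km_empirical_survivor,
    logrank_chi2,
    youden_scan,
)


class TestCCC:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
            ([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], 4.0 / 7.0),
            ([-1.0, 0.0, 1.0], [1.0, 0.0, -1.0], -1.0),
        ],
    )
    def test_hand_values(self, x, y, expected):
        res = a.concordance_correlation(x, y)
        assert res.estimate == pytest.approx(expected, abs=1e-12)
        assert res.ci_lo <= res.estimate <= res.ci_hi

    def test_degenerate_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            a.concordance_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        stx.lists(stx.floats(-100, 100), min_size=4, max_size=30),
        stx.lists(stx.floats(-100, 100), min_size=4, max_size=30),
    )
    def test_symmetry_and_bounded_by_pearson(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.asarray(xs[:n]), np.asarray(ys[:n])
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
            return
        cxy = a.concordance_correlation(x, y).estimate
        cyx = a.concordance_correlation(y, x).estimate
        assert cxy == pytest.approx(cyx, abs=1e-12)
        r = sps.pearsonr(x, y)[0]
        assert abs(cxy) <= abs(r) + 1e-9
        assert -1 - 1e-12 <= cxy <= 1 + 1e-12


class TestPairedT:
    def test_identical_pairs_degenerate(self):
        with pytest.raises(DegenerateDataError):
            a.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_hand_arithmetic(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2*sqrt(3), df = 2
        t, p = a.paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(2 * math.sqrt(3), df=2), abs=1e-12)

    def test_simulated_tat_exceeds_cat(self, default_cohort):
        t, p = a.paired_t_test(default_cohort.tat_hu, default_cohort.cat_hu)
        assert t > 0 and p < 0.001


class TestGroupCompare:
    def test_identical_group_multisets_give_h_zero(self):
        values = [1, 2, 3, 1, 2, 3, 1, 2, 3]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = a.group_compare(values, groups)
        assert res.test_name == "kruskal_wallis"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_hand_rank_arithmetic_h(self):
        res = a.group_compare(
            [1, 2, 3, 4, 5, 6, 7, 8, 9], ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        )
        assert res.statistic == pytest.approx(7.2, abs=1e-12)
        assert res.posthoc is not None and len(res.posthoc) == 3

    def test_two_groups_use_student_t(self):
        res = a.group_compare([1.0, 2.0, 3.0, 6.0, 7.0, 8.0], ["a"] * 3 + ["b"] * 3)
        assert res.test_name == "student_t"
        t, p = sps.ttest_ind([1.0, 2.0, 3.0], [6.0, 7.0, 8.0], equal_var=True)
        assert res.statistic == pytest.approx(float(t))
        assert res.p_value == pytest.approx(float(p))

    def test_posthoc_separates_programmed_stage_ordering(self):
        big = a.simulate_cohort(a.CohortSpec(n_patients=3000), seed=9)
        res = a.group_compare(big.tat_hu.to_numpy(), big.t_stage.to_numpy())
        assert res.p_value < 0.001
        assert (res.posthoc.p_value < 0.05).all()

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            a.group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestSpearman:
    def test_monotone_perfect(self):
        x = np.arange(10.0)
        rho, _ = a.spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_hand_example(self):
        rho, _ = a.spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6, abs=1e-12)

    def test_constant_degenerate(self):
        with pytest.raises(DegenerateDataError):
            a.spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_simulated_bmi_negative_with_cat(self):
        df = a.simulate_cohort(a.CohortSpec(n_patients=2000), seed=13)
        rho, p = a.spearman_correlation(df.bmi, df.cat_hu)
        assert rho < 0 and p < 0.001


def _fit_df(times, events, x):
    return pd.DataFrame(
        {"followup_months": times, "recurrence": events, "x": x}
    )


class TestCox:
    def test_four_subject_fixture_matches_grid_oracle(self):
        times, events, x = [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [1.0, 0.0, 1.0, 0.0]
        fit = a.cox_regression(_fit_df(times, events, x), ["x"])
        oracle = cox_grid_coefficient(times, events, x)
        assert fit.row("x")["coefficient"] == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_fixtures_match_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        times = rng.permutation(np.arange(1.0, n + 1))
        events = rng.integers(0, 2, n)
        events[rng.integers(0, n)] = 1  # at least one event
        x = rng.normal(0, 1, n).round(2)
        fit = a.cox_regression(_fit_df(times, events, x), ["x"])
        beta = fit.row("x")["coefficient"]
        if abs(beta) > 4.5:
            return  # near-separated fixture; grid bound would clip
        oracle = cox_grid_coefficient(times, events, x)
        assert beta == pytest.approx(oracle, abs=1e-3)

    def test_null_two_group_hazard_ratio_near_one(self):
        rng = np.random.default_rng(0)
        n = 3000
        df = _fit_df(
            rng.exponential(50, n), np.ones(n, int), rng.integers(0, 2, n)
        )
        hr = a.cox_regression(df, ["x"]).row("x")["hazard_ratio"]
        assert hr == pytest.approx(1.0, abs=0.08)

    def test_constant_covariate_and_no_events_rejected(self):
        with pytest.raises(ValidationError):
            a.cox_regression(_fit_df([1, 2, 3], [1, 1, 0], [2.0, 2.0, 2.0]), ["x"])
        with pytest.raises(ValidationError):
            a.cox_regression(_fit_df([1, 2, 3], [0, 0, 0], [1.0, 2.0, 3.0]), ["x"])

    def test_categorical_stage_expansion(self, default_cohort):
        fit = a.cox_regression(default_cohort, ["t_stage"], model_label="univariate")
        assert set(fit.table.covariate) == {"t_stage_T2", "t_stage_T3"}
        assert (fit.table.hazard_ratio > 0).all()
        assert (fit.table.ci_lo <= fit.table.hazard_ratio).all()
        assert (fit.table.hazard_ratio <= fit.table.ci_hi).all()


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self):
        times = [1.0, 2.0, 3.0]
        km = a.kaplan_meier(times, [1, 1, 1])
        assert [km.survival_at(t) for t in times] == pytest.approx([2 / 3, 1 / 3, 0.0])
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 40)
        km = a.kaplan_meier(t, np.ones(40))
        ts, s = km_empirical_survivor(t)
        assert [km.survival_at(v) for v in ts] == pytest.approx(list(s))

    def test_hand_product_limit_with_censoring(self):
        km = a.kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_all_censored_survival_stays_one(self):
        km = a.kaplan_meier([5.0, 6.0, 7.0], [0, 0, 0])
        assert km.survival_at(100.0) == 1.0
        assert km.survival_at(-1.0) == 1.0


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 1, 1, 1, 1]
        chi2, p = a.log_rank(times, events, [True, True, True, False, False, False])
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_six_subject_hand_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 0, 1, 1, 1]
        group = [True, False, True, True, False, False]
        chi2, _ = a.log_rank(times, events, group)
        assert chi2 == pytest.approx(logrank_chi2(times, events, group), abs=1e-6)

    def test_high_tat_group_has_worse_survival(self):
        df = a.simulate_cohort(a.CohortSpec(n_patients=2000), seed=17)
        high = df.tat_hu >= df.tat_hu.quantile(0.75)
        chi2, p = a.log_rank(df.followup_months, df.recurrence, high)
        assert p < 0.001

    def test_one_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            a.log_rank([1.0, 2.0], [1, 1], [True, True])


class TestOptimalCutoff:
    def test_perfect_separation_midpoint(self):
        res = a.optimal_cutoff([10.0, 12.0, 1.0, 2.0], [1, 1, 0, 0])
        assert res.threshold == 6.0
        assert res.youden_j == pytest.approx(1.0)

    def test_tie_break_toward_higher_sensitivity(self):
        res = a.optimal_cutoff([3.0, 5.0, 2.0, 4.0], [1, 1, 0, 0])
        assert res.threshold == 2.5
        assert res.youden_j == pytest.approx(0.5)
        assert res.sensitivity == 1.0

    def test_null_scores_give_small_j(self):
        rng = np.random.default_rng(1)
        res = a.optimal_cutoff(rng.normal(size=800), rng.integers(0, 2, 800))
        assert 0 <= res.youden_j < 0.15

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        scores = rng.normal(size=n).round(2)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = a.optimal_cutoff(scores, labels)
        thr, j, (sens, spec) = youden_scan(scores, labels)
        assert res.threshold == pytest.approx(thr)
        assert res.youden_j == pytest.approx(j)
        assert res.sensitivity == pytest.approx(sens)
        assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            a.optimal_cutoff([1.0, 2.0], [1, 1])


def _counts_frame(cells):
    """cells: list of (stage, high_flag, events, total)."""
    rows = []
    for stage, high, events, total in cells:
        score = 0.0 if high else -10.0
        for i in range(total):
            rows.append(
                {"t_stage": stage, "tat_hu": score, "recurrence": int(i < events)}
            )
    return pd.DataFrame(rows)


class TestStratifiedRecurrence:
    def test_reported_counts_reproduce_percentages(self):
        df = _counts_frame(
            [
                ("T1", False, 1, 117),
                ("T1", True, 1, 19),
                ("T2", False, 14, 110),
                ("T3", True, 14, 41),
            ]
        )
        table = a.stratified_recurrence_table(df, "tat_hu", cutoff=-5.0)
        get = lambda s, arm: table[(table.stratum == s) & (table.arm == arm)].iloc[0]
        assert get("T1", "low").pct == 0.9
        assert get("T1", "high").pct == 5.3
        assert get("T2-T3", "low").pct == 12.7
        assert get("T2-T3", "high").pct == 34.1

    def test_zero_recurrence_both_arms(self):
        df = _counts_frame([("T1", False, 0, 20), ("T1", True, 0, 10)])
        table = a.stratified_recurrence_table(df, "tat_hu", cutoff=-5.0)
        t1 = table[table.stratum == "T1"]
        assert (t1.pct == 0.0).all()
        assert np.allclose(t1.p_value, 1.0)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        table22 = [[14, 96], [14, 27]]
        p_scipy = sps.fisher_exact(table22)[1]
        assert p_scipy == pytest.approx(fisher_exact_two_sided(table22), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_fisher_transpose_invariance(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 30, (2, 2))
        p1 = sps.fisher_exact(t)[1]
        p2 = sps.fisher_exact(t.T)[1]
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert p1 == pytest.approx(fisher_exact_two_sided(t.tolist()), rel=1e-9)

    def test_empty_stratum_not_evaluable(self):
        df = _counts_frame([("T1", False, 1, 10)])
        table = a.stratified_recurrence_table(df, "tat_hu", cutoff=-5.0)
        t1 = table[table.stratum == "T1"]
        assert np.isnan(t1.p_value).all()  # one empty arm -> no exact test
        assert table[table.stratum == "T2-T3"].total.sum() == 0


def test_round_half_up_report_convention():
    assert round_half_up(0.8547 * 100 / 100 * 1.0, 1) == 0.9
    assert round_half_up(12.727) == 12.7
    assert round_half_up(34.146) == 34.1
    assert round_half_up(0.05, 1) == 0.1  # half rounds up, not to even
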