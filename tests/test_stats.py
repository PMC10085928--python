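"""Inaccuracy metrics, rank tests, weighted kappa, stage timing."""

from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from acetage import (
    EstimatePair,
    absolute_error,
    band_report,
    bias,
    boxplot_summary,
    compare_stage_timing,
    landis_koch_label,
    mann_whitney_u,
    stage_timing_summary,
    weighted_kappa,
    wilcoxon_signed_rank,
)
from conftest import make_record


def pairs_from(chron, est):
    return [EstimatePair(str(i), c, e) for i, (c, e) in enumerate(zip(chron, est))]


class TestBiasAndAbsoluteError:
    def test_perfect_estimates_give_zero(self):
        p = pairs_from([30, 50, 70], [30, 50, 70])
        assert bias(p) == 0.0
        assert absolute_error(p) == 0.0

    def test_symmetric_errors_cancel_in_bias_not_error(self):
        p = pairs_from([55, 55], [50, 60])
        assert bias(p) == 0.0
        assert absolute_error(p) == 5.0

    def test_overestimation_is_positive(self):
        p = pairs_from([45, 45], [50, 60])
        assert bias(p) == pytest.approx(10.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bias([])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(15, 100), st.floats(15, 100)),
                    min_size=1, max_size=30))
    def test_abs_error_dominates_bias(self, data):
        p = pairs_from([c for c, _ in data], [e for _, e in data])
        assert abs(bias(p)) <= absolute_error(p) + 1e-12


class TestBandReport:
    @pytest.mark.parametrize("age,scope", [(39, "15-39"), (40, "40-64"),
                                           (64, "40-64"), (65, ">=65")])
    def test_band_boundaries(self, age, scope):
        reports = band_report(pairs_from([age], [age + 2.0]))
        by_scope = {r.scope: r for r in reports}
        assert by_scope[scope].n == 1
        assert by_scope[scope].bias == pytest.approx(2.0)

    def test_global_is_weighted_combination_of_bands(self):
        rng = np.random.default_rng(0)
        chron = rng.uniform(16, 95, size=40)
        est = chron + rng.normal(0, 8, size=40)
        reports = {r.scope: r for r in band_report(pairs_from(chron, est))}
        bands = [reports["15-39"], reports["40-64"], reports[">=65"]]
        n = sum(b.n for b in bands)
        combined_bias = sum(b.n * b.bias for b in bands if b.n) / n
        combined_err = sum(b.n * b.absolute_error for b in bands if b.n) / n
        assert reports["global"].n == n
        assert reports["global"].bias == pytest.approx(combined_bias)
        assert reports["global"].absolute_error == pytest.approx(combined_err)

    def test_empty_band_flagged_with_nan(self):
        reports = {r.scope: r for r in band_report(pairs_from([70.0], [72.0]))}
        assert reports["15-39"].n == 0
        assert np.isnan(reports["15-39"].bias)

    def test_no_estimation_counts_passed_through(self):
        reports = band_report(pairs_from([70.0], [72.0]),
                              no_estimation_counts={"global": 3, ">=65": 3})
        by_scope = {r.scope: r for r in reports}
        assert by_scope["global"].no_estimation_count == 3
        assert by_scope[">=65"].no_estimation_count == 3


def exact_wilcoxon_two_sided(diffs):
    """Oracle: enumerate all sign assignments of the ranked differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = [np.sum([r for r, keep in zip(ranks, signs) if keep])
          for signs in product([False, True], repeat=len(d))]
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


def exact_mannwhitney_two_sided(a, b):
    """Oracle: enumerate all group assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in combinations(range(len(pooled)), n_a):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        us.append(sum(1 for x in ga for y in gb if x > y))
    us = np.asarray(us)
    return min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))


class TestWilcoxonSignedRank:
    def test_identical_samples_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_three_positive_differences_exact(self):
        res = wilcoxon_signed_rank([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.25)
        assert res.p_value == pytest.approx(exact_wilcoxon_two_sided([1, 2, 3]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(1.0, 2.0, size=8)
        d = d[d != 0]
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_wilcoxon_two_sided(d))

    def test_large_shifted_sample_significant_by_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(8.0, 3.0, size=40)
        y = rng.normal(0.0, 3.0, size=40)
        res = wilcoxon_signed_rank(x, y)
        assert "approximation" in res.method
        assert res.p_value < 0.05

    def test_zero_differences_dropped_before_ranking(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 5.0], [1.0, 1.0, 1.0, 1.0])
        assert res.n == (3,)


class TestMannWhitneyU:
    def test_separated_samples_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(
            exact_mannwhitney_two_sided(np.array([1., 2., 3.]),
                                        np.array([4., 5., 6.])))

    def test_swap_symmetry(self):
        a, b = [1.0, 5.0, 9.0, 12.0], [2.0, 3.0, 11.0]
        r1 = mann_whitney_u(a, b)
        r2 = mann_whitney_u(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.statistic == pytest.approx(len(a) * len(b) - r2.statistic)

    def test_identical_samples_u_half_product(self):
        a = [10.0, 20.0, 30.0, 40.0]
        res = mann_whitney_u(a, a)
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value > 0.9

    @pytest.mark.parametrize("seed", [4, 5])
    def test_exact_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=4)
        b = rng.normal(1, 1, size=4)
        res = mann_whitney_u(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_mannwhitney_two_sided(a, b))

    def test_tied_samples_use_corrected_approximation(self):
        res = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert "approximation" in res.method


class TestWeightedKappa:
    def test_perfect_agreement(self):
        res = weighted_kappa([0, 1, 2, 3, 2], [0, 1, 2, 3, 2])
        assert res.kappa == pytest.approx(1.0)
        assert res.label == "almost perfect"

    def test_hand_worked_contingency_table(self):
        # counts {(0,0): 4, (0,1): 1, (1,1): 3, (2,2): 2}, linear weights:
        # sum wO = 0.1, sum wE = 0.82 -> kappa = 1 - 0.1/0.82
        r1 = [0] * 5 + [1] * 3 + [2] * 2
        r2 = [0] * 4 + [1] * 4 + [2] * 2
        res = weighted_kappa(r1, r2, weighting="linear")
        assert res.kappa == pytest.approx(1 - 0.1 / 0.82)

    @pytest.mark.parametrize("weighting", ["linear", "quadratic"])
    def test_agrees_with_sklearn(self, weighting):
        rng = np.random.default_rng(1)
        r1 = rng.integers(0, 5, size=60)
        noise = rng.integers(-1, 2, size=60)
        r2 = np.clip(r1 + noise, 0, 4)
        ours = weighted_kappa(r1, r2, weighting=weighting)
        theirs = cohen_kappa_score(r1, r2, weights=weighting)
        assert ours.kappa == pytest.approx(theirs)

    def test_substantial_band(self):
        assert landis_koch_label(0.70) == "substantial"
        assert landis_koch_label(0.85) == "almost perfect"

    def test_invariant_to_distance_preserving_relabeling(self):
        rng = np.random.default_rng(2)
        r1 = rng.integers(0, 4, size=40)
        r2 = np.clip(r1 + rng.integers(-1, 2, size=40), 0, 3)
        base = weighted_kappa(r1, r2, n_categories=4)
        flipped = weighted_kappa(3 - r1, 3 - r2, n_categories=4)
        assert flipped.kappa == pytest.approx(base.kappa)

    def test_zero_chance_disagreement_flagged(self):
        res = weighted_kappa([1, 1, 1], [1, 1, 1])
        assert res.undefined and np.isnan(res.kappa)


class TestStageTiming:
    def test_mean_age_per_stage(self):
        records = [make_record(0, 40, v1=1), make_record(1, 56, v1=1)]
        rows = {(r.variable, r.stage): r for r in stage_timing_summary(records)}
        row = rows[("v1", 1)]
        assert row.n == 2 and row.mean_age == pytest.approx(48.0)

    def test_stage_counts_partition_records(self):
        rng = np.random.default_rng(3)
        records = [make_record(i, int(rng.integers(20, 90)),
                               v1=int(rng.integers(0, 4))) for i in range(50)]
        rows = [r for r in stage_timing_summary(records) if r.variable == "v1"]
        assert sum(r.n for r in rows) == 50

    def test_singleton_stage_has_nan_sd(self):
        rows = stage_timing_summary([make_record(0, 40, v1=2)])
        assert np.isnan(rows[0].sd)

    def test_compare_flags_shifted_population(self):
        rng = np.random.default_rng(4)
        a = [make_record(i, int(rng.normal(60, 8)), population="A", v1=2)
             for i in range(100)]
        b = [make_record(i, int(rng.normal(52, 8)), population="B", v1=2)
             for i in range(100)]
        frame = compare_stage_timing(a, b)
        row = frame[(frame.variable == "v1") & (frame.stage == 2)].iloc[0]
        assert row.significant
        assert row.mean_a > row.mean_b

    def test_stage_in_one_population_marked_not_applicable(self):
        a = [make_record(0, 40, v1=1)]
        b = [make_record(0, 45, v1=2)]
        frame = compare_stage_timing(a, b)
        solo = frame[(frame.variable == "v1") & (frame.stage == 1)].iloc[0]
        assert "not applicable" in solo.test

    def test_identical_populations_nominal_flag_rate(self):
        # under the null the 0.05-level flag rate stays near nominal
        rng = np.random.default_rng(5)
        flags, total = 0, 0
        for rep in range(30):
            ages_a = rng.integers(30, 80, size=40)
            ages_b = rng.integers(30, 80, size=40)
            a = [make_record(i, int(x), v1=1) for i, x in enumerate(ages_a)]
            b = [make_record(i, int(x), v1=1) for i, x in enumerate(ages_b)]
            frame = compare_stage_timing(a, b)
            flags += int(frame.significant.sum())
            total += len(frame)
        assert flags / total < 0.15


class TestBoxplotSummary:
    def test_odd_symmetric_sample(self):
        records = [make_record(i, a, v1=1) for i, a in
                   enumerate([20, 30, 40, 50, 60])]
        row = boxplot_summary(records).iloc[0]
        assert (row["min"], row["q1"], row["median"], row["q3"], row["max"]) == \
            (20, 30, 40, 50, 60)

    def test_single_record_all_equal(self):
        row = boxplot_summary([make_record(0, 44, v1=1)]).iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == 44

    def test_interpolated_quartiles(self):
        # ages 21..24, linear interpolation: q1 = 21.75, q3 = 23.25
        records = [make_record(i, a, v1=1) for i, a in enumerate([21, 22, 23, 24])]
        row = boxplot_summary(records).iloc[0]
        assert row.q1 == pytest.approx(21.75)
        assert row.q3 == pytest.approx(23.25)
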