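"""Pooled summaries, paired tests, agreement statistics and tertiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hrindex import (assign_tertiles, bland_altman, compare_arm,
                     identity_regression, paired_t, percent_difference,
                     pooled_summary)
from hrindex.errors import (DegenerateDesignError, DomainError,
                            EmptySelectionError, InsufficientDataError,
                            MissingDataError, PairingError)
from hrindex.records import Arm, StudyRecord


def make_point(i, hr_rest, hr_max, vo2, arm=Arm.MEASURED):
    return StudyRecord(study_id=f"p{i}", first_author="A", year=2000, arm=arm,
                       n=100, age_mean=50.0, male_pct=50.0, category="H",
                       protocol="B", hr_rest=hr_rest, hr_max=hr_max,
                       vo2peak=vo2)


class TestPooledSummary:
    def test_hand_example(self):
        mean, sd, count = pooled_summary([2.0, 4.0, 6.0])
        assert (mean, sd, count) == (4.0, 2.0, 3)

    def test_single_value_sd_undefined(self):
        mean, sd, count = pooled_summary([6.51])
        assert mean == 6.51 and math.isnan(sd) and count == 1

    def test_empty_selection(self):
        with pytest.raises(EmptySelectionError):
            pooled_summary([])

    def test_matches_two_pass_oracle(self, rng):
        v = rng.normal(6.5, 2.0, 100)
        mean, sd, _ = pooled_summary(v)
        m = sum(v) / len(v)
        s = math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))
        assert mean == pytest.approx(m, abs=1e-12)
        assert sd == pytest.approx(s, abs=1e-12)

    def test_weighted_matches_oracle(self, rng):
        v = rng.normal(6.5, 2.0, 50)
        w = rng.integers(1, 500, 50).astype(float)
        mean, sd, _ = pooled_summary(v, weights=w)
        m = float((w * v).sum() / w.sum())
        s = math.sqrt(float((w * (v - m) ** 2).sum() / (w.sum() - 1)))
        assert mean == pytest.approx(m, abs=1e-12)
        assert sd == pytest.approx(s, abs=1e-12)


class TestPercentDifference:
    def test_arm_vs_arm_prints_24_7(self):
        assert round(percent_difference(8.12, 6.51), 1) == 24.7

    def test_surrogate_gap_prints_2_6(self):
        assert round(percent_difference(6.71, 6.54), 1) == 2.6

    def test_zero_iff_equal(self):
        assert percent_difference(3.3, 3.3) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(DomainError):
            percent_difference(5.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(min_value=0.1, max_value=30),
           st.floats(min_value=0.1, max_value=30))
    def test_opposite_signs(self, a, b):
        fwd, rev = percent_difference(a, b), percent_difference(b, a)
        if a == b:
            assert fwd == rev == 0.0
        else:
            assert fwd * rev < 0


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p, res.degenerate) == (0.0, 1.0, True)

    def test_constant_shift_is_degenerate_with_p_zero(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p == 0.0 and math.isinf(res.t)

    def test_five_pair_textbook_formula(self):
        a = [6.2, 7.1, 5.9, 8.4, 6.6]
        b = [5.8, 7.3, 5.5, 7.9, 6.1]
        d = [x - y for x, y in zip(a, b)]
        m = sum(d) / 5
        sd = math.sqrt(sum((x - m) ** 2 for x in d) / 4)
        expected_t = m / (sd / math.sqrt(5))
        res = paired_t(a, b)
        assert res.t == pytest.approx(expected_t, abs=1e-10)
        assert res.df == 4

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a = rng.normal(6, 2, n)
            b = a + rng.normal(0.2, 0.5, n)
            res = paired_t(a, b)
            ref = sps.ttest_rel(a, b)
            assert res.t == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([(2.0, 2.0), (3.0, 3.0)])
        assert res.bias == res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        res = bland_altman([(2.5, 2.0), (3.5, 3.0), (4.5, 4.0)])
        assert res.bias == pytest.approx(0.5, abs=1e-12)
        assert res.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_bias_is_brute_force_mean_difference(self, rng):
        a = rng.normal(7, 2, 50)
        b = rng.normal(6.5, 2, 50)
        res = bland_altman(list(zip(a, b)))
        assert res.bias == pytest.approx(float(np.mean(a - b)), abs=1e-12)

    def test_limits_bracket_bias_at_196_sd(self, rng):
        a, b = rng.normal(7, 2, 30), rng.normal(6.5, 2, 30)
        res = bland_altman(list(zip(a, b)))
        assert res.loa_low == pytest.approx(res.bias - 1.96 * res.sd_diff)
        assert res.loa_high == pytest.approx(res.bias + 1.96 * res.sd_diff)
        assert res.loa_low <= res.bias <= res.loa_high

    def test_single_pair_insufficient(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([(1.0, 1.0)])


class TestIdentityRegression:
    def test_exact_identity_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        fit = identity_regression(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.slope_departure == pytest.approx(0.0, abs=1e-12)

    def test_refits_surrogate_relation_on_noiseless_pairs(self):
        hri = np.linspace(1.0, 4.0, 25)
        mets = 6 * hri - 5
        fit = identity_regression(hri, mets)
        assert fit.slope == pytest.approx(6.0, abs=1e-9)
        assert fit.intercept == pytest.approx(-5.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(6.5, 2.0, 60)
        y = 1.1 * x - 0.4 + rng.normal(0, 0.5, 60)
        fit = identity_regression(x, y)
        design = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
        assert fit.slope == pytest.approx(beta[1], abs=1e-9)

    def test_zero_variance_design(self):
        with pytest.raises(DegenerateDesignError):
            identity_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestAssignTertiles:
    def test_even_split(self):
        labels = assign_tertiles([1, 2, 3, 4, 5, 6])
        assert labels.tolist() == [1, 1, 2, 2, 3, 3]

    def test_remainder_to_lowest_first(self):
        labels = assign_tertiles([7, 1, 5, 3, 6, 2, 4])
        counts = np.bincount(labels)[1:]
        assert counts.tolist() == [3, 2, 2]
        assert labels[1] == 1 and labels[5] == 1 and labels[3] == 1

    def test_matches_sort_based_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            v = rng.normal(0, 1, n)
            labels = assign_tertiles(v)
            order = sorted(range(n), key=lambda i: (v[i], i))
            base, rem = divmod(n, 3)
            sizes = [base + (i < rem) for i in range(3)]
            expected = np.empty(n, dtype=int)
            start = 0
            for t, size in enumerate(sizes, start=1):
                for i in order[start:start + size]:
                    expected[i] = t
                start += size
            assert labels.tolist() == expected.tolist()

    def test_tertile_means_nondecreasing(self, rng):
        v = rng.normal(6.5, 2.0, 57)
        labels = assign_tertiles(v)
        means = [v[labels == t].mean() for t in (1, 2, 3)]
        assert means[0] <= means[1] <= means[2]

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            assign_tertiles([1.0, 2.0])


class TestCompareArm:
    def test_null_cohort_small_percent_difference(self, null_cohort):
        result = compare_arm(null_cohort, Arm.MEASURED)
        # no injected bias: pooled difference within Monte Carlo noise
        se = result.comparison.hri_sd / math.sqrt(result.comparison.n_points)
        assert abs(result.comparison.abs_diff) < 2 * se

    def test_biased_cohort_recovers_injected_bias(self, biased_cohort):
        result = compare_arm(biased_cohort, Arm.PREDICTED)
        assert result.comparison.pct_diff == pytest.approx(21.1, abs=3.0)
        assert result.comparison.p_value < 0.001

    def test_bias_equals_mean_difference(self, biased_cohort):
        result = compare_arm(biased_cohort, Arm.PREDICTED)
        c = result.comparison
        assert result.bland_altman.bias == pytest.approx(
            c.tm_mean - c.hri_mean, abs=1e-12)
        assert c.abs_diff == pytest.approx(result.bland_altman.bias, abs=1e-12)

    def test_two_identical_records_degenerate(self):
        recs = [make_point(i, 70.0, 140.0, 7.5) for i in range(2)]
        result = compare_arm(recs, Arm.MEASURED)
        assert result.comparison.degenerate
        assert result.comparison.pct_diff == pytest.approx(
            100 * (7.5 - 7.0) / 7.0)

    def test_missing_data_names_study(self):
        recs = [make_point(0, 70.0, 140.0, 7.0),
                make_point(1, 70.0, 140.0, None)]
        with pytest.raises(MissingDataError) as err:
            compare_arm(recs, Arm.MEASURED)
        assert err.value.study_id == "p1"
        assert err.value.field == "vo2peak"

    def test_reference_switch_flips_comparison(self, biased_cohort):
        hri_ref = compare_arm(biased_cohort, Arm.PREDICTED, reference="hri")
        tm_ref = compare_arm(biased_cohort, Arm.PREDICTED,
                             reference="treadmill")
        assert hri_ref.comparison.pct_diff > 0 > tm_ref.comparison.pct_diff

    def test_pooled_hr_sensitivity_mode_close_to_default(self, biased_cohort):
        per_point = compare_arm(biased_cohort, Arm.PREDICTED)
        pooled = compare_arm(biased_cohort, Arm.PREDICTED,
                             hri_pooling="pooled_hr")
        # the two aggregation conventions agree to within a few percent
        assert pooled.comparison.hri_mean == pytest.approx(
            per_point.comparison.hri_mean, rel=0.05)

    def test_tertile_means_track_reference(self, biased_cohort):
        result = compare_arm(biased_cohort, Arm.PREDICTED)
        hri_means = [row.hri_mean for row in result.tertiles]
        assert hri_means == sorted(hri_means)
        assert [row.tertile for row in result.tertiles] == [1, 2, 3]
        sizes = [row.n_points for row in result.tertiles]
        assert max(sizes) - min(sizes) <= 1
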