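import numpy as np
import pytest
import scipy.stats as sp
from hypothesis import given
from hypothesis import strategies as st

from iolcalc.stats import (
    compare_absolute_errors,
    compare_band_proportions,
    compare_mean_errors,
    friedman_statistic,
    holm_adjust,
    regress_error_on_covariate,
    summarize_errors,
    two_sample_t_test,
)

# Frozen oracles: hand evaluation of the textbook formulas (Welch t and df,
# repeated-measures sums of squares, tie-corrected Friedman ranks, 2x2
# chi-squared O/E sums, Holm step-down) on the toy instances below.
WELCH_T_TOY = -1.224744871391589
WELCH_P_TOY = 0.28786413472669053
RM_ANOVA_TOY = [
    [0.10, 0.30, 0.55],
    [-0.20, 0.00, 0.10],
    [0.05, 0.25, 0.40],
    [0.30, 0.35, 0.70],
    [-0.10, 0.05, 0.15],
    [0.00, 0.20, 0.35],
]
RM_ANOVA_F_TOY = 60.18181818181821
RM_ANOVA_P_TOY = 2.6559363882718486e-06
FRIEDMAN_TOY = [
    [0.10, 0.30, 0.20],
    [0.05, 0.40, 0.25],
    [0.50, 0.10, 0.30],
    [0.15, 0.45, 0.35],
    [0.20, 0.60, 0.40],
]
FRIEDMAN_Q_TOY = 3.6
FRIEDMAN_P_TOY = 0.16529888822158653
FRIEDMAN_TIES_TOY = [
    [0.10, 0.10, 0.30],
    [0.20, 0.40, 0.40],
    [0.50, 0.50, 0.50],
    [0.15, 0.25, 0.35],
    [0.30, 0.10, 0.20],
]
FRIEDMAN_TIES_Q_TOY = 2.7142857142857144
CHI2_2X2_STAT = 20.0
CHI2_2X2_RESID00 = 4.47213595499958


class TestErrorSummary:
    def test_hand_checkable_example(self):
        s = summarize_errors([0.10, -0.30, 0.60, 0.00])
        assert s.mean_pe == pytest.approx(0.10)
        assert s.medae == pytest.approx(0.20)
        assert s.pct_within_025 == 50.0
        assert s.pct_within_050 == 75.0
        assert s.pct_within_100 == 100.0
        assert s.pct_over_plus_050 == 25.0

    def test_all_zero(self):
        s = summarize_errors([0.0, 0.0, 0.0])
        assert (s.mean_pe, s.sd_pe, s.medae) == (0.0, 0.0, 0.0)
        assert s.pct_within_025 == 100.0 and s.pct_over_plus_050 == 0.0

    def test_boundary_is_inclusive_for_band_strict_for_tail(self):
        s = summarize_errors([0.50])
        assert s.pct_within_050 == 100.0
        assert s.pct_over_plus_050 == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_errors([])

    @given(
        pe=st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=40)
    )
    def test_band_nesting_and_tail_complement(self, pe):
        s = summarize_errors(pe)
        assert s.pct_within_025 <= s.pct_within_050 <= s.pct_within_100
        assert 0.0 <= s.pct_over_plus_050 <= 100.0 - s.pct_within_050 + 1e-9


class TestRMANOVA:
    def test_identical_columns_degenerate(self):
        res = compare_mean_errors({"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3]})
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.pairwise[0].p_adjusted == 1.0

    def test_toy_matrix_matches_sums_of_squares_oracle(self):
        mat = np.array(RM_ANOVA_TOY)
        res = compare_mean_errors({m: mat[:, j] for j, m in enumerate("abc")})
        assert res.statistic == pytest.approx(RM_ANOVA_F_TOY, abs=1e-9)
        assert res.p_value == pytest.approx(RM_ANOVA_P_TOY, rel=1e-9)

    def test_constant_offset_pair_flagged(self):
        a = np.arange(10, dtype=float) / 10
        res = compare_mean_errors({"a": a, "b": a + 1.0})
        pair = res.pairwise[0]
        assert pair.p_adjusted <= np.finfo(float).tiny
        assert "degenerate" in pair.note

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            compare_mean_errors({"a": [0.1, 0.2], "b": [0.1]})

    def test_holm_adjusted_pairs_never_below_raw(self):
        rng = np.random.default_rng(0)
        res = compare_mean_errors(
            {m: rng.normal(0.05 * j, 0.3, size=20) for j, m in enumerate("abcd")}
        )
        for pair in res.pairwise:
            assert pair.p_adjusted >= pair.p_raw - 1e-15


class TestFriedman:
    def test_identical_columns(self):
        res = compare_absolute_errors({"a": [0.1, 0.2], "b": [0.1, 0.2], "c": [0.1, 0.2]})
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_no_tie_toy_matches_rank_sum_oracle(self):
        mat = np.array(FRIEDMAN_TOY)
        res = compare_absolute_errors({m: mat[:, j] for j, m in enumerate("abc")})
        assert res.statistic == pytest.approx(FRIEDMAN_Q_TOY, abs=1e-12)
        assert res.p_value == pytest.approx(FRIEDMAN_P_TOY, rel=1e-12)

    def test_tied_toy_uses_midranks(self):
        mat = np.array(FRIEDMAN_TIES_TOY)
        res = compare_absolute_errors({m: mat[:, j] for j, m in enumerate("abc")})
        assert res.statistic == pytest.approx(FRIEDMAN_TIES_Q_TOY, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_scipy_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.normal(size=(12, 4))
        stat, p, _, _ = friedman_statistic(mat)
        ref = sp.friedmanchisquare(*[mat[:, j] for j in range(4)])
        assert stat == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_scheffe_adjusted_not_below_raw(self):
        mat = np.array(FRIEDMAN_TOY)
        res = compare_absolute_errors({m: mat[:, j] for j, m in enumerate("abc")})
        for pair in res.pairwise:
            assert pair.p_adjusted >= pair.p_raw


class TestBandProportions:
    def test_identical_rows_no_association(self):
        res = compare_band_proportions([[30, 10], [30, 10], [30, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.flagged.any()

    def test_2x2_matches_closed_form(self):
        res = compare_band_proportions([[30, 10], [10, 30]])
        assert res.statistic == pytest.approx(CHI2_2X2_STAT, abs=1e-12)
        assert res.residuals[0, 0] == pytest.approx(CHI2_2X2_RESID00, abs=1e-12)
        assert res.flagged[0, 0]

    @pytest.mark.parametrize("seed", [3, 4])
    def test_two_column_rows_have_antisymmetric_residuals(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(5, 60, size=(4, 2))
        res = compare_band_proportions(counts)
        assert np.allclose(res.residuals[:, 0], -res.residuals[:, 1])

    def test_zero_expected_count_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            compare_band_proportions([[5, 0], [7, 0]])


class TestRegression:
    def test_exact_linear_bias_recovered(self):
        rng = np.random.default_rng(1)
        wtw = rng.uniform(10.5, 12.9, size=50)
        pe = 0.1 * (wtw - 11.8)
        res = regress_error_on_covariate(pe, wtw)
        assert res.slope == pytest.approx(0.1, abs=1e-12)
        assert res.zero_crossing == pytest.approx(11.8, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_has_no_association(self):
        rng = np.random.default_rng(12345)
        cov = rng.uniform(10.5, 12.9, size=200)
        pe = rng.normal(0, 0.4, size=200)
        res = regress_error_on_covariate(pe, cov)
        assert res.r_squared < 0.05
        assert res.p_value > 0.05

    def test_identity_regression(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        res = regress_error_on_covariate(x, x)
        assert res.slope == pytest.approx(1.0) and res.intercept == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress_error_on_covariate([0.1, 0.2, 0.3], [11.7, 11.7, 11.7])


class TestWelch:
    def test_identical_samples(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_matches_formula(self):
        res = two_sample_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(WELCH_T_TOY, abs=1e-12)
        assert res.p_value == pytest.approx(WELCH_P_TOY, rel=1e-10)

    def test_degenerate_equal_constants(self):
        res = two_sample_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_shift_increases_statistic_magnitude(self):
        a = [1.0, 2.0, 3.0, 4.0]
        mags = [
            abs(two_sample_t_test(a, [x + shift for x in a]).statistic)
            for shift in (0.5, 1.0, 2.0)
        ]
        assert mags[0] < mags[1] < mags[2]


class TestHolm:
    def test_step_down_example(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == [pytest.approx(0.2)]

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @given(ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    def test_never_below_input_and_permutation_consistent(self, ps):
        adj = holm_adjust(ps)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        perm = list(reversed(ps))
        assert sorted(holm_adjust(perm)) == pytest.approx(sorted(adj))
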