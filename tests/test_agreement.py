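"""Pearson, Bland-Altman, ICC, and correlation-strength categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elbowrom import (
    ValidationError,
    bland_altman,
    icc,
    limits_from_summary,
    pearson,
    strength_category,
)


def anova_oracle(data):
    """Brute-force one-way/two-way sums of squares, written independently
    of the implementation: explicit loops over cells."""
    n, k = data.shape
    grand = sum(data[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(data[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(data[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_within = sum((data[i, j] - row[i]) ** 2 for i in range(n) for j in range(k))
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_err = sum(
        (data[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    bms = ss_rows / (n - 1)
    wms = ss_within / (n * (k - 1))
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return bms, wms, jms, ems


class TestPearson:
    def test_perfect_positive_affine_relation(self):
        x = np.arange(1.0, 8.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.category == "almost perfect"

    def test_perfect_negative_relation(self):
        x = np.arange(1.0, 6.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # deviations (+-1.5, +-0.5) give covariance 4, variances 5 each
        res = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8, abs=1e-12)
        assert res.n == 4

    def test_p_value_matches_t_transform(self):
        from scipy import stats

        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0, 9.0])
        y = np.array([1.2, 1.9, 3.1, 5.5, 6.2, 8.1])
        res = pearson(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p_two_sided == pytest.approx(2 * stats.t.sf(abs(t), res.n - 2), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson([1, 1, 1], [1, 2, 3])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_positive_affine_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = x + rng.normal(scale=0.5, size=10)
        base = pearson(x, y).r
        assert pearson(3.0 * x + 7.0, y).r == pytest.approx(base, abs=1e-12)
        assert pearson(x, 0.25 * y - 2.0).r == pytest.approx(base, abs=1e-12)


class TestBlandAltman:
    def test_identical_arrays_all_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x, x)
        assert res.mean_diff_deg == res.sd_diff_deg == 0.0
        assert res.upper_loa_deg == res.lower_loa_deg == res.half_width_deg == 0.0

    def test_differences_closed_form(self):
        # diffs {-1, 3}: mean 1, sd sqrt(8), half-width 1.96*sqrt(8)
        res = bland_altman([0.0, 3.0], [1.0, 0.0])
        assert res.mean_diff_deg == pytest.approx(1.0)
        assert res.sd_diff_deg == pytest.approx(np.sqrt(8))
        assert res.half_width_deg == pytest.approx(1.96 * np.sqrt(8))
        assert res.half_width_deg == pytest.approx(5.5437, abs=1e-4)

    def test_limits_structure(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 2, 30)
        y = rng.normal(10, 2, 30)
        res = bland_altman(x, y)
        assert res.upper_loa_deg == pytest.approx(res.mean_diff_deg + 1.96 * res.sd_diff_deg)
        assert res.lower_loa_deg == pytest.approx(res.mean_diff_deg - 1.96 * res.sd_diff_deg)
        assert res.upper_loa_deg >= res.lower_loa_deg

    def test_common_shift_moves_mean_not_sd(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = bland_altman(x, y)
        shifted = bland_altman(x + 5.0, y)
        assert shifted.sd_diff_deg == pytest.approx(base.sd_diff_deg)
        assert shifted.mean_diff_deg == pytest.approx(base.mean_diff_deg + 5.0)

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [2.0])


class TestLimitsFromSummary:
    def test_zero_summary_all_zero(self):
        res = limits_from_summary(0.0, 0.0)
        assert res.upper_loa_deg == res.lower_loa_deg == res.half_width_deg == 0.0

    def test_unrounded_arithmetic(self):
        res = limits_from_summary(2.0, 2.8)
        assert res.upper_loa_deg == pytest.approx(7.488)
        assert res.lower_loa_deg == pytest.approx(-3.488)
        assert res.half_width_deg == pytest.approx(5.488)

    def test_larger_sd(self):
        assert limits_from_summary(1.0, 11.2).half_width_deg == pytest.approx(21.952)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            limits_from_summary(0.0, -1.0)


class TestICC:
    def test_identical_columns_give_one_for_every_form(self):
        data = np.array([[1.0, 1, 1], [5, 5, 5], [9, 9, 9], [2, 2, 2]])
        for model in ("oneway", "twoway_random"):
            for unit in ("single", "average"):
                assert icc(data, model=model, unit=unit).estimate == 1.0

    def test_structured_matrix_matches_explicit_anova(self):
        data = np.arange(1.0, 13.0).reshape(4, 3)
        bms, wms, jms, ems = anova_oracle(data)
        expect_single = (bms - wms) / (bms + 2 * wms)
        expect_avg = (bms - wms) / bms
        assert icc(data, "oneway", "single").estimate == pytest.approx(expect_single, abs=1e-12)
        assert icc(data, "oneway", "average").estimate == pytest.approx(expect_avg, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_random_matrices_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(50, 10, size=(4, 3))
        bms, wms, jms, ems = anova_oracle(data)
        n, k = data.shape
        assert icc(data, "oneway", "single").estimate == pytest.approx(
            (bms - wms) / (bms + (k - 1) * wms), abs=1e-12
        )
        assert icc(data, "twoway_random", "single").estimate == pytest.approx(
            (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n), abs=1e-12
        )
        assert icc(data, "twoway_random", "average").estimate == pytest.approx(
            (bms - ems) / (bms + (jms - ems) / n), abs=1e-12
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_average_of_k_at_least_single(self, seed):
        # Spearman-Brown: averaging k measurements can only help
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 1, size=(6, 4)) + rng.normal(0, 2, size=(6, 1))
        for model in ("oneway", "twoway_random"):
            single = icc(data, model, "single").estimate
            avg = icc(data, model, "average").estimate
            if single > 0 and avg > 0:
                assert avg >= single - 1e-12

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        # strong between-target variance: the realistic reliability regime
        data = rng.normal(60, 3, size=(8, 4)) + rng.normal(0, 20, size=(8, 1))
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(8), 4),
                "rater": np.tile(np.arange(4), 8),
                "score": data.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="target", raters="rater", ratings="score")
        ref = ref.set_index("Type")
        cases = {
            "ICC(1,1)": ("oneway", "single"),
            "ICC(1,k)": ("oneway", "average"),
            "ICC(A,1)": ("twoway_random", "single"),
            "ICC(A,k)": ("twoway_random", "average"),
        }
        for label, (model, unit) in cases.items():
            ours = icc(data, model=model, unit=unit)
            assert ours.estimate == pytest.approx(ref.loc[label, "ICC"], abs=1e-9)
            lo, hi = ref.loc[label, "CI95"]  # pingouin rounds its CI to 2 dp
            assert ours.ci95[0] == pytest.approx(lo, abs=1e-2)
            assert ours.ci95[1] == pytest.approx(hi, abs=1e-2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            icc(np.ones((4, 3)))
        with pytest.raises(ValidationError):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValidationError):
            icc(np.array([[1.0, 2.0]]))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1, size=(10, 3)) + rng.normal(0, 3, size=(10, 1))
        for model in ("oneway", "twoway_random"):
            for unit in ("single", "average"):
                res = icc(data, model, unit)
                assert res.ci95[0] <= res.estimate <= res.ci95[1]


class TestStrengthCategory:
    @pytest.mark.parametrize(
        "r, label",
        [
            (0.0, "slight"),
            (0.20, "slight"),  # band edges belong to the lower band
            (0.21, "fair"),
            (0.40, "fair"),
            (0.41, "moderate"),
            (0.56, "moderate"),
            (0.60, "moderate"),
            (0.61, "substantial"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
            (0.999, "almost perfect"),
            (-0.56, "moderate"),  # categorized on |r|
        ],
    )
    def test_band_assignment(self, r, label):
        assert strength_category(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            strength_category(1.1)
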