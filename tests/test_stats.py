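"""Response dichotomisation, group tests, rank correlations and ICC agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata, spearmanr

from dkimri import (
    CohortTable,
    classify_response,
    compare_groups,
    icc_agreement,
    run_cohort_analysis,
    spearman_corr,
)
from dkimri.stats import _exact_spearman_p


def exact_mann_whitney_p(a, b):
    """Enumeration oracle: two-sided exact Mann-Whitney p for tie-free data.

    Enumerates every C(n, n_a) assignment of the pooled values to group A
    and reports 2*min(P(U <= u_obs), P(U >= u_obs)), the convention of the
    exact test.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    u_obs = sum(x > y for x in a for y in b)
    us = []
    for idx in itertools.combinations(range(n), na):
        av = pooled[list(idx)]
        bv = np.delete(pooled, list(idx))
        us.append(sum(x > y for x in av for y in bv))
    us = np.asarray(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def icc_absolute_single_anova(mat):
    """ANOVA-formula oracle for the two-way absolute-agreement single-rater ICC."""
    mat = np.asarray(mat, float)
    n, k = mat.shape
    grand = mat.mean()
    row_m, col_m = mat.mean(axis=1), mat.mean(axis=0)
    msr = k * ((row_m - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_m - grand) ** 2).sum() / (k - 1)
    mse = ((mat - row_m[:, None] - col_m[None, :] + grand) ** 2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "category,expected",
        [
            ("CR", "responder"),
            ("PR", "responder"),
            ("SD", "non-responder"),
            ("PD", "non-responder"),
            ("pr", "responder"),  # case-insensitive
            (None, "unclassified"),
            (float("nan"), "unclassified"),
            ("", "unclassified"),
        ],
    )
    def test_mapping(self, category, expected):
        assert classify_response(category) == expected

    def test_unknown_category_is_error(self):
        with pytest.raises(ValueError, match="unknown RECIST"):
            classify_response("XX")


class TestCompareGroups:
    def test_forced_mann_whitney_separated_triples(self):
        # U = 0; all 20 rank splits enumerable: two-sided P = 2/20
        res = compare_groups([1, 2, 3], [4, 5, 6], test="mann_whitney")
        assert res.test_used == "mann_whitney"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.100, abs=1e-12)

    def test_extreme_shift_5v10_exact_tail(self):
        # a >> b with n=(5,10): both extremes of C(15,5)=3003 splits
        a = np.arange(5) + 1000.0
        b = np.arange(10, dtype=float)
        res = compare_groups(a, b, test="mann_whitney")
        assert res.p_value == pytest.approx(2 / 3003, rel=1e-12)

    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        t_res = compare_groups(vals, vals, test="student_t")
        assert t_res.statistic == 0.0
        assert t_res.p_value == 1.0
        mw_res = compare_groups(vals, vals, test="mann_whitney")
        assert mw_res.p_value >= 0.95  # continuity correction in the tied branch

    def test_gate_consistency(self):
        # the normality gate must route to the t-test iff both groups pass
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = np.exp(rng.normal(0, rng.uniform(0.1, 2.0), 12))
            b = rng.normal(5, 1, 15)
            res = compare_groups(a, b)
            expected_t = res.shapiro_p_a > res.alpha and res.shapiro_p_b > res.alpha
            assert (res.test_used == "student_t") == expected_t

    def test_group_too_small_is_error(self):
        with pytest.raises(ValueError, match="n >= 3"):
            compare_groups([1, 2], [3, 4, 5])

    @pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (5, 6), (5, 7), (6, 6)])
    def test_exact_p_matches_full_enumeration(self, na, nb):
        """Exact Mann-Whitney equals the brute-force enumeration for n <= 12."""
        rng = np.random.default_rng(na * 100 + nb)
        for _ in range(5):
            a = rng.normal(0, 1, na)
            b = rng.normal(0.8, 1, nb)
            res = compare_groups(a, b, test="mann_whitney")
            assert res.p_value == pytest.approx(exact_mann_whitney_p(a, b), rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_label_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1.2, 9)
        r1 = compare_groups(a, b)
        r2 = compare_groups(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)
        assert r1.test_used == r2.test_used


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_corr(x, np.exp(x)).spearman_rho == pytest.approx(1.0)
        assert spearman_corr(x, -x).spearman_rho == pytest.approx(-1.0)

    def test_hand_computed_rank_difference_formula(self):
        # d = (1,-1,1,-1) (ranks of y vs x), sum d^2 = 4: rho = 1 - 24/60
        res = spearman_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.spearman_rho == pytest.approx(0.6)

    def test_rho_equals_pearson_of_midranks(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 5, 30).astype(float)  # plenty of ties
        y = x + rng.integers(0, 3, 30)
        rho = spearman_corr(x, y).spearman_rho
        rx, ry = rankdata(x), rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], rel=1e-12)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            spearman_corr([1, 2, 3], [1, 2])

    def test_exact_permutation_p_small_n(self):
        # n=5 identity: only the 2 perfectly monotone permutations of 120
        # reach |rho| = 1, so the two-sided exact p is 1/60
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = spearman_corr(x, x**3, method="exact")
        assert res.p_value == pytest.approx(2 / 120, rel=1e-12)

    def test_exact_p_matches_direct_enumeration(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=6), rng.normal(size=6)
        rho_obs = spearmanr(x, y).statistic
        count = sum(
            abs(spearmanr(x, perm).statistic) >= abs(rho_obs) - 1e-12
            for perm in itertools.permutations(y)
        )
        import math

        assert _exact_spearman_p(x, y, rho_obs) == pytest.approx(
            count / math.factorial(6), rel=1e-12
        )


class TestICC:
    def test_duplicated_ratings_give_one(self):
        v = np.array([1.0, 2.0, 3.5, 4.0, 5.5, 7.0])
        res = icc_agreement(np.column_stack([v, v]))
        assert res.icc_value == pytest.approx(1.0)

    def test_rater_offset_distinguishes_absolute_from_consistency(self):
        v = np.array([1.0, 2.0, 3.5, 4.0, 5.5, 7.0])
        shifted = np.column_stack([v, v + 50.0])
        absolute = icc_agreement(shifted, model="absolute")
        consistency = icc_agreement(shifted, model="consistency")
        assert absolute.icc_value < 0.1
        assert consistency.icc_value == pytest.approx(1.0)

    def test_matches_anova_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            latent = rng.normal(0, 2, 8)
            mat = np.column_stack(
                [latent + rng.normal(0, 0.5, 8), latent + 0.3 + rng.normal(0, 0.5, 8)]
            )
            res = icc_agreement(mat)
            assert res.icc_value == pytest.approx(icc_absolute_single_anova(mat), abs=1e-6)
            assert res.ci_low <= res.icc_value <= res.ci_high

    def test_null_ratings_have_near_zero_mean_icc(self):
        rng = np.random.default_rng(4)
        vals = [icc_agreement(rng.standard_normal((6, 2))).icc_value for _ in range(400)]
        assert abs(np.mean(vals)) < 0.1

    @pytest.mark.parametrize(
        "mat,msg",
        [
            (np.ones((4, 2)), "5 units"),
            (np.ones((6, 1)), "2 raters"),
            (np.array([[1.0, np.nan]] * 6), "complete"),
        ],
    )
    def test_input_validation(self, mat, msg):
        with pytest.raises(ValueError, match=msg):
            icc_agreement(mat)


def _cohort_frame(n_resp=5, n_nonresp=10, n_uncl=2, histology=True, seed=0):
    rng = np.random.default_rng(seed)
    n = n_resp + n_nonresp + n_uncl
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:02d}" for i in range(n)],
            "response_class": ["responder"] * n_resp
            + ["non-responder"] * n_nonresp
            + ["unclassified"] * n_uncl,
            "k_app_voi": rng.normal(0.6, 0.15, n),
            "d_app_voi": rng.normal(1.5e-3, 3e-4, n),
            "adc_voi": rng.normal(1.3e-3, 2.5e-4, n),
        }
    )
    if histology:
        df["cellularity_cells_per_um2"] = rng.uniform(0.002, 0.01, n)
        df["ki67_percent"] = rng.uniform(10, 80, n)
    return df


class TestRunCohortAnalysis:
    def test_full_study_layout(self):
        report = run_cohort_analysis(CohortTable(_cohort_frame()))
        assert len(report.comparisons) == 3
        assert len(report.correlations) == 6
        # unclassified patients excluded from comparisons, kept for correlations
        assert all(c.n_a + c.n_b == 15 for c in report.comparisons)
        assert all(r.n == 17 for r in report.correlations)

    def test_all_unclassified_skips_comparisons_keeps_correlations(self):
        df = _cohort_frame()
        df["response_class"] = "unclassified"
        report = run_cohort_analysis(CohortTable(df))
        assert report.comparisons == []
        assert len(report.skipped) == 3
        assert len(report.correlations) == 6

    def test_missing_histology_skips_correlations(self):
        report = run_cohort_analysis(CohortTable(_cohort_frame(histology=False)))
        assert report.correlations == []
        assert len(report.skipped) == 6

    def test_report_serialisation_round_trip(self):
        import json

        report = run_cohort_analysis(CohortTable(_cohort_frame()))
        payload = json.loads(report.to_json())
        assert len(payload["comparisons"]) == 3
        frame = report.to_frame()
        assert set(frame["analysis"]) == {"group_comparison", "spearman_correlation"}
        assert "K_app" in report.summary()
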