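"""Tests of the agreement / method-comparison statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chestgait import (bland_altman, classify_agreement, compare_devices,
                       error_metrics, icc_2way_random_absolute, pearson)
from chestgait.agreement import test_retest as retest_reliability
from oracles import brute_bland_altman, brute_icc21, brute_pearson


class TestBlandAltman:
    def test_identical_measurements_collapse_loa_to_zero(self):
        x = np.array([1.0, 1.2, 1.4, 1.1])
        ba = bland_altman(x, x)
        assert ba["bias"] == 0.0
        assert ba["loa_lower"] == 0.0 == ba["loa_upper"]

    def test_symmetric_differences(self):
        ref = np.array([1.0, 1.0, 1.0])
        test = ref + np.array([-0.1, 0.0, 0.1])
        ba = bland_altman(test, ref)
        assert ba["bias"] == pytest.approx(0.0, abs=1e-15)
        assert ba["loa_upper"] == pytest.approx(1.96 * 0.1, rel=1e-12)
        assert ba["loa_lower"] == pytest.approx(-1.96 * 0.1, rel=1e-12)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ref = rng.normal(1.2, 0.2, 20)
            test = ref + rng.normal(-0.05, 0.1, 20)
            ba = bland_altman(test, ref)
            bias, lo, hi = brute_bland_altman(test.tolist(), ref.tolist())
            assert ba["bias"] == pytest.approx(bias, abs=1e-12)
            assert ba["loa_lower"] == pytest.approx(lo, abs=1e-12)
            assert ba["loa_upper"] == pytest.approx(hi, abs=1e-12)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 1.1], [1.0, 1.0])

    def test_bias_ci_contains_bias(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(1, 0.1, 15)
        ba = bland_altman(ref + rng.normal(0, 0.05, 15), ref)
        lo, hi = ba["bias_ci"]
        assert lo <= ba["bias"] <= hi
        assert ba["loa_lower"] <= ba["bias"] <= ba["loa_upper"]


class TestErrorMetrics:
    def test_identical_gives_zeros(self):
        m = error_metrics([1.0, 2.0], [1.0, 2.0])
        assert m == {"bias": 0.0, "mad": 0.0, "mpe": 0.0}

    def test_symmetric_pair(self):
        m = error_metrics([1.1, 0.9], [1.0, 1.0])
        assert m["bias"] == pytest.approx(0.0, abs=1e-15)
        assert m["mad"] == pytest.approx(0.1)
        assert m["mpe"] == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_percent_error(self):
        assert error_metrics([1.2], [1.0])["mpe"] == pytest.approx(20.0)

    def test_zero_reference_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero reference"):
            m = error_metrics([1.2, 1.0], [1.0, 0.0])
        assert m["mpe"] == pytest.approx(20.0)


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.column_stack([[1.0, 2.0, 3.0, 4.0]] * 2)
        icc, lb, ub = icc_2way_random_absolute(x)
        assert icc == 1.0

    def test_matches_brute_force_anova(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.normal(0, 1, (20, 2)) + rng.normal(0, 1, (20, 1))
            icc, _, _ = icc_2way_random_absolute(x)
            assert icc == pytest.approx(brute_icc21(x), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        x = rng.normal(1.2, 0.2, (15, 1)) + rng.normal(0, 0.05, (15, 3))
        icc, lb, ub = icc_2way_random_absolute(x)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 3),
            "rater": np.tile(np.arange(3), 15),
            "score": x.ravel()})
        out = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        ref = out.loc["ICC(A,1)"] if "ICC(A,1)" in out.index else out.loc["ICC2"]
        ci_col = "CI95" if "CI95" in ref.index else "CI95%"
        assert icc == pytest.approx(ref["ICC"], abs=1e-9)
        # pingouin rounds the interval to two decimals
        assert lb == pytest.approx(ref[ci_col][0], abs=0.01)
        assert ub == pytest.approx(ref[ci_col][1], abs=0.01)

    def test_variance_ratio_nine_to_one_approaches_point_nine(self):
        """Columns = subject effect + noise with var ratio 9:1 -> ICC ~ 0.9."""
        rng = np.random.default_rng(4)
        n = 10_000
        subj = rng.normal(0, 3.0, (n, 1))
        x = subj + rng.normal(0, 1.0, (n, 2))
        icc, _, _ = icc_2way_random_absolute(x)
        assert icc == pytest.approx(0.9, abs=0.01)

    def test_anticorrelated_columns_give_negative_icc(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        icc, lb, ub = icc_2way_random_absolute(np.column_stack([a, a[::-1]]))
        assert icc < 0

    def test_incomplete_matrix_rejected(self):
        x = np.array([[1.0, 2.0], [3.0, np.nan], [2.0, 2.0]])
        with pytest.raises(ValueError, match="complete"):
            icc_2way_random_absolute(x)

    @given(scale=st.floats(0.5, 5.0), shift=st.floats(-2.0, 2.0))
    @settings(max_examples=20, deadline=None)
    def test_icc_invariant_to_affine_change_of_units(self, scale, shift):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (12, 2)) + rng.normal(0, 1, (12, 1))
        base, _, _ = icc_2way_random_absolute(x)
        moved, _, _ = icc_2way_random_absolute(scale * x + shift)
        assert moved == pytest.approx(base, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize("icc,label", [
        (0.882, "excellent"),
        (0.430, "moderate"),
        (0.75, "excellent"),
        (0.4, "poor"),
        (0.6, "good"),
        (0.59, "moderate"),
        (0.74, "good"),
        (-0.2, "poor"),
    ])
    def test_benchmark_boundaries(self, icc, label):
        assert classify_agreement(icc) == label


class TestPearson:
    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(2 * x + 1, x)[0] == pytest.approx(1.0)
        assert pearson(-x, x)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 20)
        y = 0.5 * x + rng.normal(0, 1, 20)
        r, _ = pearson(y, x)
        assert r == pytest.approx(brute_pearson(y.tolist(), x.tolist()),
                                  abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestScalingInvariance:
    def test_scaling_both_scales_bias_mad_loa_and_keeps_r(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(1.2, 0.2, 25)
        test = ref + rng.normal(-0.1, 0.05, 25)
        c = 3.7
        ba1, ba2 = bland_altman(test, ref), bland_altman(c * test, c * ref)
        assert ba2["bias"] == pytest.approx(c * ba1["bias"], rel=1e-12)
        assert (ba2["loa_upper"] - ba2["loa_lower"]) == pytest.approx(
            c * (ba1["loa_upper"] - ba1["loa_lower"]), rel=1e-12)
        m1, m2 = error_metrics(test, ref), error_metrics(c * test, c * ref)
        assert m2["mad"] == pytest.approx(c * m1["mad"], rel=1e-12)
        assert m2["mpe"] == pytest.approx(m1["mpe"], rel=1e-12)
        assert pearson(c * test, c * ref)[0] == pytest.approx(
            pearson(test, ref)[0], rel=1e-12)

    def test_constant_shift_preserves_loa_width(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(1.2, 0.2, 25)
        test = ref + rng.normal(0.0, 0.05, 25)
        ba1 = bland_altman(test, ref)
        ba2 = bland_altman(test + 5.0, ref + 5.0)
        assert ba2["bias"] == pytest.approx(ba1["bias"], abs=1e-12)
        assert ba2["loa_upper"] == pytest.approx(ba1["loa_upper"], abs=1e-12)


class TestTestRetest:
    def test_identical_visits(self):
        x = np.array([1.0, 1.2, 1.4, 1.6])
        res = retest_reliability(x, x)
        assert res["icc"] == pytest.approx(1.0, abs=1e-12)
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_correlated_visits_recover_rho(self):
        """Equal-share noise at rho = 0.8 drives ICC toward 0.8."""
        rng = np.random.default_rng(9)
        n = 1000
        rho = 0.8
        z1, z2 = rng.normal(size=(2, n))
        v1 = z1
        v2 = rho * z1 + np.sqrt(1 - rho ** 2) * z2
        res = retest_reliability(v1, v2)
        assert res["icc"] == pytest.approx(rho, abs=0.05)

    def test_independent_visits_near_zero(self):
        rng = np.random.default_rng(10)
        iccs = [retest_reliability(rng.normal(size=50), rng.normal(size=50))["icc"]
                for _ in range(30)]
        assert abs(np.mean(iccs)) < 0.1


class TestPanel:
    def test_compare_devices_bundles_everything(self):
        rng = np.random.default_rng(11)
        ref = rng.normal(1.2, 0.2, 20)
        test = ref + rng.normal(-0.05, 0.05, 20)
        res = compare_devices(test, ref, endpoint="gait_speed_mps")
        assert res.loa_lower <= res.bias <= res.loa_upper
        assert -1 <= res.icc_bounds[0] <= res.icc <= res.icc_bounds[1] <= 1
        assert res.label in {"poor", "moderate", "good", "excellent"}
        row = res.as_row()
        assert row["endpoint"] == "gait_speed_mps" and row["n"] == 20

    def test_missing_pairs_dropped_listwise(self):
        test = np.array([1.0, np.nan, 1.2, 1.1, 0.9])
        ref = np.array([1.0, 1.0, 1.1, np.nan, 1.0])
        with pytest.warns(UserWarning, match="incomplete"):
            ba = bland_altman(test, ref)
        assert ba["n"] == 3
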