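"""Value-curve fitting, local slopes, |s-/s+|, and the 2-SD outlier rule."""

import math
import warnings

import numpy as np
import pytest

from lapref import valuation as val
from lapref.keypress_analysis import CategoryValuation


class TestFitValueCurve:
    def test_linear_exact_recovery(self):
        pts = [(h, 2 * h) for h in (0.5, 1.0, 1.5, 2.0)]
        fit = val.fit_value_curve(pts, form="linear")
        assert fit.params[0] == pytest.approx(2.0)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)
        assert fit.limb == "approach"

    def test_power_exact_recovery_of_quadratic_law(self):
        pts = [(h, h**2) for h in (0.25, 0.5, 1.0, 1.5, 2.0)]
        fit = val.fit_value_curve(pts, form="power")
        a, b = fit.params
        assert a == pytest.approx(1.0, abs=1e-6)
        assert b == pytest.approx(2.0, abs=1e-6)

    def test_quadratic_exact_recovery(self):
        pts = [(h, 3 * h + 0.5 * h**2) for h in (0.5, 1.0, 2.0, 3.0)]
        fit = val.fit_value_curve(pts, form="quadratic")
        assert fit.params[0] == pytest.approx(3.0, abs=1e-8)
        assert fit.params[1] == pytest.approx(0.5, abs=1e-8)

    def test_two_points_linear_interpolates(self):
        fit = val.fit_value_curve([(1.0, 2.0), (2.0, 4.0)], form="linear")
        assert fit.params[0] == pytest.approx(2.0)

    def test_avoidance_limb_sign(self):
        pts = [(h, -2 * h) for h in (0.5, 1.0, 2.0)]
        fit = val.fit_value_curve(pts, form="linear")
        assert fit.limb == "avoidance"
        assert fit.predict(1.0) == pytest.approx(-2.0)

    def test_mixed_signs_rejected(self):
        with pytest.raises(val.UnfittableLimbError):
            val.fit_value_curve([(1.0, 1.0), (2.0, -1.0)])

    def test_identical_H_unfittable_for_power(self):
        with pytest.raises(val.UnfittableLimbError):
            val.fit_value_curve([(1.0, 1.0), (1.0, 2.0)], form="power")

    def test_clustered_H_unfittable_for_power(self):
        # a 0.3% lever arm cannot identify an exponent
        pts = [(2.98, 20.0), (2.985, 19.0), (2.99, 21.0)]
        with pytest.raises(val.UnfittableLimbError):
            val.fit_value_curve(pts, form="power")

    def test_single_point_only_linear(self):
        fit = val.fit_value_curve([(2.0, 6.0)], form="linear")
        assert fit.params[0] == pytest.approx(3.0)
        with pytest.raises(val.UnfittableLimbError):
            val.fit_value_curve([(2.0, 6.0)], form="power")


class TestLocalSlope:
    def test_linear_slope_is_constant(self):
        fit = val.fit_value_curve([(h, 2 * h) for h in (0.5, 1.0, 2.0)], form="linear")
        for frac in (0.05, 0.1, 0.5, 1.0):
            assert val.local_slope(fit, frac) == pytest.approx(2.0)

    def test_power_window_mean_slope_closed_form(self):
        # |K| = H^2 on (0, 1): mean slope over the first 10% window is
        # (0.1^2 - 0) / 0.1 = 0.1
        fit = val.ValueCurveFit(
            limb="approach", form="power", params=(1.0, 2.0),
            h_range=(0.0, 1.0), rms_residual=0.0, n_points=5,
        )
        assert val.local_slope(fit, 0.1) == pytest.approx(0.1)

    def test_avoidance_mirror_is_negative(self):
        fit = val.fit_value_curve([(h, -2 * h) for h in (0.5, 1.0, 2.0)], form="linear")
        assert val.local_slope(fit, 0.1) == pytest.approx(-2.0)

    def test_window_consistency_full_fraction_matches_global_slope(self):
        pts = [(h, 2 * h) for h in (0.5, 1.0, 1.5)]
        fit = val.fit_value_curve(pts, form="linear")
        H = np.array([p[0] for p in pts])
        K = np.array([p[1] for p in pts])
        global_slope = float(np.sum(H * K) / np.sum(H**2))
        assert val.local_slope(fit, 1.0) == pytest.approx(global_slope)

    def test_bad_fraction_rejected(self):
        fit = val.fit_value_curve([(1.0, 2.0), (2.0, 4.0)], form="linear")
        with pytest.raises(ValueError):
            val.local_slope(fit, 0.0)
        with pytest.raises(ValueError):
            val.local_slope(fit, 1.5)


def _linear_fit(slope, limb):
    sign = -1 if limb == "avoidance" else 1
    pts = [(h, sign * slope * h) for h in (0.5, 1.0, 2.0)]
    return val.fit_value_curve(pts, form="linear", limb=limb)


class TestLossAversion:
    def test_ratio_arithmetic(self):
        res = val.loss_aversion(_linear_fit(4.5, "avoidance"), _linear_fit(2.0, "approach"))
        assert res.s_minus == pytest.approx(-4.5)
        assert res.s_plus == pytest.approx(2.0)
        assert res.lam == pytest.approx(2.25)

    def test_mirror_symmetric_limbs_give_unity(self):
        res = val.loss_aversion(_linear_fit(3.0, "avoidance"), _linear_fit(3.0, "approach"))
        assert res.lam == pytest.approx(1.0)

    def test_cohort_scale_ratio(self):
        res = val.loss_aversion(_linear_fit(2.06, "avoidance"), _linear_fit(1.0, "approach"))
        assert res.lam == pytest.approx(2.06)

    def test_zero_approach_slope_yields_infinity_with_warning(self):
        flat = val.ValueCurveFit("approach", "linear", (0.0, 0.0), (0.0, 1.0), 0.0, 2)
        with pytest.warns(UserWarning):
            res = val.loss_aversion(_linear_fit(2.0, "avoidance"), flat)
        assert math.isinf(res.lam)

    def test_limb_roles_enforced(self):
        with pytest.raises(ValueError):
            val.loss_aversion(_linear_fit(2.0, "approach"), _linear_fit(1.0, "approach"))

    @pytest.mark.parametrize("form", ["power", "linear", "quadratic"])
    @pytest.mark.parametrize("c", [0.5, 3.0, 40.0])
    def test_scale_invariance_of_lambda(self, form, c):
        rng = np.random.default_rng(7)
        H = np.array([0.8, 1.5, 2.2, 2.9])
        k_minus = 3.0 * H ** 1.3 * (1 + 0.05 * rng.standard_normal(4))
        k_plus = 1.4 * H ** 1.1 * (1 + 0.05 * rng.standard_normal(4))

        def lam(scale):
            fm = val.fit_value_curve(list(zip(H, -scale * k_minus)), form=form, limb="avoidance")
            fp = val.fit_value_curve(list(zip(H, scale * k_plus)), form=form, limb="approach")
            return val.loss_aversion(fm, fp).lam

        assert lam(c) == pytest.approx(lam(1.0), rel=1e-9)

    @pytest.mark.parametrize("form", ["power", "linear", "quadratic"])
    def test_limb_swap_inverts_lambda(self, form):
        H = np.array([0.8, 1.5, 2.2, 2.9])
        k_minus = 3.0 * H ** 1.3
        k_plus = 1.4 * H ** 1.1
        fm = val.fit_value_curve(list(zip(H, -k_minus)), form=form, limb="avoidance")
        fp = val.fit_value_curve(list(zip(H, k_plus)), form=form, limb="approach")
        lam = val.loss_aversion(fm, fp).lam
        # mirror the data across K = 0 and swap limb roles
        fm2 = val.fit_value_curve(list(zip(H, -k_plus)), form=form, limb="avoidance")
        fp2 = val.fit_value_curve(list(zip(H, k_minus)), form=form, limb="approach")
        lam_swapped = val.loss_aversion(fm2, fp2).lam
        assert lam_swapped == pytest.approx(1.0 / lam, rel=1e-9)


class TestFlagOutliers:
    def test_single_extreme_value_flagged(self):
        values = [2.0] * 9 + [12.0]  # mean 3, sd sqrt(10): only 12 exceeds 2 sd
        flags = val.flag_outliers(values)
        assert flags.tolist() == [False] * 9 + [True]

    def test_constant_cohort_flags_nothing(self):
        assert not val.flag_outliers([2.0, 2.0, 2.0, 2.0]).any()

    def test_moderate_deviation_not_flagged(self):
        # mean 2.8, sd ~4.02: the 10 sits at 1.79 sd
        assert not val.flag_outliers([1.0, 1.0, 1.0, 1.0, 10.0]).any()

    def test_non_finite_always_flagged(self):
        flags = val.flag_outliers([2.0, 2.1, math.inf, 1.9])
        assert flags.tolist() == [False, False, True, False]

    def test_small_cohorts_rejected(self):
        with pytest.raises(ValueError):
            val.flag_outliers([1.0, 2.0])


class TestSubjectLossAversion:
    def _vals(self):
        return [
            CategoryValuation("angry", -20.0, 2.8, "avoidance"),
            CategoryValuation("fearful", -22.0, 2.9, "avoidance"),
            CategoryValuation("sad", -18.0, 2.7, "avoidance"),
            CategoryValuation("happy", 10.0, 2.8, "approach"),
            CategoryValuation("neutral", -0.2, 2.5, "avoidance"),
            CategoryValuation("scrambled", 0.01, 1.0, "neutral"),
        ]

    def test_neutral_and_baseline_categories_never_enter_fits(self):
        res = val.subject_loss_aversion(self._vals(), form="linear", subject_id="s1")
        # slope ratio from the three negative categories vs happy alone
        H = np.array([2.8, 2.9, 2.7])
        K = np.array([20.0, 22.0, 18.0])
        expected = (np.sum(H * K) / np.sum(H**2)) / (10.0 / 2.8)
        assert res.lam == pytest.approx(expected)

    def test_wrong_signed_category_dropped_with_warning(self):
        vals = self._vals()
        vals[0] = CategoryValuation("angry", +5.0, 2.8, "approach")
        with pytest.warns(UserWarning, match="angry"):
            res = val.subject_loss_aversion(vals, subject_id="s1")
        assert np.isfinite(res.lam)

    def test_missing_limb_raises(self):
        only_neg = [v for v in self._vals() if v.category != "happy"]
        with pytest.raises(val.UnfittableLimbError):
            val.subject_loss_aversion(only_neg)
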