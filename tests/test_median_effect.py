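import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combodex.errors import InsufficientDataError
from combodex.median_effect import (
    MedianEffectFit,
    combination_index,
    default_fa_grid,
    dose_for_effect,
    dose_reduction_index,
    effect_at_dose,
    fa_ci_curve,
    fit_median_effect,
    linearize,
)

# frozen hand-OLS oracle values for the packaged single-agent series
# (explicit covariance sums over the 5 linearized points)
Q_ORACLE = {"dm": 96.34945879123397, "m": 0.9224869714485504, "r": 0.9630422942465496}
GEM_ORACLE = {"dm": 4.787231209639356, "m": 0.8382194715046818}
CI_Q80_GEM8_ORACLE = 1.420277972390405
DRI_Q80_GEM8_ORACLE = (2.0475382562570603, 1.073091929903065)

fit_strategy = st.builds(
    lambda dm, m: MedianEffectFit(dm=dm, m=m, r=1.0, n_points=5),
    dm=st.floats(0.1, 1000.0),
    m=st.floats(0.3, 5.0),
)


class TestLinearize:
    def test_fa_half_maps_to_zero_ordinate(self):
        x, y, _ = linearize([3.7, 9.9], [0.5, 0.5])
        assert y == pytest.approx([0.0, 0.0])

    def test_unit_dose_maps_to_zero_abscissa(self):
        x, y, _ = linearize([1.0, 10.0], [0.3, 0.9])
        assert x[0] == pytest.approx(0.0)
        assert x[1] == pytest.approx(1.0)
        assert y[1] == pytest.approx(math.log10(9), abs=1e-12)

    def test_out_of_window_points_reported(self):
        x, y, excluded = linearize([0.0, 1.0, 2.0, 5.0], [0.5, 0.995, 0.3, 0.6])
        assert len(x) == 2
        reasons = dict(excluded)
        assert 0 in reasons and "dose" in reasons[0]
        assert 1 in reasons and "window" in reasons[1]

    def test_fewer_than_two_retained_is_error(self):
        with pytest.raises(InsufficientDataError):
            linearize([1.0, 2.0], [0.5, 0.999])


class TestFitMedianEffect:
    def test_exact_recovery(self):
        doses = np.array([2, 5, 10, 20, 50.0])
        truth = MedianEffectFit(dm=10, m=2, r=1, n_points=5)
        fa = [effect_at_dose(truth, d) for d in doses]
        fit = fit_median_effect(doses, fa)
        assert fit.dm == pytest.approx(10, abs=1e-9)
        assert fit.m == pytest.approx(2, abs=1e-9)
        assert fit.r == pytest.approx(1, abs=1e-9)

    @given(dm=st.floats(0.1, 1000.0), m=st.floats(0.3, 5.0))
    @settings(max_examples=60, deadline=None)
    def test_exact_recovery_property(self, dm, m):
        truth = MedianEffectFit(dm=dm, m=m, r=1, n_points=5)
        doses = dm * np.array([0.3, 0.6, 1.0, 1.8, 3.2])
        fa = [effect_at_dose(truth, d) for d in doses]
        fit = fit_median_effect(doses, fa)
        assert fit.dm == pytest.approx(dm, rel=1e-8)
        assert fit.m == pytest.approx(m, rel=1e-8)

    def test_packaged_q_series_matches_hand_ols(self, q_fit):
        assert q_fit.dm == pytest.approx(Q_ORACLE["dm"], rel=1e-12)
        assert q_fit.m == pytest.approx(Q_ORACLE["m"], rel=1e-12)
        assert q_fit.r == pytest.approx(Q_ORACLE["r"], rel=1e-9)
        assert q_fit.n_points == 5

    def test_packaged_gem_series_matches_hand_ols(self, gem_fit):
        assert gem_fit.dm == pytest.approx(GEM_ORACLE["dm"], rel=1e-12)
        assert gem_fit.m == pytest.approx(GEM_ORACLE["m"], rel=1e-12)

    def test_single_retained_point_is_error(self):
        with pytest.raises(InsufficientDataError):
            fit_median_effect([1.0, 2.0], [0.5, 0.9999])

    def test_negative_slope_flagged_unreliable(self):
        fit = fit_median_effect([1, 2, 4, 8], [0.8, 0.6, 0.4, 0.2])
        assert fit.m < 0
        assert not fit.reliable


class TestEffectDoseTransforms:
    def test_dose_for_half_effect_is_dm(self):
        fit = MedianEffectFit(dm=10, m=1.7, r=1, n_points=5)
        assert dose_for_effect(fit, 0.5) == pytest.approx(10.0)

    def test_linear_slope_nine_fold(self):
        fit = MedianEffectFit(dm=10, m=1, r=1, n_points=5)
        assert dose_for_effect(fit, 0.9) == pytest.approx(90.0)

    def test_effect_at_dose_examples(self):
        fit = MedianEffectFit(dm=10, m=2, r=1, n_points=5)
        assert effect_at_dose(fit, 10.0) == pytest.approx(0.5)
        assert effect_at_dose(fit, 30.0) == pytest.approx(0.9)
        assert effect_at_dose(fit, 1e-9) < 1e-15

    @given(fit=fit_strategy, fa=st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_inverse_consistency(self, fit, fa):
        assert effect_at_dose(fit, dose_for_effect(fit, fa)) == pytest.approx(
            fa, abs=1e-9)

    @pytest.mark.parametrize("fa", [0.0, 1.0])
    def test_degenerate_fa_rejected(self, fa):
        fit = MedianEffectFit(dm=10, m=1, r=1, n_points=5)
        with pytest.raises(ValueError):
            dose_for_effect(fit, fa)


class TestCombinationIndex:
    @given(fit=fit_strategy, fa=st.floats(0.05, 0.95), w=st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_sham_combination_ci_is_one(self, fit, fa, w):
        dx = dose_for_effect(fit, fa)
        res = combination_index(fit, fit, dx * w, dx * (1 - w), fa, alpha=0)
        assert res.ci == pytest.approx(1.0, abs=1e-6)

    def test_alpha_one_adds_product_term(self):
        fit = MedianEffectFit(dm=10, m=1, r=1, n_points=5)
        dx = dose_for_effect(fit, 0.5)
        res = combination_index(fit, fit, dx / 2, dx / 2, 0.5, alpha=1)
        assert res.ci == pytest.approx(1.25)

    def test_packaged_q80_gem8_matches_arithmetic_oracle(self, q_fit, gem_fit):
        res = combination_index(q_fit, gem_fit, 80.0, 8.0, 0.62, alpha=0)
        assert res.ci == pytest.approx(CI_Q80_GEM8_ORACLE, rel=1e-12)
        assert res.classification == "antagonistic"

    @given(fit=fit_strategy, fa=st.floats(0.1, 0.9))
    @settings(max_examples=50, deadline=None)
    def test_alpha_one_never_below_alpha_zero(self, fit, fa):
        dx = dose_for_effect(fit, fa)
        c0 = combination_index(fit, fit, dx / 3, dx / 3, fa, alpha=0).ci
        c1 = combination_index(fit, fit, dx / 3, dx / 3, fa, alpha=1).ci
        assert c1 > c0
        # equality only when one component dose is zero
        c0z = combination_index(fit, fit, dx / 3, 0.0, fa, alpha=0).ci
        c1z = combination_index(fit, fit, dx / 3, 0.0, fa, alpha=1).ci
        assert c1z == pytest.approx(c0z)

    def test_ci_decreasing_in_single_agent_potency(self, q_fit, gem_fit):
        # a more potent single agent (larger Dx needed -> smaller) raises CI
        res = combination_index(q_fit, gem_fit, 80.0, 8.0, 0.62)
        weaker = MedianEffectFit(dm=q_fit.dm * 2, m=q_fit.m, r=1, n_points=5)
        res_weaker = combination_index(weaker, gem_fit, 80.0, 8.0, 0.62)
        assert res_weaker.ci < res.ci


class TestFaCICurve:
    def test_default_grid_spans_printed_range(self):
        grid = default_fa_grid()
        assert grid[0] == pytest.approx(0.25)
        assert grid[-1] == pytest.approx(0.90)
        assert len(grid) == 14

    def test_empty_grid_rejected(self, q_fit, gem_fit):
        with pytest.raises(ValueError):
            fa_ci_curve(q_fit, gem_fit, q_fit, (10, 1), grid=[])

    def test_sham_fixed_ratio_curve_is_flat_one(self, q_fit):
        curve = fa_ci_curve(q_fit, q_fit, q_fit, (3, 7))
        assert np.allclose(curve.ci_values, 1.0, atol=1e-9)
        assert list(curve.fa_values) == pytest.approx(list(default_fa_grid()))


class TestDoseReductionIndex:
    def test_sham_half_split_gives_two(self, q_fit):
        dx = dose_for_effect(q_fit, 0.4)
        res = dose_reduction_index(q_fit, q_fit, dx / 2, dx / 2, 0.4)
        assert res.dri_a == pytest.approx(2.0)
        assert res.dri_b == pytest.approx(2.0)

    def test_full_single_dose_gives_one(self, q_fit, gem_fit):
        dx = dose_for_effect(q_fit, 0.3)
        res = dose_reduction_index(q_fit, gem_fit, dx, 1.0, 0.3)
        assert res.dri_a == pytest.approx(1.0)

    def test_zero_dose_component_is_absent(self, q_fit, gem_fit):
        res = dose_reduction_index(q_fit, gem_fit, 80.0, 0.0, 0.5)
        assert res.dri_b is None
        assert res.dri_a > 0

    def test_packaged_q80_gem8_matches_oracle(self, q_fit, gem_fit):
        res = dose_reduction_index(q_fit, gem_fit, 80.0, 8.0, 0.62)
        assert res.dri_a == pytest.approx(DRI_Q80_GEM8_ORACLE[0], rel=1e-12)
        assert res.dri_b == pytest.approx(DRI_Q80_GEM8_ORACLE[1], rel=1e-12)
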