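"""Closed-form kinetics: curve shape, derivatives, k factor, conversions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctperf import (
    GammaVariateParams,
    InjectionProtocol,
    curve_slope,
    enhancement_from_perfusion,
    evaluate_curve,
    inflection_times,
    k_exact,
    k_linear,
    max_slope,
    perfusion_from_curve_params,
    perfusion_ratio_from_enhancements,
    predict_aortic_peak,
)

ALPHAS = st.floats(min_value=3.0, max_value=15.0)


class TestEvaluateCurve:
    @pytest.mark.parametrize(
        "time, expected",
        [
            (35.0, 100.0),  # dimensionless time 1 pins the peak
            (0.0, 0.0),
            (17.5, 17.581470957133167),  # 100 * 0.5**9 * e**4.5
        ],
    )
    def test_reference_values(self, pancreas_params, time, expected):
        assert evaluate_curve(pancreas_params, time) == pytest.approx(expected, rel=1e-12)

    def test_rejects_negative_and_nonfinite_times(self, pancreas_params):
        with pytest.raises(ValueError, match="times"):
            evaluate_curve(pancreas_params, [-1.0])
        with pytest.raises(ValueError, match="finite"):
            evaluate_curve(pancreas_params, [np.nan])

    @given(y_max=st.floats(1.0, 500.0), t_max=st.floats(5.0, 60.0), alpha=ALPHAS)
    def test_unimodal_with_peak_at_t_max(self, y_max, t_max, alpha):
        p = GammaVariateParams(y_max, t_max, alpha)
        t = np.linspace(0, 4 * t_max, 400)
        y = evaluate_curve(p, t)
        assert evaluate_curve(p, t_max) == pytest.approx(y_max, rel=1e-12)
        assert np.max(y) <= y_max * (1 + 1e-12)
        # single sign change of the finite differences: up then down
        signs = np.sign(np.diff(y[y > y_max * 1e-12]))
        flips = np.count_nonzero(np.diff(signs))
        assert flips <= 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GammaVariateParams(-1.0, 35.0, 9.0)
        with pytest.raises(ValueError):
            GammaVariateParams(100.0, 0.0, 9.0)
        with pytest.raises(ValueError):
            GammaVariateParams(100.0, 35.0, 1.0)


class TestCurveSlope:
    def test_zero_at_peak_and_negative_in_washout(self, pancreas_params):
        assert curve_slope(pancreas_params, 35.0) == 0.0
        assert curve_slope(pancreas_params, 60.0) < 0.0

    def test_matches_finite_differences(self, pancreas_params):
        t = np.linspace(1.0, 70.0, 200)
        h = 1e-6
        fd = (evaluate_curve(pancreas_params, t + h) - evaluate_curve(pancreas_params, t - h)) / (2 * h)
        assert curve_slope(pancreas_params, t) == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_maximal_at_ascending_inflection(self, pancreas_params):
        # slope at t_max*(alpha-sqrt(alpha))/alpha dominates a dense grid
        t_star = 35.0 * (9 - 3) / 9
        grid = np.linspace(0.01, 35.0, 20000)
        assert curve_slope(pancreas_params, t_star) >= np.max(curve_slope(pancreas_params, grid)) - 1e-9

    def test_rejects_negative_time(self, pancreas_params):
        with pytest.raises(ValueError):
            curve_slope(pancreas_params, -0.5)


class TestInflectionAndK:
    @pytest.mark.parametrize(
        "alpha, roots",
        [
            (4.0, (0.5, 1.5)),
            (9.0, (2 / 3, 4 / 3)),
            (3.0, (0.4226497308103742, 1.5773502691896257)),
        ],
    )
    def test_inflection_roots(self, alpha, roots):
        asc, desc = inflection_times(alpha)
        assert asc == pytest.approx(roots[0], abs=1e-9)
        assert desc == pytest.approx(roots[1], abs=1e-9)
        assert 0 < asc < 1

    def test_inflection_rejects_degenerate_alpha(self):
        with pytest.raises(ValueError):
            inflection_times(1.0)

    @pytest.mark.parametrize(
        "alpha, expected",
        [
            (4.0, 1.8472640247326626),  # 4*(0.125-0.0625)*e**2
            (9.0, 2.351119091145881),  # 3*(2/3)**8*e**3
            (3.0, 1.7488071848368176),
        ],
    )
    def test_k_exact_reference_values(self, alpha, expected):
        assert k_exact(alpha) == pytest.approx(expected, rel=1e-12)

    def test_k_exact_monotone_on_clinical_range(self):
        a = np.linspace(3, 15, 200)
        assert np.all(np.diff(k_exact(a)) > 0)

    @pytest.mark.parametrize("alpha, expected", [(9.0, 2.330144), (15.0, 2.88224)])
    def test_k_linear_is_exact_arithmetic(self, alpha, expected):
        assert k_linear(alpha) == pytest.approx(expected, abs=1e-12)

    def test_k_linear_warns_outside_clinical_range(self):
        with pytest.warns(UserWarning, match="calibrated"):
            assert k_linear(0.0) == pytest.approx(1.502)

    @given(alpha=ALPHAS)
    def test_k_linear_tracks_k_exact_within_two_percent(self, alpha):
        assert abs(k_linear(alpha) - k_exact(alpha)) / k_exact(alpha) < 0.02


class TestMaxSlopeAndPerfusion:
    def test_max_slope_values(self, pancreas_params):
        assert max_slope(pancreas_params, "exact") == pytest.approx(6.717483117559659, rel=1e-12)
        assert max_slope(pancreas_params, "linear") == pytest.approx(6.657554285714284, rel=1e-12)
        assert max_slope(GammaVariateParams(0.0, 35.0, 9.0), "exact") == 0.0

    @given(t_max=st.floats(5.0, 60.0), alpha=ALPHAS)
    def test_max_slope_exact_matches_numerical_supremum(self, t_max, alpha):
        p = GammaVariateParams(100.0, t_max, alpha)
        grid = np.linspace(1e-3, t_max, 5000)
        numeric = np.max(curve_slope(p, grid))
        assert max_slope(p, "exact") == pytest.approx(numeric, rel=1e-4)

    def test_perfusion_from_curve_params(self, pancreas_params):
        est = perfusion_from_curve_params(pancreas_params, 350.0, k_mode="linear")
        assert est.method == "gamma_two_phase"
        assert est.perfusion == pytest.approx(0.019021583673469383, rel=1e-12)
        assert est.perfusion_per_min == pytest.approx(1.1412950204081629, rel=1e-12)
        assert est.perfusion == est.max_slope / est.aortic_peak

    def test_perfusion_linear_in_y_max(self, pancreas_params):
        double = GammaVariateParams(200.0, 35.0, 9.0)
        p1 = perfusion_from_curve_params(pancreas_params, 350.0).perfusion
        p2 = perfusion_from_curve_params(double, 350.0).perfusion
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_rejects_nonpositive_aortic_peak(self, pancreas_params):
        with pytest.raises(ValueError, match="aortic_peak"):
            perfusion_from_curve_params(pancreas_params, 0.0)

    @pytest.mark.parametrize(
        "perfusion_per_min, expected_hu",
        [(1.15, 100.76272825484892), (2.5, 219.04940924967158), (0.0, 0.0)],
    )
    def test_enhancement_from_perfusion_worked_examples(self, perfusion_per_min, expected_hu):
        y = enhancement_from_perfusion(perfusion_per_min / 60.0, 350.0, 35.0, 9.0, k_mode="linear")
        assert y == pytest.approx(expected_hu, rel=1e-12, abs=1e-12)

    @given(
        perfusion=st.floats(0.001, 0.1),
        peak=st.floats(100.0, 600.0),
        t_max=st.floats(5.0, 60.0),
        alpha=ALPHAS,
        k_mode=st.sampled_from(["linear", "exact"]),
    )
    def test_perfusion_enhancement_round_trip(self, perfusion, peak, t_max, alpha, k_mode):
        y = enhancement_from_perfusion(perfusion, peak, t_max, alpha, k_mode=k_mode)
        back = perfusion_from_curve_params(
            GammaVariateParams(y, t_max, alpha), peak, k_mode=k_mode
        ).perfusion
        assert back == pytest.approx(perfusion, rel=1e-10)


class TestProtocolAndRatios:
    @pytest.mark.parametrize(
        "protocol, expected",
        [
            (InjectionProtocol(3.2, 350.0, 83.0), 353.27228915662647),
            (InjectionProtocol(0.0, 350.0, 83.0), 0.0),
            (InjectionProtocol(5.0, 350.0, 83.33), 549.8019920796831),
        ],
    )
    def test_predicted_aortic_peak(self, protocol, expected):
        assert predict_aortic_peak(protocol) == pytest.approx(expected, rel=1e-12)

    def test_protocol_rejects_nonpositive_cardiac_output(self):
        with pytest.raises(ValueError, match="cardiac_output"):
            InjectionProtocol(3.2, 350.0, 0.0)

    @pytest.mark.parametrize("y1, y2, expected", [(100, 100, 1.0), (220, 100, 2.2)])
    def test_enhancement_ratio_arithmetic(self, y1, y2, expected):
        assert perfusion_ratio_from_enhancements(y1, y2) == pytest.approx(expected)

    def test_enhancement_ratio_rejects_zero_denominator(self):
        with pytest.raises(ValueError):
            perfusion_ratio_from_enhancements(100.0, 0.0)

    @given(y1=st.floats(1.0, 400.0), y2=st.floats(1.0, 400.0), alpha=ALPHAS)
    def test_ratio_equals_perfusion_ratio_for_shared_input(self, y1, y2, alpha):
        # two organs sharing aortic peak, t_max and bolus shape
        peak, t_max = 350.0, 35.0
        p1 = perfusion_from_curve_params(GammaVariateParams(y1, t_max, alpha), peak).perfusion
        p2 = perfusion_from_curve_params(GammaVariateParams(y2, t_max, alpha), peak).perfusion
        assert perfusion_ratio_from_enhancements(y1, y2) == pytest.approx(p1 / p2, rel=1e-12)
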