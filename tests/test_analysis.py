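import numpy as np
import pytest

from lsoloop import (
    delta_sigma,
    equal_activation_ild,
    sensitivity,
    steady_state,
    temporal_slices,
    tt90,
)
from lsoloop.analysis import build_response_curve


T = np.linspace(0.0, 1.0, 20001)


class TestSteadyState:
    def test_constant_trace(self):
        assert steady_state(np.full_like(T, 0.37), T, 0.1) == pytest.approx(0.37)

    def test_ramp_mean_over_last_tenth(self):
        assert steady_state(T, T, 0.1) == pytest.approx(0.95, abs=1e-4)

    def test_decaying_oscillation_close_to_baseline(self):
        eps = 1e-3
        trace = 0.6 + eps * np.exp(-10 * T) * np.sin(200 * np.pi * T)
        assert abs(steady_state(trace, T, 0.1) - 0.6) < eps

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            steady_state(T, T, 2.0)

    def test_invariant_to_resampling(self):
        t_coarse = np.linspace(0.0, 1.0, 4001)
        trace_fine = 0.42 + np.exp(-T / 0.01)
        trace_coarse = 0.42 + np.exp(-t_coarse / 0.01)
        a = steady_state(trace_fine, T, 0.1)
        b = steady_state(trace_coarse, t_coarse, 0.1)
        assert a == pytest.approx(b, abs=1e-6)


class TestDeltaSigma:
    def test_identical_curves_give_zero(self):
        c = np.linspace(0, 1, 5)
        np.testing.assert_array_equal(delta_sigma(c, c), np.zeros(5))

    def test_swap_flips_sign(self):
        left, right = np.array([0.1, 0.4]), np.array([0.3, 0.2])
        np.testing.assert_allclose(delta_sigma(left, right), -delta_sigma(right, left))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delta_sigma(np.zeros(3), np.zeros(4))


class TestTT90:
    def test_linear_ramp(self):
        assert tt90(T, T) == pytest.approx(0.9, abs=1e-6)

    def test_step(self):
        trace = (T >= 0.3).astype(float)
        assert tt90(trace, T) == pytest.approx(0.3, abs=1e-4)

    def test_constant_trace_returns_onset(self):
        assert tt90(np.full_like(T, 0.5), T) == 0.0

    def test_overshoot_crossing_before_peak(self):
        # rises to a transient peak at t = 0.1 then settles at 0.6
        trace = np.where(T < 0.1, 10 * T, 0.6 + 0.4 * np.exp(-(T - 0.1) / 0.05))
        assert tt90(trace, T) < 0.1

    def test_invariant_under_positive_rescaling(self):
        trace = np.minimum(T * 2, 1.0) * (1 + 0.1 * np.sin(40 * T))
        assert tt90(5.0 * trace, T) == pytest.approx(tt90(trace, T), rel=1e-12)


class TestTemporalSlices:
    def test_constant(self):
        np.testing.assert_allclose(
            temporal_slices(np.full_like(T, 0.2), T, 0.1), np.full(10, 0.2)
        )

    def test_slice_count(self):
        assert temporal_slices(T, T, 0.1).size == 10

    def test_ramp_slice_means_increase_linearly(self):
        means = temporal_slices(T, T, 0.1)
        np.testing.assert_allclose(np.diff(means), 0.1, atol=1e-4)

    def test_trailing_partial_window_dropped(self):
        t = np.linspace(0.0, 0.95, 951)
        assert temporal_slices(t, t, 0.1).size == 9

    def test_dt_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            temporal_slices(T, T, 2.0)


class TestSensitivity:
    def test_linear_curve_exact(self):
        ild = np.linspace(-1, 1, 11)
        np.testing.assert_allclose(sensitivity(ild, 0.3 * ild + 0.1), 0.3, atol=1e-12)

    def test_constant_curve_zero(self):
        ild = np.linspace(-1, 1, 9)
        np.testing.assert_array_equal(sensitivity(ild, np.ones(9)), np.zeros(9))

    def test_logistic_curve_matches_analytic_derivative(self):
        ild = np.linspace(-1, 1, 201)
        k, x0 = 8.0, 0.2
        sig = 1 / (1 + np.exp(-k * (ild - x0)))
        dsig = sensitivity(ild, sig)
        analytic = k * sig * (1 - sig)
        np.testing.assert_allclose(dsig[1:-1], analytic[1:-1], rtol=2e-3)
        assert ild[np.argmax(dsig)] == pytest.approx(x0, abs=0.02)

    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError):
            sensitivity(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            sensitivity(np.array([0.0, 0.1, 0.5]), np.zeros(3))
        with pytest.raises(ValueError):
            sensitivity(np.array([0.0, -0.1, -0.2]), np.zeros(3))

    def test_difference_curve_sensitivity_is_linear(self):
        ild = np.linspace(-1, 1, 21)
        left = 1 / (1 + np.exp(5 * ild))
        right = 1 / (1 + np.exp(-5 * ild))
        np.testing.assert_allclose(
            sensitivity(ild, right - left),
            sensitivity(ild, right) - sensitivity(ild, left),
            atol=1e-12,
        )


class TestResponseCurve:
    def test_assembly_and_crossing(self):
        ild = np.linspace(-1, 1, 9)
        t = np.linspace(0, 1, 2001)
        right = 1 / (1 + np.exp(-6 * ild))
        left = right[::-1]
        traces_l = np.tile(left, (t.size, 1))
        traces_r = np.tile(right, (t.size, 1))
        curve = build_response_curve(ild, t, traces_l, traces_r)
        np.testing.assert_allclose(curve.sigma_eq[0], left)
        np.testing.assert_allclose(curve.delta_sigma_eq, right - left)
        assert curve.slices.shape == (2, 10, 9)
        assert equal_activation_ild(curve) == pytest.approx(0.0, abs=1e-12)
        frame = curve.to_frame()
        assert set(frame.columns) == {"ild", "side", "sigma_eq", "tt90", "sensitivity"}
        assert len(frame) == 18

    def test_no_crossing_rejected(self):
        ild = np.linspace(-1, 1, 5)
        t = np.linspace(0, 1, 101)
        low = np.tile(np.full(5, 0.1), (t.size, 1))
        high = np.tile(np.full(5, 0.9), (t.size, 1))
        curve = build_response_curve(ild, t, low, high)
        with pytest.raises(ValueError):
            equal_activation_ild(curve)
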