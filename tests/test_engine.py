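import numpy as np
import pytest

from lsoloop import (
    CONFIGURATIONS,
    StimulusSpec,
    SystemSpec,
    efferent_gains,
    envelope_rhs,
    equal_activation_ild,
    ild_stimulus,
    ild_sweep,
    initialize,
    lso_rate,
    lso_rhs,
    make_surrogate_sensors,
    mntb_rate,
    mntb_rhs,
    run_closed_loop,
    run_open_loop_table,
    sensor_rhs,
)
from lsoloop import _kernels
from lsoloop.engine import SweepError, closed_form_initial_state


@pytest.fixture(scope="module")
def spec():
    return SystemSpec.symmetric()


def _reference_rhs(t, y, spec, stim):
    """Compose the closed-loop derivative from the public module functions."""
    n = spec.neural
    sig_l, sig_r = lso_rate(y[11], n), lso_rate(y[13], n)
    a_l, _ = efferent_gains(sig_l, sig_r, spec.feedback, spec.sensor_left.a_f_crit)
    _, a_r = efferent_gains(sig_l, sig_r, spec.feedback, spec.sensor_right.a_f_crit)
    f_l, f_r = ild_stimulus(stim, t)
    dy = np.empty(14)
    dy[0:4] = sensor_rhs(y[0:4], a_l, f_l, spec.sensor_left)
    dy[4] = envelope_rhs(y[4], y[3], spec.sensor_left.tau_lpf)
    dy[5:9] = sensor_rhs(y[5:9], a_r, f_r, spec.sensor_right)
    dy[9] = envelope_rhs(y[9], y[8], spec.sensor_right.tau_lpf)
    dy[10] = mntb_rhs(y[10], y[9], n)  # contralateral relay
    dy[11] = lso_rhs(y[11], y[4], mntb_rate(y[10]), n)
    dy[12] = mntb_rhs(y[12], y[4], n)
    dy[13] = lso_rhs(y[13], y[9], mntb_rate(y[12]), n)
    return dy


@pytest.mark.parametrize("config", sorted(CONFIGURATIONS))
def test_kernel_matches_module_composition(spec, config, rng):
    """The compiled 14-state RHS equals the composition of the sensor,
    envelope, neuron, feedback and stimulus module functions."""
    s = spec.with_(feedback=CONFIGURATIONS[config])
    stim = StimulusSpec(ild=0.35)
    a_l, a_r = stim.amplitudes
    p = _kernels.pack_closed_loop(
        s.sensor_left, s.sensor_right, s.neural, s.feedback,
        a_l, a_r, stim.omega, True,
    )
    for _ in range(5):
        y = rng.normal(scale=[1e-6, 1e-3, 1.0, 0.5, 0.5, 1e-6, 1e-3, 1.0, 0.5, 0.5,
                              50.0, 0.3, 50.0, 0.3])
        y[4], y[9] = abs(y[4]), abs(y[9])
        t = rng.uniform(0.0, 1e-3)
        np.testing.assert_allclose(
            _kernels.closed_loop_rhs(t, y, p),
            _reference_rhs(t, y, s, stim),
            rtol=1e-12, atol=1e-12,
        )


def test_analytic_jacobian_matches_finite_differences(spec, rng):
    s = spec.with_(feedback=CONFIGURATIONS["contra_neg"])
    p = _kernels.pack_closed_loop(
        s.sensor_left, s.sensor_right, s.neural, s.feedback, 0.4, 0.6,
        2e3 * np.pi, True,
    )
    # a state away from the |u_ac| and rectifier kinks and the sigma clamp
    y = np.array([1e-7, 1e-4, 0.7, 0.05, 0.1, -2e-7, -2e-4, 0.8, 0.08, 0.2,
                  10.0, 0.1, 20.0, -0.1])
    J = _kernels.closed_loop_jac(0.3, y, p)
    eps = 1e-8
    f0 = _kernels.closed_loop_rhs(0.3, y, p)
    for k in range(14):
        yp = y.copy()
        yp[k] += eps * max(1.0, abs(y[k]))
        fd = (_kernels.closed_loop_rhs(0.3, yp, p) - f0) / (eps * max(1.0, abs(y[k])))
        np.testing.assert_allclose(J[:, k], fd, rtol=5e-5, atol=1e-2)


class TestInitialization:
    def test_matches_closed_form_equilibrium(self, spec):
        y0 = initialize(spec)
        expected = closed_form_initial_state(spec)
        assert np.max(np.abs(y0 - expected)) < 1e-6
        assert y0[2] == pytest.approx(0.7152580, rel=1e-5)  # theta_eq, K
        assert y0[0] == pytest.approx(3.4786e-7, rel=1e-4)  # x_eq, m

    def test_independent_of_baseline_gain_and_deterministic(self, spec):
        y_a = initialize(spec.with_(feedback=spec.feedback.with_(k_a_const=0.1)))
        y_b = initialize(spec.with_(feedback=spec.feedback.with_(k_a_const=0.5)))
        assert np.max(np.abs(y_a - y_b)) < 1e-9
        np.testing.assert_array_equal(y_a, initialize(
            spec.with_(feedback=spec.feedback.with_(k_a_const=0.1))))
        # near the clamp the 2 s settling leaves a larger (reported) residual
        # but still converges onto the same quiescent state
        y_c = initialize(spec.with_(feedback=spec.feedback.with_(k_a_const=0.8)))
        assert np.max(np.abs(y_c - y_a)) < 1e-4


class TestClosedLoop:
    def test_zero_ild_is_left_right_symmetric(self, spec):
        s = spec.with_(feedback=CONFIGURATIONS["ipsi_pos"])
        res = run_closed_loop(s, StimulusSpec(ild=0.0, duration=0.3))
        assert np.max(np.abs(res.sigma[0] - res.sigma[1])) < 1e-6

    def test_constant_gain_trace_without_efferent_feedback(self, spec):
        res = run_closed_loop(spec, StimulusSpec(ild=0.4, duration=0.2))
        expected = spec.feedback.k_a_const * spec.sensor_left.a_f_crit
        assert np.all(res.a_f == expected)

    def test_traces_cover_requested_duration_at_sample_rate(self, spec):
        res = run_closed_loop(spec, StimulusSpec(ild=0.0, duration=0.2))
        assert res.t[0] == 0.0
        assert res.t[-1] == pytest.approx(0.2)
        assert np.allclose(np.diff(res.t), spec.solver.sample_dt)
        assert res.x is not None and res.x.shape == res.sigma.shape

    def test_solver_tolerance_independence(self, spec):
        """Tightening tolerances tenfold leaves the steady-state response
        unchanged to 1e-4."""
        from lsoloop import steady_state

        s = spec.with_(feedback=CONFIGURATIONS["ipsi_pos"])
        stim = StimulusSpec(ild=0.7, duration=0.5)
        res = run_closed_loop(s, stim)
        tight = s.with_(solver=s.solver.with_(rtol=1e-7, atol=1e-10))
        res_t = run_closed_loop(tight, stim)
        for k in (0, 1):
            a = steady_state(res.sigma[k], res.t, 0.1)
            b = steady_state(res_t.sigma[k], res_t.t, 0.1)
            assert a == pytest.approx(b, abs=1e-4)

    def test_wrong_mode_rejected(self, spec):
        with pytest.raises(ValueError):
            run_closed_loop(spec.with_(mode="open_loop_table"), StimulusSpec())


class TestSweep:
    def test_symmetric_sweep_balanced_at_zero(self, spec):
        grid = np.array([-1.0, 0.0, 1.0])
        curve = ild_sweep(spec, grid, StimulusSpec(duration=0.3), window=0.1)
        assert abs(curve.delta_sigma_eq[1]) < 1e-3

    def test_grid_order_irrelevant(self, spec):
        grid = np.array([-0.8, 0.0, 0.8])
        stim = StimulusSpec(duration=0.2)
        fwd = ild_sweep(spec, grid, stim, window=0.1)
        rev = ild_sweep(spec, grid[::-1], stim, window=0.1)
        np.testing.assert_array_equal(fwd.sigma_eq, rev.sigma_eq)
        np.testing.assert_array_equal(fwd.ild, rev.ild)

    def test_failures_identify_offending_ild(self, spec):
        with pytest.raises(SweepError) as err:
            ild_sweep(spec, [0.0, 1.5], StimulusSpec(duration=0.2), window=0.1)
        assert err.value.failures[0][0] == 1.5


@pytest.fixture(scope="module")
def open_spec(neural_open):
    return SystemSpec.symmetric(neural=neural_open).with_(mode="open_loop_table")


class TestOpenLoopTable:
    GRID = np.linspace(-1, 1, 11)
    STIM = StimulusSpec(duration=0.6)

    def test_matched_sensors_cross_at_zero(self, open_spec):
        table = make_surrogate_sensors(mismatch=0.0)
        curve = ild_sweep(open_spec, self.GRID, self.STIM, window=0.333,
                          slice_dt=0.1, table=table, k_a=(0.4, 0.4))
        assert equal_activation_ild(curve) == pytest.approx(0.0, abs=0.02)

    def test_stronger_right_feedback_shifts_crossing_negative(self, open_spec):
        table = make_surrogate_sensors(mismatch=0.0)
        base = ild_sweep(open_spec, self.GRID, self.STIM, window=0.333,
                         slice_dt=0.1, table=table, k_a=(0.4, 0.4))
        boosted = ild_sweep(open_spec, self.GRID, self.STIM, window=0.333,
                            slice_dt=0.1, table=table, k_a=(0.4, 0.8))
        assert equal_activation_ild(boosted) < equal_activation_ild(base) - 0.05

    def test_sensor_mismatch_moves_crossing_off_center(self, open_spec):
        table = make_surrogate_sensors(mismatch=0.3)
        curve = ild_sweep(open_spec, self.GRID, self.STIM, window=0.333,
                          slice_dt=0.1, table=table, k_a=(0.4, 0.4))
        assert abs(equal_activation_ild(curve)) > 0.05
        res = run_open_loop_table(open_spec, table, 0.4, 0.4, 0.0,
                                  StimulusSpec(duration=0.1))
        assert res.x is None  # sensor states are not dynamical in this mode
        assert res.sigma.shape[0] == 2
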