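"""Assembly and integration of the full binaural closed-loop system.

The closed loop couples 14 states: five per sensor channel (deflection,
velocity, temperature, high-pass readout, envelope) and a membrane
potential for each of the two MNTB and two LSO neurons.  The efferent
gains enter the right-hand side algebraically from the instantaneous LSO
rates — there is no synaptic delay and no discrete update step.

Runs follow the two-phase protocol: a 2 s stimulus-free initialization
with constant gains settles the system onto its quiescent equilibrium;
the main run then switches on the chosen feedback configuration together
with the stimulus at t = 0.

Integration uses a stiff multistep solver (LSODA with an analytic
Jacobian) at rtol 1e-6 / atol 1e-9; traces are sampled onto a uniform
grid (default 50 us) by dense-output interpolation so that the analysis
windows do not depend on the solver's internal steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels, analysis
from .feedback import FeedbackConfig, efferent_gains
from .neurons import NeuralParams, lso_rate, mntb_rate
from .sensor import CantileverParams, equilibrium
from .stimulus import StimulusSpec, SurrogateSensorTable, envelope_from_table

__all__ = [
    "SolverSettings",
    "SystemSpec",
    "SimResult",
    "SimulationError",
    "InitializationError",
    "SweepError",
    "initialize",
    "run_closed_loop",
    "run_open_loop_table",
    "run_single_sensor",
    "ild_sweep",
]

# abort thresholds for physically unbounded trajectories
_X_BOUND = 1.0e-2  # m; four orders above the nm-scale operating deflection
_R_BOUND = 100.0  # V; membrane potentials live in [-gamma_r/kappa_r, beta_r]


class SimulationError(RuntimeError):
    """Solver failure or unbounded state during a run."""


class InitializationError(RuntimeError):
    """Initialization did not converge to the quiescent equilibrium."""


class SweepError(RuntimeError):
    """One or more ILD grid points failed; carries per-point diagnostics."""

    def __init__(self, failures):
        self.failures = failures
        super().__init__(
            "; ".join(f"ild={ild}: {err}" for ild, err in failures)
        )


@dataclass(frozen=True)
class SolverSettings:
    method: str = "LSODA"
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    max_step: float = np.inf
    sample_dt: float = 50.0e-6  # uniform output grid spacing, s

    def with_(self, **kwargs) -> "SolverSettings":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SystemSpec:
    """Full binaural system: two sensors, shared neural parameters, one
    feedback configuration, and solver settings."""

    sensor_left: CantileverParams
    sensor_right: CantileverParams
    neural: NeuralParams
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    mode: str = "closed_loop"
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        if self.mode not in ("closed_loop", "open_loop_table"):
            raise ValueError("mode must be 'closed_loop' or 'open_loop_table'")

    @classmethod
    def symmetric(
        cls,
        sensor: Optional[CantileverParams] = None,
        neural: Optional[NeuralParams] = None,
        feedback: Optional[FeedbackConfig] = None,
        **kwargs,
    ) -> "SystemSpec":
        """Identical sensor parameters on both sides (the default study
        condition of the closed-loop experiments)."""
        sensor = sensor if sensor is not None else CantileverParams()
        neural = neural if neural is not None else NeuralParams(
            w_mntb_exc=200.0, w_lso_exc=100.0
        )
        feedback = feedback if feedback is not None else FeedbackConfig()
        return cls(
            sensor_left=sensor, sensor_right=sensor, neural=neural,
            feedback=feedback, **kwargs,
        )

    def with_(self, **kwargs) -> "SystemSpec":
        return replace(self, **kwargs)


@dataclass
class SimResult:
    """Uniformly sampled traces of one run.

    Per-side arrays have shape (2, n) with row 0 = left, row 1 = right.
    Sensor-state arrays are ``None`` in the table-driven open-loop mode,
    where only envelopes and neurons are dynamical (6 states).
    """

    t: np.ndarray
    u_env: np.ndarray
    q: np.ndarray
    r: np.ndarray
    sigma: np.ndarray
    g_q: np.ndarray
    a_f: np.ndarray
    x: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    theta: Optional[np.ndarray] = None
    u_ac: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format traces: one row per (time, side)."""
        frames = []
        for k, side in enumerate(("left", "right")):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.t,
                        "side": side,
                        "u_env": self.u_env[k],
                        "q": self.q[k],
                        "g_q": self.g_q[k],
                        "r": self.r[k],
                        "sigma": self.sigma[k],
                        "a_f": self.a_f[k],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _solve(rhs, jac, t_span, y0, p, solver: SolverSettings, t_eval):
    kwargs = dict(
        method=solver.method,
        rtol=solver.rtol,
        atol=solver.atol,
        max_step=solver.max_step,
        t_eval=t_eval,
        args=(p,),
    )
    if jac is not None and solver.method in ("LSODA", "BDF", "Radau"):
        kwargs["jac"] = jac
    sol = solve_ivp(rhs, t_span, y0, **kwargs)
    if not sol.success:
        raise SimulationError(f"solver failed: {sol.message}")
    return sol


def _closed_loop_params(spec: SystemSpec, stim: Optional[StimulusSpec], stim_on: bool):
    if stim is None:
        amp_l = amp_r = omega = 0.0
    else:
        amp_l, amp_r = stim.amplitudes
        omega = stim.omega
    return _kernels.pack_closed_loop(
        spec.sensor_left, spec.sensor_right, spec.neural, spec.feedback,
        amp_l, amp_r, omega, stim_on,
    )


def closed_form_initial_state(spec: SystemSpec) -> np.ndarray:
    """Analytic quiescent state: each sensor at its thermal/mechanical
    equilibrium with zero readout and envelope, neurons at rest."""
    y = np.zeros(_kernels.CLOSED_LOOP_STATES)
    for k, sensor in enumerate((spec.sensor_left, spec.sensor_right)):
        eq = equilibrium(sensor)
        y[5 * k : 5 * k + 5] = eq.as_array()
    return y


def initialize(spec: SystemSpec, duration: float = 2.0) -> np.ndarray:
    """Settle the system for ``duration`` seconds without stimulus.

    The efferent coupling is replaced by the constant baseline gain
    ``k_a_const * a_f_crit`` on both sides (open-loop initialization), so
    the system relaxes onto its quiescent equilibrium.  The result is
    checked against the closed-form equilibrium to 1e-6 absolute per
    state and against a small residual derivative norm.
    """
    fb_const = spec.feedback.with_(topology="none")
    p = _kernels.pack_closed_loop(
        spec.sensor_left, spec.sensor_right, spec.neural, fb_const,
        0.0, 0.0, 0.0, False,
    )
    y_start = np.zeros(_kernels.CLOSED_LOOP_STATES)
    sol = _solve(
        _kernels.closed_loop_rhs, _kernels.closed_loop_jac,
        (0.0, duration), y_start, p, spec.solver, t_eval=[duration],
    )
    y_final = sol.y[:, -1]
    expected = closed_form_initial_state(spec)
    # the neural states amplify any residual envelope by the input weights,
    # so their convergence tolerance scales with the linearized gains
    n = spec.neural
    q_gain = max(1.0, n.beta_q * n.w_mntb_exc / n.alpha_q)
    r_gain = max(1.0, n.beta_r * n.w_lso_exc + n.gamma_r * q_gain)
    tol = np.full(_kernels.CLOSED_LOOP_STATES, 1e-6)
    tol[[10, 12]] *= q_gain
    tol[[11, 13]] *= r_gain
    if np.any(np.abs(y_final - expected) > tol):
        raise InitializationError(
            f"initialization did not reach the quiescent equilibrium: "
            f"max deviation {np.max(np.abs(y_final - expected)):.3e}"
        )
    resid = np.max(np.abs(_kernels.closed_loop_rhs(duration, y_final, p)))
    if resid > 1e-3:
        raise InitializationError(f"residual derivative norm {resid:.3e} too large")
    return y_final


def _unpack_closed(spec: SystemSpec, sol, stim: Optional[StimulusSpec]) -> SimResult:
    y = sol.y
    t = sol.t
    x = np.stack([y[0], y[5]])
    v = np.stack([y[1], y[6]])
    theta = np.stack([y[2], y[7]])
    u_ac = np.stack([y[3], y[8]])
    u_env = np.stack([y[4], y[9]])
    q = np.stack([y[10], y[12]])
    r = np.stack([y[11], y[13]])
    if np.max(np.abs(x)) > _X_BOUND or np.max(np.abs(r)) > _R_BOUND:
        raise SimulationError(
            f"unbounded state: max|x|={np.max(np.abs(x)):.3e} m, "
            f"max|r|={np.max(np.abs(r)):.3e} V"
        )
    sigma = lso_rate(r, spec.neural)
    # each side's gain scales with its own critical factor
    a_f_left, _ = efferent_gains(
        sigma[0], sigma[1], spec.feedback, spec.sensor_left.a_f_crit
    )
    _, a_f_right = efferent_gains(
        sigma[0], sigma[1], spec.feedback, spec.sensor_right.a_f_crit
    )
    a_f = np.stack([np.broadcast_to(a_f_left, t.shape),
                    np.broadcast_to(a_f_right, t.shape)])
    return SimResult(
        t=t, u_env=u_env, q=q, r=r, sigma=sigma, g_q=mntb_rate(q), a_f=a_f,
        x=x, v=v, theta=theta, u_ac=u_ac,
        metadata={
            "mode": "closed_loop",
            "feedback": spec.feedback,
            "stimulus": stim,
            "rho_w": spec.neural.rho_w,
        },
    )


def run_closed_loop(
    spec: SystemSpec, stim: StimulusSpec, y0: Optional[np.ndarray] = None
) -> SimResult:
    """Integrate the coupled 14-state system for ``stim.duration``.

    The efferent gains are recomputed from the instantaneous LSO rates
    inside the right-hand side (continuous coupling).  If ``y0`` is not
    given the system is initialized first (2 s stimulus-free settling).
    """
    if spec.mode != "closed_loop":
        raise ValueError("spec.mode must be 'closed_loop'")
    if y0 is None:
        y0 = initialize(spec)
    p = _closed_loop_params(spec, stim, stim_on=True)
    dt = spec.solver.sample_dt
    t_eval = np.arange(0.0, stim.duration + 0.5 * dt, dt)
    t_eval[-1] = min(t_eval[-1], stim.duration)
    sol = _solve(
        _kernels.closed_loop_rhs, _kernels.closed_loop_jac,
        (0.0, stim.duration), y0, p, spec.solver, t_eval,
    )
    return _unpack_closed(spec, sol, stim)


def run_open_loop_table(
    spec: SystemSpec,
    table: SurrogateSensorTable,
    k_a_left: float,
    k_a_right: float,
    ild: float,
    stim: Optional[StimulusSpec] = None,
) -> SimResult:
    """Table-driven mode: sensor dynamics replaced by tabulated transfer.

    For each side the readout ``u_ac(t)`` is synthesized as a sinusoid at
    the sensor's resonance frequency whose amplitude is looked up from
    the transfer table at (k_a, stimulus amplitude for this ILD); only
    the envelope extractor and the neural stage are integrated (6
    states).
    """
    if spec.mode != "open_loop_table":
        raise ValueError("spec.mode must be 'open_loop_table'")
    stim = stim if stim is not None else StimulusSpec(ild=ild)
    if stim.ild != ild:
        stim = replace(stim, ild=ild)
    amp_l, amp_r = stim.amplitudes
    uac_amp_l = envelope_from_table(table, "left", k_a_left, amp_l)
    uac_amp_r = envelope_from_table(table, "right", k_a_right, amp_r)
    p = _kernels.pack_open_loop(
        spec.sensor_left.tau_lpf,
        spec.sensor_right.tau_lpf,
        uac_amp_l,
        uac_amp_r,
        2.0 * np.pi * table.f_res["left"],
        2.0 * np.pi * table.f_res["right"],
        spec.neural,
    )
    dt = spec.solver.sample_dt
    t_eval = np.arange(0.0, stim.duration + 0.5 * dt, dt)
    t_eval[-1] = min(t_eval[-1], stim.duration)
    y0 = np.zeros(_kernels.OPEN_LOOP_STATES)
    sol = _solve(
        _kernels.open_loop_rhs, None, (0.0, stim.duration), y0, p,
        spec.solver, t_eval,
    )
    y = sol.y
    u_env = np.stack([y[0], y[1]])
    q = np.stack([y[2], y[4]])
    r = np.stack([y[3], y[5]])
    if np.max(np.abs(r)) > _R_BOUND:
        raise SimulationError(f"unbounded LSO potential {np.max(np.abs(r)):.3e} V")
    sigma = lso_rate(r, spec.neural)
    a_f = np.stack(
        [
            np.full_like(sol.t, k_a_left * spec.sensor_left.a_f_crit),
            np.full_like(sol.t, k_a_right * spec.sensor_right.a_f_crit),
        ]
    )
    return SimResult(
        t=sol.t, u_env=u_env, q=q, r=r, sigma=sigma, g_q=mntb_rate(q), a_f=a_f,
        metadata={
            "mode": "open_loop_table",
            "k_a": (k_a_left, k_a_right),
            "stimulus": stim,
            "rho_w": spec.neural.rho_w,
        },
    )


def run_single_sensor(
    params: CantileverParams,
    a_f: float,
    amplitude: float = 0.0,
    freq: Optional[float] = None,
    duration: float = 0.2,
    y0: Optional[np.ndarray] = None,
    solver: Optional[SolverSettings] = None,
):
    """Integrate one 5-state sensor channel at a fixed feedback factor.

    Used for open-loop characterization (transfer curves) and for probing
    the Hopf bifurcation (``amplitude = 0`` with a perturbed ``y0``).

    Returns
    -------
    (t, y) : uniform time grid and a (5, n) state array.
    """
    solver = solver or SolverSettings()
    freq = freq if freq is not None else params.f0
    p = _kernels.pack_single_sensor(params, a_f, amplitude, 2.0 * np.pi * freq)
    if y0 is None:
        y0 = equilibrium(params).as_array()
    dt = solver.sample_dt
    t_eval = np.arange(0.0, duration + 0.5 * dt, dt)
    t_eval[-1] = min(t_eval[-1], duration)
    sol = _solve(
        _kernels.single_sensor_rhs, None, (0.0, duration), np.asarray(y0, float),
        p, solver, t_eval,
    )
    return sol.t, sol.y


def ild_sweep(
    spec: SystemSpec,
    ild_grid: Sequence[float],
    stim_defaults: Optional[StimulusSpec] = None,
    window: float = 0.1,
    slice_dt: float = 0.1,
    keep_traces: bool = False,
    table: Optional[SurrogateSensorTable] = None,
    k_a: tuple = (0.4, 0.4),
) -> analysis.ResponseCurve:
    """Run one simulation per ILD grid point and assemble the response curve.

    Grid points are independent (the initialization equilibrium does not
    depend on the stimulus, so it is computed once and reused).  Per-point
    failures are collected into a single :class:`SweepError` naming the
    offending ILD values.
    """
    ild_grid = np.sort(np.asarray(ild_grid, dtype=float))  # order-insensitive
    stim_defaults = stim_defaults if stim_defaults is not None else StimulusSpec()
    y0 = initialize(spec) if spec.mode == "closed_loop" else None
    sig_left, sig_right, t_grid = [], [], None
    failures = []
    for ild in ild_grid:
        try:
            stim = replace(stim_defaults, ild=float(ild))
            if spec.mode == "closed_loop":
                res = run_closed_loop(spec, stim, y0=y0)
            else:
                res = run_open_loop_table(spec, table, k_a[0], k_a[1], float(ild), stim)
        except (SimulationError, ValueError) as err:
            failures.append((float(ild), err))
            continue
        t_grid = res.t
        sig_left.append(res.sigma[0])
        sig_right.append(res.sigma[1])
    if failures:
        raise SweepError(failures)
    return analysis.build_response_curve(
        ild_grid,
        t_grid,
        np.column_stack(sig_left),
        np.column_stack(sig_right),
        window=window,
        slice_dt=slice_dt,
        keep_traces=keep_traces,
        metadata={
            "feedback": spec.feedback,
            "rho_w": spec.neural.rho_w,
            "mode": spec.mode,
            "k_a": k_a if spec.mode == "open_loop_table" else None,
        },
    )
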