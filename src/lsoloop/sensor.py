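"""Adaptive MEMS cantilever sensor model.

A silicon cantilever with piezo-resistive readout acts as a resonant,
band-pass acoustic sensor.  An integrated resistive heater bends the beam
thermomechanically, which closes a local electronic feedback loop: the
high-pass-filtered readout voltage, scaled by a feedback factor ``a_f``, is
added to a DC bias and applied to the heater.  Raising ``a_f`` sharpens and
amplifies the resonance; at a critical value the quiescent state loses
stability in a Hopf bifurcation and the beam oscillates autonomously.  The
sensor is therefore operated at ``a_f`` below that critical gain, where it
behaves as a tunable small-signal amplifier.

One sensor channel carries five dynamical states: tip deflection ``x``,
velocity ``v``, beam-ambient temperature difference ``theta``, the high-pass
filtered readout ``u_ac``, and the rectified low-pass envelope ``u_env``
that drives the downstream neural stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CantileverParams",
    "SensorState",
    "NoBifurcationError",
    "actuation_voltage",
    "heating_rate",
    "sensor_rhs",
    "envelope_rhs",
    "equilibrium",
    "sensor_jacobian",
    "find_critical_gain",
]


class NoBifurcationError(RuntimeError):
    """Raised when no Hopf crossing is found in the swept gain range."""


@dataclass(frozen=True)
class CantileverParams:
    """Physical and filter parameters of one cantilever channel.

    Defaults are the values used throughout: a 1 kHz resonator with
    quality factor 50, thermomechanical actuation, and RC high/low-pass
    stages for readout filtering and envelope extraction.

    Parameters
    ----------
    f0 : float
        Resonance frequency in Hz.  ``omega0 = 2*pi*f0`` is derived.
    Q0 : float
        Quality factor (dimensionless).
    alpha_s : float
        Temperature-to-deflection transfer factor, m s^-2 K^-1.
    beta_s : float
        Thermal relaxation rate, s^-1.
    gamma_s : float
        Voltage-to-heating transfer factor, K Ohm^2 s^-1 V^-2.
    R : float
        Heater resistance, Ohm.
    kappa_s : float
        Combined piezo-resistive and pre-amplification factor mapping
        deflection to readout voltage, V m^-1.
    tau_hpf, tau_lpf : float
        High-pass (readout) and low-pass (envelope) time constants, s.
    u_dc : float
        Constant bias offset of the actuation voltage, V.
    a_f_crit : float
        Critical feedback factor at the Hopf point (dimensionless).  The
        stored default is the reference value; :func:`find_critical_gain`
        recomputes it from the other parameters.
    limiter : {"current", "voltage"}
        Placement of the tanh saturation in the heating law.  "current"
        evaluates ``gamma_s * tanh(u_act/R)**2`` (default); "voltage"
        evaluates ``gamma_s * (tanh(u_act)/R)**2``.  The two differ only
        in the large-signal regime and in a sub-percent shift of the
        critical gain.
    """

    f0: float = 1.0e3
    Q0: float = 50.0
    alpha_s: float = 19.2
    beta_s: float = 1006.6
    gamma_s: float = 16.2e6
    R: float = 15.0
    kappa_s: float = 0.602e6
    tau_hpf: float = 1.0e-3
    tau_lpf: float = 5.0e-3
    u_dc: float = -100.0e-3
    a_f_crit: float = 0.03236
    limiter: str = "current"

    def __post_init__(self) -> None:
        for name in ("f0", "Q0", "tau_hpf", "tau_lpf", "R", "beta_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.limiter not in ("current", "voltage"):
            raise ValueError("limiter must be 'current' or 'voltage'")

    @property
    def omega0(self) -> float:
        """Angular resonance frequency 2*pi*f0, rad/s."""
        return 2.0 * np.pi * self.f0

    def with_(self, **kwargs) -> "CantileverParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SensorState:
    """Dynamical state of one sensor channel."""

    x: float = 0.0  # tip deflection, m
    v: float = 0.0  # deflection velocity, m/s
    theta: float = 0.0  # beam-ambient temperature difference, K
    u_ac: float = 0.0  # high-pass filtered readout, V
    u_env: float = 0.0  # envelope voltage, V

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.v, self.theta, self.u_ac, self.u_env])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SensorState":
        return cls(*(float(c) for c in y[:5]))


def actuation_voltage(u_ac, a_f, u_dc):
    """Heater actuation voltage: feedback term plus DC bias.

    ``u_act = a_f * u_ac + u_dc``.
    """
    return a_f * u_ac + u_dc


def heating_rate(u_act, params: CantileverParams):
    """Thermal power delivered to the beam per unit heat capacity, K/s.

    The Joule heating of the resistive actuator saturates through a tanh
    limiter; the result is non-negative and even in ``u_act``.
    """
    if params.limiter == "current":
        return params.gamma_s * np.tanh(u_act / params.R) ** 2
    return params.gamma_s * (np.tanh(u_act) / params.R) ** 2


def sensor_rhs(state, a_f: float, F_ext: float, params: CantileverParams) -> np.ndarray:
    """Time derivatives of the four mechanical/electrical sensor states.

    The beam is a driven, damped harmonic oscillator forced by the
    thermal bending moment and the external sound acceleration; the
    temperature relaxes toward the actuation heating; the readout
    high-pass is integrated in the substituted form
    ``du_ac = kappa_s * v - u_ac / tau_hpf`` (using ``du_s = kappa_s * dx``),
    which avoids differentiating a solver output.

    Parameters
    ----------
    state : SensorState or array-like
        Current state; only ``(x, v, theta, u_ac)`` are used.
    a_f : float
        Instantaneous feedback factor.
    F_ext : float
        External (sound) forcing in m s^-2, mass-normalized.

    Returns
    -------
    numpy.ndarray
        ``(dx, dv, dtheta, du_ac)``.
    """
    if isinstance(state, SensorState):
        x, v, theta, u_ac = state.x, state.v, state.theta, state.u_ac
    else:
        x, v, theta, u_ac = state[0], state[1], state[2], state[3]
    w0 = params.omega0
    u_act = actuation_voltage(u_ac, a_f, params.u_dc)
    return np.array(
        [
            v,
            -(w0 / params.Q0) * v - w0**2 * x + params.alpha_s * theta + F_ext,
            -params.beta_s * theta + heating_rate(u_act, params),
            params.kappa_s * v - u_ac / params.tau_hpf,
        ]
    )


def envelope_rhs(u_env, u_ac, tau_lpf: float):
    """Envelope extractor: full-wave rectifier into a first-order low-pass."""
    if tau_lpf <= 0:
        raise ValueError("tau_lpf must be positive")
    return (np.abs(u_ac) - u_env) / tau_lpf


def equilibrium(params: CantileverParams) -> SensorState:
    """Closed-form quiescent state of the sensor with no sound input.

    At equilibrium ``v = 0`` forces ``u_ac = 0`` through the high-pass, so
    the heater sees only the DC bias:
    ``theta_eq = heating_rate(u_dc)/beta_s`` and
    ``x_eq = alpha_s*theta_eq/omega0**2``.  The equilibrium is independent
    of the feedback factor.
    """
    theta_eq = float(heating_rate(params.u_dc, params)) / params.beta_s
    x_eq = params.alpha_s * theta_eq / params.omega0**2
    return SensorState(x=x_eq, v=0.0, theta=theta_eq, u_ac=0.0, u_env=0.0)


def _dheating_du(u_act: float, params: CantileverParams) -> float:
    """Derivative of heating_rate with respect to u_act."""
    if params.limiter == "current":
        t = np.tanh(u_act / params.R)
        return params.gamma_s * 2.0 * t * (1.0 - t * t) / params.R
    t = np.tanh(u_act)
    return params.gamma_s * 2.0 * t * (1.0 - t * t) / params.R**2


def sensor_jacobian(a_f: float, params: CantileverParams) -> np.ndarray:
    """Jacobian of the autonomous 4-state loop at its equilibrium.

    States ordered ``(x, v, theta, u_ac)`` with ``F_ext = 0``.
    """
    w0 = params.omega0
    u_act_eq = actuation_voltage(0.0, a_f, params.u_dc)
    dh = _dheating_du(u_act_eq, params)
    return np.array(
        [
            [0.0, 1.0, 0.0, 0.0],
            [-w0**2, -w0 / params.Q0, params.alpha_s, 0.0],
            [0.0, 0.0, -params.beta_s, dh * a_f],
            [0.0, params.kappa_s, 0.0, -1.0 / params.tau_hpf],
        ]
    )


def _oscillatory_growth_rate(a_f: float, params: CantileverParams) -> float:
    """Max real part over the complex-conjugate eigenvalue pairs."""
    eig = np.linalg.eigvals(sensor_jacobian(a_f, params))
    osc = eig[np.abs(eig.imag) > 1e-9]
    if osc.size == 0:
        return -np.inf
    return float(osc.real.max())


def find_critical_gain(
    params: CantileverParams,
    sweep_step: float = 1.0e-3,
    sweep_max: float = 1.0,
    tol: float = 1.0e-6,
) -> float:
    """Locate the Hopf bifurcation of the local sensor feedback loop.

    Sweeps the feedback factor upward from zero in steps of
    ``sweep_step`` until the oscillatory eigenvalue pair of the
    equilibrium Jacobian crosses into the right half plane, then bisects
    the bracketing interval to absolute tolerance ``tol``.

    Returns
    -------
    float
        The smallest positive feedback factor at which the quiescent
        state loses stability to autonomous oscillation.

    Raises
    ------
    NoBifurcationError
        If no crossing occurs up to ``sweep_max`` (e.g. when the
        actuation path is broken, ``alpha_s = 0`` or ``gamma_s = 0``).
    """
    a_lo, g_lo = 0.0, _oscillatory_growth_rate(0.0, params)
    a_hi = None
    a = sweep_step
    while a <= sweep_max + 1e-15:
        g = _oscillatory_growth_rate(a, params)
        if g > 0.0 and np.isfinite(g):
            a_hi = a
            break
        if np.isfinite(g):
            a_lo, g_lo = a, g
        a += sweep_step
    if a_hi is None or not np.isfinite(g_lo):
        raise NoBifurcationError(
            f"no Hopf crossing found for a_f in (0, {sweep_max}]"
        )
    while a_hi - a_lo > tol:
        mid = 0.5 * (a_lo + a_hi)
        if _oscillatory_growth_rate(mid, params) > 0.0:
            a_hi = mid
        else:
            a_lo = mid
    return 0.5 * (a_lo + a_hi)
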