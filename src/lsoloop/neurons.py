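"""Conductance-based rate neurons of the MNTB/LSO binaural circuit.

The lateral superior olive (LSO) encodes interaural level differences by
combining excitatory drive from the ipsilateral ear with inhibitory drive
from the contralateral ear, relayed through the medial nucleus of the
trapezoid body (MNTB).  Both neurons are single-compartment rate models:
the MNTB is a leaky integrator of its excitatory input with a half-wave
rectified output, the LSO a conductance-based unit whose excitatory and
inhibitory conductances pull the membrane potential toward reversal
potentials ``beta_r`` and ``-gamma_r/kappa_r`` respectively.  The LSO
output rate is a logistic function of its membrane potential.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NeuralParams",
    "NeuralState",
    "mntb_rhs",
    "mntb_rate",
    "mntb_equilibrium",
    "lso_rhs",
    "lso_rate",
    "lso_equilibrium",
]


@dataclass(frozen=True)
class NeuralParams:
    """Parameters of one MNTB/LSO pair (shared between the two sides).

    The input weights ``w_mntb_exc`` and ``w_lso_exc`` carry no default:
    they are the experiment's excitation-inhibition balance
    ``rho_w = w_lso_exc / w_mntb_exc`` and are set by the experiment
    configuration (2/1 for the table-driven open-loop mode, 200..750/100
    for the full closed-loop mode).
    """

    w_mntb_exc: float
    w_lso_exc: float
    tau_q: float = 25.0e-6  # MNTB membrane time constant, s
    alpha_q: float = 2.0  # MNTB leak rate
    beta_q: float = 1.0  # MNTB input scale, V
    tau_r: float = 25.0e-6  # LSO membrane time constant, s
    alpha_r: float = 1.0  # LSO leak rate
    beta_r: float = 1.0  # excitatory reversal potential, V
    gamma_r: float = 3.0  # subtractive inhibition, V
    kappa_r: float = 4.0  # divisive inhibition
    alpha_sigma: float = 20.0  # output sigmoid steepness, 1/V
    beta_sigma: float = 0.2  # output sigmoid offset, V

    def __post_init__(self) -> None:
        if self.tau_q <= 0 or self.tau_r <= 0:
            raise ValueError("time constants must be positive")
        if self.beta_r <= 0 or self.kappa_r <= 0:
            raise ValueError("beta_r and kappa_r must be positive")

    @property
    def rho_w(self) -> float:
        """Excitation-inhibition balance w_lso_exc / w_mntb_exc."""
        return self.w_lso_exc / self.w_mntb_exc

    def with_(self, **kwargs) -> "NeuralParams":
        return replace(self, **kwargs)


@dataclass
class NeuralState:
    """Membrane potentials of one MNTB/LSO pair, V."""

    q: float = 0.0
    r: float = 0.0


def mntb_rhs(q, u_env, params: NeuralParams):
    """dq/dt of the MNTB leaky integrator driven by the sensor envelope."""
    s_q = u_env * params.w_mntb_exc
    return (-params.alpha_q * q + params.beta_q * s_q) / params.tau_q


def mntb_rate(q):
    """MNTB output: half-wave rectified membrane potential."""
    return np.maximum(q, 0.0)


def mntb_equilibrium(u_env, params: NeuralParams):
    """Closed-form MNTB fixed point q_eq = beta_q * s_q / alpha_q."""
    return params.beta_q * u_env * params.w_mntb_exc / params.alpha_q


def lso_rhs(r, u_env, g_in, params: NeuralParams):
    """dr/dt of the conductance-based LSO neuron.

    Parameters
    ----------
    r : float
        LSO membrane potential, V.
    u_env : float
        Ipsilateral sensor envelope (excitatory drive), V.
    g_in : float
        Contralateral MNTB rate (inhibitory conductance), V.
    """
    s_r = u_env * params.w_lso_exc
    return (
        -params.alpha_r * r
        + (params.beta_r - r) * s_r
        - (params.gamma_r + params.kappa_r * r) * g_in
    ) / params.tau_r


def lso_rate(r, params: NeuralParams):
    """LSO output rate: logistic function of the membrane potential, in (0,1)."""
    with np.errstate(over="ignore"):  # exp overflow saturates cleanly to 0
        return 1.0 / (1.0 + np.exp(-(r - params.beta_sigma) * params.alpha_sigma))


def lso_equilibrium(u_env, g_in, params: NeuralParams):
    """Closed-form LSO fixed point under constant inputs.

    r_eq = (beta_r*s_r - gamma_r*g) / (alpha_r + s_r + kappa_r*g).
    """
    s_r = u_env * params.w_lso_exc
    return (params.beta_r * s_r - params.gamma_r * g_in) / (
        params.alpha_r + s_r + params.kappa_r * g_in
    )
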