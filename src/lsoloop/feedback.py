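"""Efferent feedback: routing LSO output back to the sensor gains.

The LSO rate on each side can modulate the local feedback factor of
either the same-side (ipsilateral) or opposite-side (contralateral)
sensor, with positive (amplifying) or negative (damping) sign.  The
gain is expressed relative to the sensor's critical feedback factor and
clamped below it (``k_max < 1``) so the efferent drive alone can never
push a sensor across its Hopf point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = ["FeedbackConfig", "efferent_gains", "CONFIGURATIONS"]

_TOPOLOGIES = ("none", "ipsi", "contra")


@dataclass(frozen=True)
class FeedbackConfig:
    """One efferent feedback condition.

    topology
        "ipsi" routes each LSO output to the same-side sensor, "contra"
        to the opposite side, "none" applies the constant baseline gain
        ``k_a_const * a_f_crit`` on both sides.
    k_inv
        +1 for positive (non-inverted) feedback, -1 for negative.
    k_max
        Clamp on the relative gain; keeps the closed loop strictly below
        the sensor's bifurcation.
    k_a_const
        Baseline relative gain used when topology is "none" and during
        initialization.
    """

    topology: str = "none"
    k_inv: int = +1
    k_max: float = 0.95
    k_a_const: float = 0.5

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"topology must be one of {_TOPOLOGIES}")
        if self.k_inv not in (+1, -1):
            raise ValueError("k_inv must be +1 or -1")
        if not 0.0 < self.k_max < 1.0:
            raise ValueError("k_max must lie in (0, 1)")
        if not abs(self.k_a_const) < 1.0:
            raise ValueError("|k_a_const| must be < 1")

    def with_(self, **kwargs) -> "FeedbackConfig":
        return replace(self, **kwargs)


#: The five feedback conditions studied: the four closed-loop topologies
#: plus the constant-gain baseline.
CONFIGURATIONS = {
    "no_fb": FeedbackConfig(topology="none"),
    "ipsi_pos": FeedbackConfig(topology="ipsi", k_inv=+1),
    "ipsi_neg": FeedbackConfig(topology="ipsi", k_inv=-1),
    "contra_pos": FeedbackConfig(topology="contra", k_inv=+1),
    "contra_neg": FeedbackConfig(topology="contra", k_inv=-1),
}


def efferent_gains(
    sigma_left, sigma_right, config: FeedbackConfig, a_f_crit: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Map the two LSO rates to the two sensor feedback factors.

    Each gain is ``k_inv * min(sigma, k_max) * a_f_crit`` where ``sigma``
    is the LSO rate of the source side selected by the topology; the
    clamp acts on the rate before the sign is applied.  Accepts scalars
    or arrays (e.g. whole rate traces).

    Returns
    -------
    (a_f_left, a_f_right)
    """
    sigma_left = np.asarray(sigma_left, dtype=float)
    sigma_right = np.asarray(sigma_right, dtype=float)
    if config.topology == "none":
        const = config.k_a_const * a_f_crit
        return (
            np.broadcast_to(const, sigma_left.shape).copy()[()],
            np.broadcast_to(const, sigma_right.shape).copy()[()],
        )
    if config.topology == "ipsi":
        src_left, src_right = sigma_left, sigma_right
    else:  # contra: swap the routing
        src_left, src_right = sigma_right, sigma_left
    a_left = config.k_inv * np.minimum(src_left, config.k_max) * a_f_crit
    a_right = config.k_inv * np.minimum(src_right, config.k_max) * a_f_crit
    return a_left[()], a_right[()]
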