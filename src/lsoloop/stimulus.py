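"""Binaural ILD stimulus and surrogate sensor transfer tables.

The stimulus is a pure tone whose left/right amplitudes sum to a constant,
parameterized by a dimensionless interaural level difference (ILD) in
[-1, 1]: ``A_right = beta_ild + alpha_ild*ILD`` and
``A_left = beta_ild - alpha_ild*ILD``.  The constant sum removes overall
loudness and distance cues so only the level difference carries location
information.  Positive ILD means a louder right channel.

The surrogate sensor tables are synthetic stand-ins for measured
cantilever transfer curves (envelope voltage vs. sound amplitude at a set
of local feedback strengths ``k_a``): two slightly mismatched resonators
near 950 and 986 Hz whose gain grows with ``k_a`` like the model sensor's
small-signal resonant gain, ``1/(1 - k_a)``.  They drive the table-based
open-loop mode in which the sensor dynamics are replaced by interpolation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "StimulusSpec",
    "SurrogateSensorTable",
    "ild_stimulus",
    "make_surrogate_sensors",
    "envelope_from_table",
]

SIDES = ("left", "right")


@dataclass(frozen=True)
class StimulusSpec:
    """Constant-sum binaural pure-tone stimulus."""

    ild: float = 0.0
    alpha_ild: float = 0.5  # level slope per ILD unit
    beta_ild: float = 0.5  # level offset (mean amplitude)
    freq: float = 1.0e3  # carrier frequency, Hz
    duration: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.beta_ild < self.alpha_ild:
            raise ValueError("beta_ild must be >= alpha_ild for non-negative amplitudes")
        if self.alpha_ild != 0 and abs(self.ild) > self.beta_ild / self.alpha_ild:
            raise ValueError(
                f"|ild| = {abs(self.ild)} exceeds beta_ild/alpha_ild "
                f"= {self.beta_ild / self.alpha_ild}: negative amplitude"
            )
        if self.freq <= 0 or self.duration <= 0:
            raise ValueError("freq and duration must be positive")

    @property
    def amplitudes(self) -> tuple:
        """(A_left, A_right); their sum is 2*beta_ild for every ILD."""
        return (
            self.beta_ild - self.alpha_ild * self.ild,
            self.beta_ild + self.alpha_ild * self.ild,
        )

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.freq


def ild_stimulus(spec: StimulusSpec, t):
    """Left/right sound forcing (m s^-2, mass-normalized) at times ``t``."""
    a_left, a_right = spec.amplitudes
    s = np.sin(spec.omega * np.asarray(t, dtype=float))
    return a_left * s, a_right * s


@dataclass
class SurrogateSensorTable:
    """Envelope-vs-amplitude transfer curves for two sensors.

    ``env[side]`` has shape ``(len(k_a_grid), len(amplitude_grid))`` and
    holds the steady envelope voltage for each (feedback strength, sound
    amplitude) pair.  Round-trips through a tidy delimited text file so a
    measured table can be substituted for the synthetic one.
    """

    k_a_grid: np.ndarray
    amplitude_grid: np.ndarray
    env: dict  # side -> 2D array (k_a, amplitude)
    f_res: dict = field(default_factory=lambda: {"left": 950.0, "right": 986.0})
    mismatch: float = 0.0
    seed: int = 42

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for side in SIDES:
            for i, ka in enumerate(self.k_a_grid):
                for j, amp in enumerate(self.amplitude_grid):
                    rows.append((side, ka, amp, self.env[side][i, j]))
        return pd.DataFrame(rows, columns=["sensor", "k_a", "amplitude", "envelope"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, f_res=None) -> "SurrogateSensorTable":
        k_a = np.array(sorted(df["k_a"].unique()))
        amp = np.array(sorted(df["amplitude"].unique()))
        env = {}
        for side in SIDES:
            sub = df[df["sensor"] == side].pivot(
                index="k_a", columns="amplitude", values="envelope"
            )
            env[side] = sub.loc[k_a, amp].to_numpy()
        table = cls(k_a_grid=k_a, amplitude_grid=amp, env=env)
        if f_res is not None:
            table.f_res = dict(f_res)
        return table

    @classmethod
    def read_csv(cls, path) -> "SurrogateSensorTable":
        return cls.from_frame(pd.read_csv(path))


def make_surrogate_sensors(
    mismatch: float = 0.3,
    seed: int = 42,
    k_a_grid=(0.0, 0.2, 0.4, 0.6, 0.8),
    amplitude_grid=None,
    base_gain: float = 0.5,
    noise_sigma: float = 0.005,
) -> SurrogateSensorTable:
    """Generate synthetic transfer tables for two mismatched sensors.

    Each sensor's envelope is linear in sound amplitude with slope
    ``G * 1/(1 - k_a)``; the right sensor's base gain is
    ``base_gain * (1 + mismatch)``.  Multiplicative Gaussian noise of
    relative width ``noise_sigma`` (default 0.5%) emulates measurement
    scatter while preserving monotonicity and the zero at zero amplitude.
    """
    if mismatch < 0:
        raise ValueError("mismatch must be >= 0")
    k_a = np.asarray(k_a_grid, dtype=float)
    amp = (
        np.linspace(0.0, 1.0, 11)
        if amplitude_grid is None
        else np.asarray(amplitude_grid, dtype=float)
    )
    rng = np.random.default_rng(seed)
    env = {}
    for side, gain0 in (("left", base_gain), ("right", base_gain * (1.0 + mismatch))):
        clean = gain0 / (1.0 - k_a)[:, None] * amp[None, :]
        noise = rng.standard_normal(clean.shape)
        env[side] = clean * (1.0 + noise_sigma * noise)
    if mismatch == 0.0:
        env["right"] = env["left"].copy()
    return SurrogateSensorTable(
        k_a_grid=k_a, amplitude_grid=amp, env=env, mismatch=mismatch, seed=seed
    )


def envelope_from_table(
    table: SurrogateSensorTable, side: str, k_a: float, amplitude: float
) -> float:
    """Bilinear interpolation of the envelope at (k_a, amplitude).

    Raises ``ValueError`` for queries outside the tabulated grid.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    interp = RegularGridInterpolator(
        (table.k_a_grid, table.amplitude_grid),
        table.env[side],
        method="linear",
        bounds_error=True,
    )
    return float(interp([[k_a, amplitude]])[0])
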