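"""Response metrics extracted from LSO rate traces.

All quantities are computed from the LSO output rate sigma(t) sampled on
a time grid: the steady-state response (mean over a trailing window),
the left-right steady-state difference, the transient timing TT90 (first
attainment of 90% of the trace maximum), non-overlapping temporal slice
means, and the ILD sensitivity d(sigma_eq)/d(ILD) by finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ResponseCurve",
    "steady_state",
    "delta_sigma",
    "tt90",
    "temporal_slices",
    "sensitivity",
    "build_response_curve",
    "equal_activation_ild",
]


def steady_state(sigma_trace, t_grid, window: float) -> float:
    """Mean of the trace over its final ``window`` seconds."""
    t = np.asarray(t_grid, dtype=float)
    sigma = np.asarray(sigma_trace, dtype=float)
    duration = t[-1] - t[0]
    if window > duration * (1 + 1e-12):
        raise ValueError(f"window {window} s exceeds trace duration {duration} s")
    mask = t >= t[-1] - window * (1 + 1e-12)
    return float(sigma[mask].mean())


def delta_sigma(curve_left, curve_right) -> np.ndarray:
    """Elementwise right minus left steady-state response."""
    left = np.asarray(curve_left, dtype=float)
    right = np.asarray(curve_right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left/right curves must share one ILD grid")
    return right - left


def tt90(sigma_trace, t_grid, onset: float = 0.0) -> float:
    """Time from onset to the first crossing of 90% of the trace maximum.

    The crossing is located by linear interpolation between the two
    bracketing samples; a trace that starts at or above threshold (e.g. a
    constant) returns the onset time difference of the first sample.
    """
    t = np.asarray(t_grid, dtype=float)
    sigma = np.asarray(sigma_trace, dtype=float)
    if sigma.size == 0:
        raise ValueError("empty trace")
    thr = 0.9 * sigma.max()
    above = np.nonzero(sigma >= thr)[0]
    i = above[0]
    if i == 0:
        return float(t[0] - onset)
    # linear interpolation across the crossing
    t_cross = t[i - 1] + (thr - sigma[i - 1]) * (t[i] - t[i - 1]) / (
        sigma[i] - sigma[i - 1]
    )
    return float(t_cross - onset)


def temporal_slices(sigma_trace, t_grid, dt: float) -> np.ndarray:
    """Means over consecutive windows [n*dt, (n+1)*dt); trailing partial
    windows are dropped."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.asarray(t_grid, dtype=float)
    sigma = np.asarray(sigma_trace, dtype=float)
    duration = t[-1] - t[0]
    n_slices = int(np.floor(duration / dt + 1e-9))
    if n_slices < 1:
        raise ValueError(f"dt {dt} s exceeds trace duration {duration} s")
    out = np.empty(n_slices)
    t0 = t[0]
    for n in range(n_slices):
        mask = (t >= t0 + n * dt) & (t < t0 + (n + 1) * dt)
        out[n] = sigma[mask].mean()
    return out


def sensitivity(ild_grid, sigma_eq) -> np.ndarray:
    """d(sigma_eq)/d(ILD): central differences inside the grid, first-order
    one-sided at both ends, so the output matches the grid length."""
    ild = np.asarray(ild_grid, dtype=float)
    sig = np.asarray(sigma_eq, dtype=float)
    if ild.size < 3:
        raise ValueError("need at least 3 grid points")
    h = np.diff(ild)
    if np.any(h <= 0):
        raise ValueError("ild grid must be strictly increasing")
    if not np.allclose(h, h[0], rtol=1e-8):
        raise ValueError("ild grid must be uniformly spaced")
    out = np.empty_like(sig)
    out[1:-1] = (sig[2:] - sig[:-2]) / (2.0 * h[0])
    out[0] = (sig[1] - sig[0]) / h[0]
    out[-1] = (sig[-1] - sig[-2]) / h[0]
    return out


@dataclass
class ResponseCurve:
    """Per-ILD summary of a binaural sweep.

    ``sigma_eq``, ``tt90`` and ``sensitivity`` are (2, n_ild) arrays with
    row 0 = left and row 1 = right LSO; ``slices`` has shape
    (2, n_slices, n_ild).  ``sigma_traces``, when retained, is a
    (2, n_time, n_ild) array of the raw LSO rate traces.
    """

    ild: np.ndarray
    sigma_eq: np.ndarray
    delta_sigma_eq: np.ndarray
    tt90: np.ndarray
    sensitivity: np.ndarray
    slices: np.ndarray
    window: float
    slice_dt: float
    t_grid: Optional[np.ndarray] = None
    sigma_traces: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, side in enumerate(("left", "right")):
            for j, ild in enumerate(self.ild):
                rows.append(
                    (
                        ild,
                        side,
                        self.sigma_eq[k, j],
                        self.tt90[k, j],
                        self.sensitivity[k, j],
                    )
                )
        return pd.DataFrame(
            rows, columns=["ild", "side", "sigma_eq", "tt90", "sensitivity"]
        )


def build_response_curve(
    ild_grid,
    t_grid,
    sigma_left_traces,
    sigma_right_traces,
    window: float = 0.1,
    slice_dt: float = 0.1,
    keep_traces: bool = False,
    metadata: Optional[dict] = None,
) -> ResponseCurve:
    """Assemble a ResponseCurve from per-ILD LSO rate traces.

    ``sigma_*_traces`` are (n_time, n_ild) arrays on the shared ``t_grid``.
    """
    ild = np.asarray(ild_grid, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    traces = np.stack(
        [np.asarray(sigma_left_traces), np.asarray(sigma_right_traces)]
    )  # (2, n_time, n_ild)
    n_ild = ild.size
    sig_eq = np.empty((2, n_ild))
    tt = np.empty((2, n_ild))
    for k in range(2):
        for j in range(n_ild):
            sig_eq[k, j] = steady_state(traces[k, :, j], t, window)
            tt[k, j] = tt90(traces[k, :, j], t)
    slc0 = temporal_slices(traces[0, :, 0], t, slice_dt)
    slices = np.empty((2, slc0.size, n_ild))
    for k in range(2):
        for j in range(n_ild):
            slices[k, :, j] = temporal_slices(traces[k, :, j], t, slice_dt)
    sens = np.stack([sensitivity(ild, sig_eq[0]), sensitivity(ild, sig_eq[1])])
    return ResponseCurve(
        ild=ild,
        sigma_eq=sig_eq,
        delta_sigma_eq=delta_sigma(sig_eq[0], sig_eq[1]),
        tt90=tt,
        sensitivity=sens,
        slices=slices,
        window=window,
        slice_dt=slice_dt,
        t_grid=t if keep_traces else None,
        sigma_traces=traces if keep_traces else None,
        metadata=metadata or {},
    )


def equal_activation_ild(curve: ResponseCurve) -> float:
    """ILD at which the left and right steady-state curves intersect.

    Locates the sign change of ``delta_sigma_eq`` along the grid and
    interpolates linearly.  Raises ``ValueError`` if no crossing exists.
    """
    d = curve.delta_sigma_eq
    ild = curve.ild
    sign = np.sign(d)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        raise ValueError("left and right curves do not intersect on the grid")
    i = idx[0]
    if d[i] == 0.0:
        return float(ild[i])
    return float(ild[i] - d[i] * (ild[i + 1] - ild[i]) / (d[i + 1] - d[i]))
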