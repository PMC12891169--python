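"""Experiment configuration: defaults, file loading, overrides, resolution.

A configuration is a nested mapping (YAML on disk).  Unspecified keys
fall back to the reference parameter set; the fully resolved mapping is
echoed to the output directory of every CLI run so results are
reproducible from the echoed file alone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .feedback import FeedbackConfig
from .neurons import NeuralParams
from .sensor import CantileverParams
from .stimulus import StimulusSpec
from .engine import SolverSettings, SystemSpec

__all__ = ["ExperimentConfig", "default_config"]

_SENSOR_DEFAULTS = {
    "f0": 1.0e3,
    "Q0": 50.0,
    "alpha_s": 19.2,
    "beta_s": 1006.6,
    "gamma_s": 16.2e6,
    "R": 15.0,
    "kappa_s": 0.602e6,
    "tau_hpf": 1.0e-3,
    "tau_lpf": 5.0e-3,
    "u_dc": -100.0e-3,
    "a_f_crit": 0.03236,
    "limiter": "current",
}

_DEFAULTS = {
    "seed": 0,
    "sensor": {
        "left": dict(_SENSOR_DEFAULTS),
        "right": dict(_SENSOR_DEFAULTS),
    },
    "neural": {
        "w_mntb_exc": 200.0,
        "w_lso_exc": 100.0,
        "tau_q": 25.0e-6,
        "alpha_q": 2.0,
        "beta_q": 1.0,
        "tau_r": 25.0e-6,
        "alpha_r": 1.0,
        "beta_r": 1.0,
        "gamma_r": 3.0,
        "kappa_r": 4.0,
        "alpha_sigma": 20.0,
        "beta_sigma": 0.2,
    },
    "feedback": {
        "topology": "none",
        "sign": 1,
        "k_max": 0.95,
        "k_a_const": 0.5,
    },
    "stimulus": {
        "alpha_ild": 0.5,
        "beta_ild": 0.5,
        "freq": 1.0e3,
        "duration": 1.0,
    },
    "ild_grid": {"min": -1.0, "max": 1.0, "n": 21},
    "analysis": {"window": 0.1, "slice_dt": 0.1},
    "solver": {
        "method": "LSODA",
        "rtol": 1.0e-6,
        "atol": 1.0e-9,
        "sample_dt": 50.0e-6,
    },
    "sweep": {
        "configurations": ["no_fb", "ipsi_pos", "ipsi_neg", "contra_pos", "contra_neg"],
        "w_mntb_exc": [200.0, 400.0, 750.0],
    },
    "openloop": {
        "mismatch": 0.3,
        "k_a_left": [0.4],
        "k_a_right": [0.0, 0.2, 0.4, 0.6, 0.8],
        "window": 0.333,
        "w_mntb_exc": 2.0,
        "w_lso_exc": 1.0,
        "table": None,
    },
}

_FB_NAMES = {
    "no_fb": ("none", +1),
    "ipsi_pos": ("ipsi", +1),
    "ipsi_neg": ("ipsi", -1),
    "contra_pos": ("contra", +1),
    "contra_neg": ("contra", -1),
}


def default_config() -> dict:
    """Deep copy of the reference configuration."""
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, update: dict, prefix: str = "") -> dict:
    for key, value in update.items():
        path = f"{prefix}{key}"
        if key not in base:
            raise KeyError(f"unknown configuration key: {path}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise KeyError(f"configuration key {path} expects a mapping")
            _merge(base[key], value, prefix=f"{path}.")
        else:
            base[key] = value
    return base


@dataclass
class ExperimentConfig:
    """Resolved experiment configuration with typed builders."""

    data: dict = field(default_factory=default_config)

    @classmethod
    def load(cls, path=None, overrides: Sequence[str] = ()) -> "ExperimentConfig":
        """Load YAML from ``path`` (optional) and apply ``key=value``
        dotted overrides, on top of the defaults."""
        cfg = default_config()
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
            _merge(cfg, user)
        for item in overrides:
            if "=" not in item:
                raise KeyError(f"override '{item}' must have the form key=value")
            dotted, raw = item.split("=", 1)
            node = cfg
            parts = dotted.split(".")
            for part in parts[:-1]:
                if part not in node or not isinstance(node[part], dict):
                    raise KeyError(f"unknown configuration key: {dotted}")
                node = node[part]
            leaf = parts[-1]
            if leaf not in node:
                raise KeyError(f"unknown configuration key: {dotted}")
            node[leaf] = yaml.safe_load(raw)
        return cls(cfg)

    def dump(self, path) -> None:
        """Echo the fully resolved configuration."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)

    # -- typed builders -----------------------------------------------------

    def sensor(self, side: str) -> CantileverParams:
        return CantileverParams(**self.data["sensor"][side])

    def neural(self, **overrides) -> NeuralParams:
        kw = dict(self.data["neural"])
        kw.update(overrides)
        return NeuralParams(**kw)

    def feedback(self, name: Optional[str] = None) -> FeedbackConfig:
        fb = self.data["feedback"]
        topology, k_inv = fb["topology"], int(fb["sign"])
        if name is not None:
            if name not in _FB_NAMES:
                raise KeyError(f"unknown feedback configuration: {name}")
            topology, k_inv = _FB_NAMES[name]
        return FeedbackConfig(
            topology=topology,
            k_inv=k_inv,
            k_max=fb["k_max"],
            k_a_const=fb["k_a_const"],
        )

    def stimulus(self, ild: float = 0.0) -> StimulusSpec:
        return StimulusSpec(ild=ild, **self.data["stimulus"])

    def solver(self) -> SolverSettings:
        return SolverSettings(**self.data["solver"])

    def system(
        self,
        feedback_name: Optional[str] = None,
        mode: str = "closed_loop",
        **neural_overrides,
    ) -> SystemSpec:
        return SystemSpec(
            sensor_left=self.sensor("left"),
            sensor_right=self.sensor("right"),
            neural=self.neural(**neural_overrides),
            feedback=self.feedback(feedback_name),
            mode=mode,
            solver=self.solver(),
        )

    def ild_grid(self):
        import numpy as np

        g = self.data["ild_grid"]
        return np.linspace(g["min"], g["max"], int(g["n"]))
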