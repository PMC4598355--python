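"""Structured run configuration.

A single nested key-value tree covers segmentation, arena, simulation and
calibration settings.  Every key has a documented default (the calibrated
global constants); a YAML/JSON config file overrides defaults, and CLI
flags override the file.  Unknown keys are rejected with the list of valid
keys, so typos fail loudly.
"""

from __future__ import annotations

import copy
import json
from typing import Any, Mapping

import yaml

from .arena import Arena
from .preprocess import SegmentationConfig
from . import params as defaults

__all__ = ["DEFAULTS", "load_config", "RunConfig"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "segmentation": {
        "u_min": 1.0,  # BL/s
        "body_length": 3.0,  # cm
        "tau_s": 2.0,  # s
        "tau_l": 60.0,  # s
        "smooth_window": 3,  # samples
    },
    "arena": {
        "side": defaults.ARENA_SIDE,  # cm
        "corner_radius": defaults.CORNER_RADIUS,  # cm
    },
    "simulation": {
        "dt": defaults.DT,  # s
        "duration": 300.0,  # s
        "omega_clamp": defaults.OMEGA_CLAMP,  # rad/s
        "sigma0": defaults.SIGMA0,
        "wall_amplitude": defaults.WALL_A_SIM,  # rad/s
        "wall_decay": defaults.WALL_B,  # 1/cm
        "init_policy": "random",
        "coupled": True,
    },
    "calibration": {
        "loess_span": 0.2,
        "wall_mode": "distance",
        "sigma0_max_omega": defaults.MAX_OMEGA_FOR_SIGMA0,  # rad/s
        "sigma0_theta": defaults.THETA_OMEGA_FOR_SIGMA0,  # 1/s
    },
}


class RunConfig(dict):
    """Validated configuration tree with attribute-free dict access."""

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(**self["segmentation"])

    def arena(self) -> Arena:
        return Arena(**self["arena"])


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}{key}"
        if key not in base:
            valid = ", ".join(sorted(base))
            raise ValueError(f"unknown config key {here!r}; valid keys: {valid}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ValueError(f"config key {here!r} must be a mapping")
            out[key] = _merge(base[key], value, here + ".")
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: Mapping | None = None) -> RunConfig:
    """Build the run configuration.

    Precedence: ``overrides`` (CLI flags) > file at ``path`` > defaults.
    The file may be YAML or JSON; an empty file yields the full defaults.
    """
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ValueError(f"cannot parse config file {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return RunConfig(cfg)


def dump_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(cfg), fh, indent=2)
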