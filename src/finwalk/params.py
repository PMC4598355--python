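"""Packaged default parameters.

Per-fish Ornstein-Uhlenbeck triples for the eight zebrafish that yielded
usable swimming data, their segment counts, the segment-count-weighted
global triples, and the global simulation constants (time step, arena
dimensions, turning-noise saturation, turning-speed cut-off and the wall
avoidance function).

Two deliberate quirks of the source calibration are preserved:

* the global speed parameters follow the per-fish table semantics
  (theta_u = 0.59 1/s, sigma_u = 4.21 cm s^-1 s^-1/2), which is the
  assignment consistent with the observed speed-autocorrelation half-life;
* the turning mean-reversion rate appears both as the weighted global
  value 2.74 1/s and as 2.81 1/s, the value used when deriving the
  saturation level sigma0; both are kept and a warning is logged when the
  defaults are used.
"""

from __future__ import annotations

import logging

from .calibration import OUParams

log = logging.getLogger(__name__)

#: per-fish mean O-U parameters for the speed process (cm/s)
FISH_SPEED: dict[str, OUParams] = {
    "F1": OUParams(7.555, 0.592, 3.350),
    "F2": OUParams(8.899, 0.661, 4.447),
    "F3": OUParams(14.406, 0.298, 3.981),
    "F5": OUParams(12.841, 0.426, 4.086),
    "F6": OUParams(16.135, 0.633, 4.118),
    "F7": OUParams(20.964, 0.771, 4.810),
    "F9": OUParams(11.719, 0.717, 4.651),
    "F10": OUParams(16.642, 0.741, 4.689),
}

#: per-fish mean O-U parameters for the turning-speed process (rad/s)
FISH_TURN: dict[str, OUParams] = {
    "F1": OUParams(0.028, 3.077, 3.651),
    "F2": OUParams(0.280, 2.858, 4.676),
    "F3": OUParams(-0.183, 1.971, 2.304),
    "F5": OUParams(-0.187, 2.996, 3.649),
    "F6": OUParams(0.206, 3.347, 2.355),
    "F7": OUParams(-0.384, 2.175, 1.599),
    "F9": OUParams(-0.221, 3.456, 2.914),
    "F10": OUParams(0.221, 2.606, 2.128),
}

#: number of 60-s swimming segments isolated per fish (28 total)
SEGMENT_COUNTS: dict[str, int] = {
    "F1": 4, "F2": 3, "F3": 4, "F5": 4, "F6": 4, "F7": 4, "F9": 1, "F10": 4,
}

#: segment-count-weighted global triples (printed values)
GLOBAL_SPEED = OUParams(mu=14.02, theta=0.59, sigma=4.21)
GLOBAL_TURN = OUParams(mu=-0.02, theta=2.74, sigma=2.85)

# --- global simulation constants ---
DT = 0.2  # s, matches the 5 Hz acquisition rate
ARENA_SIDE = 120.0  # cm
CORNER_RADIUS = 10.0  # cm
SIGMA0 = 12.0  # rad s^-3/2, turning-noise saturation
OMEGA_CLAMP = 15.0  # rad/s, turning-speed cut-off
WALL_A_SIM = 6.75  # rad/s, wall amplitude used in simulation (3x the fit)
WALL_B = -0.11  # 1/cm, wall decay (distance mode)

# wall-response fit values (distance and time modes) before amplification
WALL_FIT_DISTANCE = {"A": 2.25, "B": -0.11}  # rad/s, 1/cm
WALL_FIT_TIME = {"A": 2.25, "B": -1.68}  # rad/s, 1/s

#: theta value used in the sigma0 derivation (differs from GLOBAL_TURN.theta)
THETA_OMEGA_FOR_SIGMA0 = 2.81  # 1/s
MAX_OMEGA_FOR_SIGMA0 = 10.0  # rad/s


def warn_default_quirks() -> None:
    """Log the two known inconsistencies carried by the default bundle."""
    log.warning(
        "default speed parameters use the per-fish table semantics "
        "(theta_u=0.59 1/s, sigma_u=4.21); the alternative printed ordering "
        "(theta_u=4.21, sigma_u=0.59) is inconsistent with the observed "
        "speed-ACF half-life and is not used"
    )
    log.warning(
        "turning mean-reversion rate: global value 2.74 1/s, but sigma0 is "
        "derived with 2.81 1/s; both retained"
    )
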