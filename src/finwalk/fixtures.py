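"""Synthetic data generators.

Everything the calibration and validation code consumes can be produced
here from known parameters, with no external data: exact Ornstein-Uhlenbeck
samples (the transition density is Gaussian, so the discrete-time chain can
be sampled without discretization error and serves as the oracle for the
Euler-Maruyama integrator and the MLE), wall-response scatter data for the
two-stage exponential fit, and full walker trajectories written in the
package CSV dialect.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import lfilter

from .calibration import OUParams
from .kinematics import Trajectory, write_trajectory
from .simulate import ModelParams, SimulationConfig, SimulationResult, run_simulation

__all__ = ["gen_ou_exact", "gen_wall_response", "gen_reference_trajectory"]


def gen_ou_exact(
    params: OUParams,
    n: int,
    dt: float,
    seed: int | np.random.Generator = 0,
    x0: float | None = None,
) -> np.ndarray:
    """Sample an O-U process exactly at a fixed step.

    Uses the exact AR(1) transition x_{k+1} = mu + (x_k - mu) e^{-theta dt}
    + s z_k with s^2 = sigma^2 (1 - e^{-2 theta dt}) / (2 theta).  By
    default the chain starts from a stationary draw
    N(mu, sigma^2/(2 theta)), so finite-sample statistics match the
    stationary theory; pass ``x0`` for a fixed start.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = math.exp(-params.theta * dt)
    s = params.sigma * math.sqrt((1.0 - a * a) / (2.0 * params.theta))
    if x0 is None:
        x0 = params.mu + math.sqrt(params.stationary_var) * rng.standard_normal()
    z = rng.standard_normal(n - 1)
    w = np.concatenate(([x0 - params.mu], s * z))
    return params.mu + lfilter([1.0], [1.0, -a], w)


def gen_wall_response(
    A: float,
    B: float,
    noise_sd: float,
    n: int,
    z_range: tuple[float, float] = (0.0, 60.0),
    seed: int | np.random.Generator = 0,
    mode: str = "distance",
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic wall-corrected turning scatter.

    Abscissae (projected collision distance in cm or time in s) are uniform
    on ``z_range``; ordinates are A*exp(B*z) plus Gaussian noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.uniform(z_range[0], z_range[1], size=n)
    omega_c = A * np.exp(B * z) + noise_sd * rng.standard_normal(n)
    return z, omega_c


def gen_reference_trajectory(
    params: ModelParams,
    cfg: SimulationConfig,
    path=None,
) -> tuple[Trajectory, SimulationResult]:
    """Simulate a walker and optionally write its trajectory CSV fixture."""
    result = run_simulation(params, cfg)
    if path is not None:
        write_trajectory(result.trajectory, path)
    return result.trajectory, result
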