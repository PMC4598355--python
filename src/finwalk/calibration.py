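"""Model calibration from kinematic data.

Four estimation steps parameterize the walker model:

* per-segment maximum-likelihood fits of the Ornstein-Uhlenbeck triples
  (mu, theta, sigma) for speed and turning speed, using the closed-form
  maximizer of the exact conditional (AR(1)) likelihood of a regularly
  sampled O-U process;
* per-fish averages of the segment fits and a global segment-count-weighted
  average across fish;
* the wall-response fit: a LOESS regression of wall-corrected turning speed
  on projected collision distance (or time), followed by a parametric
  exponential fit A*exp(B*z) to the smoothed curve;
* the turning-noise saturation level sigma0 = max(omega) * sqrt(2*theta) / 2,
  chosen so that the stationary 2-sigma band of the turning process matches
  the largest turning speeds seen in practice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from statsmodels.nonparametric.smoothers_lowess import lowess

from .arena import Arena, wall_corrected_turning
from .kinematics import Trajectory, compute_kinematics

__all__ = [
    "OUParams",
    "WallFit",
    "CalibrationResult",
    "fit_ou_mle",
    "ou_conditional_loglik",
    "average_params",
    "weighted_mean",
    "fit_wall_response",
    "estimate_sigma0",
    "wall_samples_from_trajectory",
]

log = logging.getLogger(__name__)


@dataclass
class OUParams:
    """Ornstein-Uhlenbeck triple dS = theta*(mu - S)*dt + sigma*dW.

    mu : equilibrium level (process units).
    theta : mean-reversion rate (1/s); the autocorrelation time is 1/theta.
    sigma : Wiener amplitude (process units * s^-1/2); the stationary
        variance is sigma^2 / (2*theta).
    """

    mu: float
    theta: float
    sigma: float

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def stationary_var(self) -> float:
        return self.sigma**2 / (2.0 * self.theta)

    def to_dict(self) -> dict:
        return {"mu": self.mu, "theta": self.theta, "sigma": self.sigma}

    @classmethod
    def from_dict(cls, d: Mapping) -> "OUParams":
        return cls(float(d["mu"]), float(d["theta"]), float(d["sigma"]))


@dataclass
class WallFit:
    """Exponential wall-repulsion fit omega_c ~ A*exp(B*z).

    ``mode`` records whether ``z`` is the projected collision distance
    (B in 1/cm) or time (B in 1/s).  A repulsive fit has A > 0 and B < 0.
    """

    A: float
    B: float
    se_A: float
    se_B: float
    mode: str = "distance"


@dataclass
class CalibrationResult:
    """Per-segment fits, per-fish averages and the weighted global set."""

    per_segment: dict[str, list[tuple[OUParams, OUParams]]]
    per_fish: dict[str, tuple[OUParams, OUParams]]
    counts: dict[str, int]
    global_speed: OUParams
    global_turn: OUParams
    wall_fit: WallFit | None = None
    sigma0: float | None = None


def _ou_sums(x: np.ndarray):
    x0, x1 = x[:-1], x[1:]
    return (
        float(x0.sum()),
        float(x1.sum()),
        float((x0 * x0).sum()),
        float((x0 * x1).sum()),
        float((x1 * x1).sum()),
        len(x0),
    )


def fit_ou_mle(x: np.ndarray, dt: float) -> OUParams:
    """Exact-likelihood MLE for a regularly sampled O-U process.

    Uses the conditional-Gaussian AR(1) representation
    ``x_{k+1} | x_k ~ N(mu + (x_k - mu) * a, sigma^2 (1 - a^2) / (2 theta))``
    with ``a = exp(-theta * dt)``; the maximizer has a closed form in the
    pairwise sums, so the score equations are satisfied to machine
    precision.

    Raises on a constant series and when the implied ``a`` falls outside
    (0, 1), i.e. when the sample carries no evidence of mean reversion.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate variance: series is constant")
    sx, sy, sxx, sxy, syy, n = _ou_sums(x)
    denom = n * (sxx - sxy) - (sx**2 - sx * sy)
    if denom == 0:
        raise ValueError("degenerate variance: cannot identify mu")
    mu = (sy * sxx - sx * sxy) / denom
    a_den = sxx - 2.0 * mu * sx + n * mu**2
    if a_den <= 0:
        raise ValueError("degenerate variance: cannot identify autocorrelation")
    a = (sxy - mu * (sx + sy) + n * mu**2) / a_den
    if not (0.0 < a < 1.0):
        raise ValueError(
            f"non-mean-reverting sample: fitted lag-1 coefficient a={a:.6g} "
            "outside (0, 1)"
        )
    theta = -math.log(a) / dt
    var_eps = (
        syy
        - 2.0 * a * sxy
        + a**2 * sxx
        - 2.0 * mu * (1.0 - a) * (sy - a * sx)
        + n * mu**2 * (1.0 - a) ** 2
    ) / n
    sigma2 = var_eps * 2.0 * theta / (1.0 - a**2)
    return OUParams(mu=float(mu), theta=float(theta), sigma=float(math.sqrt(max(sigma2, 0.0))))


def ou_conditional_loglik(params: OUParams, x: np.ndarray, dt: float) -> float:
    """Conditional (AR(1)) log-likelihood of an O-U parameter triple."""
    x = np.asarray(x, dtype=float)
    a = math.exp(-params.theta * dt)
    var = params.sigma**2 * (1.0 - a * a) / (2.0 * params.theta)
    resid = x[1:] - params.mu - (x[:-1] - params.mu) * a
    n = len(resid)
    return float(-0.5 * n * math.log(2.0 * math.pi * var) - 0.5 * np.sum(resid**2) / var)


def weighted_mean(values: Sequence[float], counts: Sequence[int]) -> float:
    """Segment-count-weighted mean of per-fish parameter values."""
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if values.size == 0 or counts.sum() <= 0:
        raise ValueError("empty input")
    return float((values * counts).sum() / counts.sum())


def _mean_params(fits: Sequence[OUParams]) -> OUParams:
    return OUParams(
        mu=float(np.mean([p.mu for p in fits])),
        theta=float(np.mean([p.theta for p in fits])),
        sigma=float(np.mean([p.sigma for p in fits])),
    )


def average_params(
    per_segment: Mapping[str, Sequence[tuple[OUParams, OUParams]]],
) -> CalibrationResult:
    """Per-fish and global parameter averages.

    ``per_segment`` maps a fish label to its list of per-segment
    (speed, turn) O-U fits.  The per-fish parameters are unweighted means
    over that fish's segments; the global parameters weight each fish by
    its segment count.
    """
    if not per_segment or all(len(v) == 0 for v in per_segment.values()):
        raise ValueError("empty input: no segment fits")
    per_fish: dict[str, tuple[OUParams, OUParams]] = {}
    counts: dict[str, int] = {}
    for fish, fits in per_segment.items():
        if not fits:
            continue
        per_fish[fish] = (
            _mean_params([f[0] for f in fits]),
            _mean_params([f[1] for f in fits]),
        )
        counts[fish] = len(fits)
    fish_ids = list(per_fish)
    n = [counts[f] for f in fish_ids]

    def _global(which: int, attr: str) -> float:
        return weighted_mean([getattr(per_fish[f][which], attr) for f in fish_ids], n)

    global_speed = OUParams(_global(0, "mu"), _global(0, "theta"), _global(0, "sigma"))
    global_turn = OUParams(_global(1, "mu"), _global(1, "theta"), _global(1, "sigma"))
    return CalibrationResult(
        per_segment=dict(per_segment),
        per_fish=per_fish,
        counts=counts,
        global_speed=global_speed,
        global_turn=global_turn,
    )


def fit_wall_response(
    z: np.ndarray,
    omega_c: np.ndarray,
    mode: str = "distance",
    loess_span: float = 0.2,
    grid_size: int = 100,
) -> WallFit:
    """Two-stage wall-repulsion fit.

    Stage 1 smooths the (z, omega_c) scatter with a locally weighted
    (degree-1) LOESS regression; stage 2 fits ``A*exp(B*z)`` to the LOESS
    curve evaluated on an even grid over the observed abscissa range, with
    (A, B) initialized from a log-linear fit to the positive part of the
    curve.  Standard errors come from the stage-2 least-squares covariance.
    """
    z = np.asarray(z, dtype=float)
    omega_c = np.asarray(omega_c, dtype=float)
    if len(z) < 50:
        raise ValueError("need at least 50 samples")
    if mode not in ("distance", "time"):
        raise ValueError("mode must be 'distance' or 'time'")
    smoothed = lowess(omega_c, z, frac=loess_span, return_sorted=True)
    zs, ys = smoothed[:, 0], smoothed[:, 1]
    grid = np.linspace(zs.min(), zs.max(), grid_size)
    curve = np.interp(grid, zs, ys)
    pos = curve > 0
    if not pos.any():
        raise ValueError("no repulsive signal: LOESS curve is non-positive everywhere")
    slope, intercept = np.polyfit(grid[pos], np.log(curve[pos]), 1)
    p0 = (math.exp(intercept), slope)
    popt, pcov = curve_fit(
        lambda zz, A, B: A * np.exp(B * zz), grid, curve, p0=p0, maxfev=10000
    )
    se = np.sqrt(np.diag(pcov))
    return WallFit(
        A=float(popt[0]), B=float(popt[1]), se_A=float(se[0]), se_B=float(se[1]), mode=mode
    )


def estimate_sigma0(max_omega: float, theta_omega: float) -> float:
    """Turning-noise saturation sigma0 = max_omega * sqrt(2*theta_omega) / 2.

    Chosen so that the stationary standard deviation of an O-U process with
    amplitude sigma0 equals max_omega / 2, i.e. max_omega sits at the
    2-sigma boundary of the stationary turning-speed distribution.
    """
    if max_omega <= 0 or theta_omega <= 0:
        raise ValueError("max_omega and theta_omega must be positive")
    return max_omega * math.sqrt(2.0 * theta_omega) / 2.0


def wall_samples_from_trajectory(
    traj: Trajectory, arena: Arena, mode: str = "distance"
) -> tuple[np.ndarray, np.ndarray]:
    """Pool (z, omega_c) pairs from one trajectory for the wall fit.

    For each sample with nonzero speed and measurable turning, the
    projected collision is computed from the sample's position and heading
    and the turning speed is signed by whether the turn steers away from
    the projected collision.  ``z`` is d_W (cm) in distance mode or t_W (s)
    in time mode; infinite t_W samples are dropped.
    """
    kin = compute_kinematics(traj)
    zs, ws = [], []
    for k in range(len(traj)):
        if kin.omega_mask[k] or kin.u[k] <= 0:
            continue
        if not arena.contains(traj.x[k], traj.y[k]):
            continue
        proj = arena.project_collision(traj.x[k], traj.y[k], kin.phi[k], kin.u[k])
        z = proj.d_w if mode == "distance" else proj.t_w
        if not math.isfinite(z):
            continue
        zs.append(z)
        ws.append(wall_corrected_turning(kin.omega[k], proj.phi_w))
    return np.asarray(zs), np.asarray(ws)
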