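"""Stochastic walker simulation.

The walker carries four state variables: speed ``U`` (cm/s), turning speed
``Omega`` (rad/s), heading ``phi`` and position.  Speed and turning speed
follow coupled Ornstein-Uhlenbeck equations

    dU = theta_u (mu_u - U) dt + sigma_u dW
    dOmega = theta_w (mu_w + f_W - Omega) dt + f_c(U) dZ

integrated with the Euler-Maruyama scheme.  ``f_W`` biases the turning
equilibrium away from the projected wall collision (exponential in the
collision distance), and ``f_c`` ties the turning-noise amplitude to the
current speed: large-variance turning is available only at low speed,
reproducing the burst-and-coast signature of small fish.  A hard boundary
makes wall crossings fully inelastic: the position is reverted and the
speed set to zero.

Each step the heading advances by ``Omega * dt`` (wrapped to [-pi, pi)) and
the position by ``U * dt`` along the new heading; the trajectory's velocity
samples are backwards differences of position, so their norms equal the
latent speed away from collision steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .arena import Arena
from .calibration import OUParams
from .kinematics import Trajectory
from . import params as defaults

__all__ = [
    "ModelParams",
    "SimulationConfig",
    "WalkerState",
    "SimulationResult",
    "coupling_fc",
    "wall_force_fw",
    "em_step",
    "run_simulation",
    "simulate_ou_em",
]


@dataclass
class ModelParams:
    """Full walker parameterization.

    speed, turn : O-U triples for U and Omega.
    sigma0 : turning-noise saturation (rad s^-3/2); must exceed turn.sigma
        when the processes are coupled.
    A, B : wall-avoidance amplitude (rad/s) and decay (1/cm, <= 0).
    coupled : replace the constant turning noise sigma_omega by f_c(U).
    """

    speed: OUParams
    turn: OUParams
    sigma0: float = defaults.SIGMA0
    A: float = defaults.WALL_A_SIM
    B: float = defaults.WALL_B
    coupled: bool = True

    def __post_init__(self):
        if self.coupled and not self.sigma0 > self.turn.sigma:
            raise ValueError("sigma0 must exceed the turning-noise amplitude sigma_omega")
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if self.B > 0:
            raise ValueError("B must be <= 0 (decaying repulsion)")

    @classmethod
    def default(cls, **overrides) -> "ModelParams":
        """Global calibrated parameter bundle (copies, safe to mutate)."""
        kw = dict(
            speed=replace(defaults.GLOBAL_SPEED), turn=replace(defaults.GLOBAL_TURN)
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def for_fish(cls, fish: str, **overrides) -> "ModelParams":
        """Per-fish calibrated bundle (labels F1..F10, minus F4/F8)."""
        kw = dict(
            speed=replace(defaults.FISH_SPEED[fish]),
            turn=replace(defaults.FISH_TURN[fish]),
        )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "speed": self.speed.to_dict(),
            "turn": self.turn.to_dict(),
            "sigma0": self.sigma0,
            "A": self.A,
            "B": self.B,
            "coupled": self.coupled,
        }

    @classmethod
    def from_dict(cls, d) -> "ModelParams":
        return cls(
            speed=OUParams.from_dict(d["speed"]),
            turn=OUParams.from_dict(d["turn"]),
            sigma0=float(d.get("sigma0", defaults.SIGMA0)),
            A=float(d.get("A", defaults.WALL_A_SIM)),
            B=float(d.get("B", defaults.WALL_B)),
            coupled=bool(d.get("coupled", True)),
        )


@dataclass
class SimulationConfig:
    """Run settings.

    arena=None disables both the wall bias and the hard boundary
    (free-space walker).  init_policy "random" draws the start position
    uniformly in the arena with uniform heading; "fixed" starts at the
    given state.  omega_clamp may be ``math.inf`` to disable the cut-off.
    """

    dt: float = defaults.DT
    duration: float = 300.0
    seed: int = 0
    omega_clamp: float = defaults.OMEGA_CLAMP
    arena: Arena | None = field(default_factory=Arena)
    init_policy: str = "random"
    x0: float = 0.0
    y0: float = 0.0
    phi0: float = 0.0

    def __post_init__(self):
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")
        if self.omega_clamp <= 0:
            raise ValueError("omega_clamp must be positive")
        if self.init_policy not in ("random", "fixed"):
            raise ValueError("init_policy must be 'random' or 'fixed'")


@dataclass
class WalkerState:
    x: float
    y: float
    phi: float
    U: float
    Omega: float
    t: float = 0.0


@dataclass
class SimulationResult:
    trajectory: Trajectory
    t: np.ndarray
    U: np.ndarray
    Omega: np.ndarray
    phi: np.ndarray
    collisions: np.ndarray


def coupling_fc(U: float, sigma_omega: float, sigma0: float, mu_u: float):
    """Speed-dependent turning-noise amplitude.

    f_c(U) = sigma0 * (2*sigma0/sigma_omega)^(-U/mu_u): equals sigma0 for a
    stationary walker, sigma_omega/2 at the equilibrium speed, and decays
    to zero as U grows.
    """
    if not (sigma0 > sigma_omega > 0):
        raise ValueError("need sigma0 > sigma_omega > 0")
    if mu_u <= 0:
        raise ValueError("mu_u must be positive")
    U = np.asarray(U, dtype=float)
    if np.any(U < 0):
        raise ValueError("U must be non-negative")
    out = sigma0 * (2.0 * sigma0 / sigma_omega) ** (-U / mu_u)
    return float(out) if out.ndim == 0 else out


def wall_force_fw(phi_w, d_w, A: float, B: float):
    """Wall-avoidance turning bias sgn(phi_w) * A * exp(B * d_w).

    Positive when a left (anticlockwise) turn steers away from the
    projected collision; magnitude at most A and decaying with distance.
    """
    phi_w = np.asarray(phi_w, dtype=float)
    d_w = np.asarray(d_w, dtype=float)
    out = np.sign(phi_w) * A * np.exp(B * d_w)
    return float(out) if out.ndim == 0 else out


def em_step(
    state: WalkerState,
    params: ModelParams,
    cfg: SimulationConfig,
    noise: tuple[float, float],
) -> WalkerState:
    """One Euler-Maruyama step of the full walker.

    Order of operations: wall projection from the current state; speed
    update (floored at 0); turning-speed update with the wall bias and the
    noise amplitude evaluated at the pre-update speed (clamped to
    +-omega_clamp); heading update with the new turning speed; position
    update with the new heading and speed; inelastic hard-boundary check
    (position and heading reverted, speed zeroed on a crossing).
    """
    z1, z2 = noise
    dt = cfg.dt
    sp, tu = params.speed, params.turn
    fw = 0.0
    if cfg.arena is not None and params.A > 0:
        proj = cfg.arena.project_collision(state.x, state.y, state.phi, state.U)
        fw = wall_force_fw(proj.phi_w, proj.d_w, params.A, params.B)
    sqdt = math.sqrt(dt)
    U_new = state.U + sp.theta * (sp.mu - state.U) * dt + sp.sigma * sqdt * z1
    U_new = max(U_new, 0.0)
    amp = (
        coupling_fc(state.U, tu.sigma, params.sigma0, sp.mu)
        if params.coupled
        else tu.sigma
    )
    Om_new = state.Omega + tu.theta * (tu.mu + fw - state.Omega) * dt + amp * sqdt * z2
    if math.isfinite(cfg.omega_clamp):
        Om_new = min(max(Om_new, -cfg.omega_clamp), cfg.omega_clamp)
    phi_new = (state.phi + math.pi + Om_new * dt) % (2.0 * math.pi) - math.pi
    x_new = state.x + U_new * dt * math.cos(phi_new)
    y_new = state.y + U_new * dt * math.sin(phi_new)
    if cfg.arena is not None and not cfg.arena.contains(x_new, y_new):
        # fully inelastic collision: stay put, stop, keep heading
        return WalkerState(state.x, state.y, state.phi, 0.0, Om_new, state.t + dt)
    return WalkerState(x_new, y_new, phi_new, U_new, Om_new, state.t + dt)


def run_simulation(params: ModelParams, cfg: SimulationConfig) -> SimulationResult:
    """Iterate the walker for duration/dt steps.

    Reproducible for a fixed seed: one generator drives the run, with two
    standard-normal draws per step (speed first, then turning).  Initial
    speed is mu_u and initial turning speed 0; position/heading follow
    ``cfg.init_policy``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration / cfg.dt))
    if cfg.init_policy == "random":
        if cfg.arena is not None:
            x0, y0 = cfg.arena.sample_position(rng)
        else:
            x0, y0 = 0.0, 0.0
        phi0 = float(rng.uniform(-math.pi, math.pi))
    else:
        x0, y0, phi0 = cfg.x0, cfg.y0, cfg.phi0
    state = WalkerState(x=x0, y=y0, phi=phi0, U=params.speed.mu, Omega=0.0)
    noise = rng.standard_normal((n, 2))
    t = np.arange(n + 1) * cfg.dt
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    Us = np.empty(n + 1)
    Oms = np.empty(n + 1)
    phis = np.empty(n + 1)
    collisions = np.zeros(n + 1, dtype=bool)
    xs[0], ys[0], Us[0], Oms[0], phis[0] = state.x, state.y, state.U, state.Omega, state.phi
    for k in range(n):
        prev_x, prev_y = state.x, state.y
        state = em_step(state, params, cfg, (noise[k, 0], noise[k, 1]))
        xs[k + 1], ys[k + 1] = state.x, state.y
        Us[k + 1], Oms[k + 1], phis[k + 1] = state.U, state.Omega, state.phi
        collisions[k + 1] = state.U == 0.0 and state.x == prev_x and state.y == prev_y
    vx = np.empty(n + 1)
    vy = np.empty(n + 1)
    vx[1:] = np.diff(xs) / cfg.dt
    vy[1:] = np.diff(ys) / cfg.dt
    vx[0] = Us[0] * math.cos(phis[0])
    vy[0] = Us[0] * math.sin(phis[0])
    traj = Trajectory(t, xs, ys, vx, vy, subject_id="walker")
    return SimulationResult(trajectory=traj, t=t, U=Us, Omega=Oms, phi=phis, collisions=collisions)


def simulate_ou_em(
    params: OUParams, n: int, dt: float, seed: int | np.random.Generator = 0, x0: float | None = None
) -> np.ndarray:
    """Euler-Maruyama integration of a single (uncoupled) O-U process.

    Vectorized AR(1) recursion x_{k+1} = x_k + theta*(mu-x_k)*dt +
    sigma*sqrt(dt)*z_k; used for discretization checks against the exact
    sampler.  ``x0`` defaults to a stationary draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = 1.0 - params.theta * dt
    if not (-1.0 < a < 1.0):
        raise ValueError("theta*dt too large: explicit Euler unstable")
    if x0 is None:
        x0 = params.mu + math.sqrt(params.stationary_var) * rng.standard_normal()
    z = rng.standard_normal(n - 1)
    # y_k = a*y_{k-1} + w_k with y = x - mu and w_k = sigma*sqrt(dt)*z_k
    w = np.concatenate(([x0 - params.mu], params.sigma * math.sqrt(dt) * z))
    y = lfilter([1.0], [1.0, -a], w)
    return params.mu + y
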