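"""Walker dynamics: coupling, wall bias, Euler-Maruyama integration."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from finwalk import (
    Arena,
    ModelParams,
    OUParams,
    SimulationConfig,
    WalkerState,
    coupling_fc,
    em_step,
    gen_ou_exact,
    run_simulation,
    simulate_ou_em,
    wall_force_fw,
)

TURN = OUParams(-0.02, 2.74, 2.85)


def _free_cfg(**kw):
    kw.setdefault("arena", None)
    kw.setdefault("init_policy", "fixed")
    return SimulationConfig(**kw)


class TestCouplingFc:
    def test_stationary_limit_is_sigma0(self):
        assert coupling_fc(0.0, 2.85, 12.0, 14.02) == pytest.approx(12.0)

    def test_at_mean_speed_is_half_sigma_omega(self):
        assert coupling_fc(14.02, 2.85, 12.0, 14.02) == pytest.approx(2.85 / 2)

    def test_double_mean_speed(self):
        got = coupling_fc(28.04, 2.85, 12.0, 14.02)
        assert got == pytest.approx(12.0 * (24.0 / 2.85) ** -2, rel=1e-12)
        assert got == pytest.approx(0.1692, abs=1e-4)

    def test_strictly_decreasing_and_positive(self):
        u = np.linspace(0.0, 60.0, 200)
        vals = coupling_fc(u, 2.85, 12.0, 14.02)
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) < 0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            coupling_fc(1.0, 12.0, 2.85, 14.02)  # sigma0 < sigma_omega
        with pytest.raises(ValueError):
            coupling_fc(-1.0, 2.85, 12.0, 14.02)


class TestWallForce:
    def test_contact_amplitude(self):
        assert wall_force_fw(0.5, 0.0, 6.75, -0.11) == pytest.approx(6.75)

    def test_antisymmetric(self):
        d = np.linspace(0.0, 60.0, 50)
        assert np.allclose(
            wall_force_fw(0.3, d, 6.75, -0.11), -wall_force_fw(-0.3, d, 6.75, -0.11)
        )

    def test_amplified_value_at_ten_cm(self):
        assert wall_force_fw(1.0, 10.0, 6.75, -0.11) == pytest.approx(
            6.75 * math.exp(-1.1), rel=1e-12
        )

    def test_bounded_by_amplitude(self, rng):
        phi_w = rng.uniform(-math.pi, math.pi, 100)
        d = rng.uniform(0.0, 120.0, 100)
        assert np.all(np.abs(wall_force_fw(phi_w, d, 6.75, -0.11)) <= 6.75)


class TestModelParams:
    def test_sigma0_must_dominate_sigma_omega(self):
        with pytest.raises(ValueError, match="sigma0"):
            ModelParams(speed=OUParams(14, 0.6, 4.2), turn=TURN, sigma0=2.0)

    def test_uncoupled_skips_sigma0_check(self):
        ModelParams(speed=OUParams(14, 0.6, 4.2), turn=TURN, sigma0=2.0, coupled=False)

    def test_json_round_trip(self):
        p = ModelParams.default()
        assert ModelParams.from_dict(p.to_dict()) == p


class TestEmStep:
    def test_deterministic_straight_line(self):
        params = ModelParams(
            speed=OUParams(14.02, 0.59, 0.0),
            turn=OUParams(0.0, 2.74, 0.0),
            coupled=False,
            A=0.0,
        )
        cfg = _free_cfg(duration=1.0)
        state = WalkerState(x=0.0, y=0.0, phi=0.0, U=14.02, Omega=0.0)
        state = em_step(state, params, cfg, (0.0, 0.0))
        assert state.x == pytest.approx(14.02 * 0.2)
        assert state.y == 0.0 and state.phi == 0.0
        assert state.U == pytest.approx(14.02)

    def test_deterministic_omega_recursion(self):
        # with all noise off, Omega follows the explicit Euler geometric decay
        mu_w, theta_w, om0 = 0.5, 2.74, 3.0
        params = ModelParams(
            speed=OUParams(14.02, 0.59, 0.0),
            turn=OUParams(mu_w, theta_w, 0.0),
            coupled=False,
            A=0.0,
        )
        cfg = _free_cfg(duration=1.0)
        state = WalkerState(x=0.0, y=0.0, phi=0.0, U=14.02, Omega=om0)
        for k in range(1, 6):
            state = em_step(state, params, cfg, (0.0, 0.0))
            expect = mu_w + (om0 - mu_w) * (1 - theta_w * 0.2) ** k
            assert state.Omega == pytest.approx(expect, rel=1e-12)

    def test_hard_boundary_inelastic(self, arena):
        params = ModelParams.default()
        cfg = SimulationConfig(duration=1.0, arena=arena, init_policy="fixed")
        state = WalkerState(x=59.5, y=0.0, phi=0.0, U=14.0, Omega=0.0)
        new = em_step(state, params, cfg, (0.5, -0.3))
        assert (new.x, new.y) == (59.5, 0.0)
        assert new.U == 0.0
        assert new.phi == state.phi

    def test_speed_floor(self):
        params = ModelParams.default(coupled=False)
        cfg = _free_cfg(duration=1.0)
        state = WalkerState(x=0.0, y=0.0, phi=0.0, U=0.5, Omega=0.0)
        new = em_step(state, params, cfg, (-10.0, 0.0))
        assert new.U == 0.0

    def test_omega_clamp(self):
        params = ModelParams.default()
        cfg = _free_cfg(duration=1.0, omega_clamp=15.0)
        state = WalkerState(x=0.0, y=0.0, phi=0.0, U=0.0, Omega=14.0)
        new = em_step(state, params, cfg, (0.0, 50.0))
        assert new.Omega == 15.0


class TestRunSimulation:
    def test_same_seed_identical(self):
        params = ModelParams.default()
        cfg = SimulationConfig(duration=30.0, seed=99)
        a = run_simulation(params, cfg)
        b = run_simulation(params, cfg)
        assert np.array_equal(a.trajectory.x, b.trajectory.x)
        assert np.array_equal(a.Omega, b.Omega)

    def test_state_invariants_inside_arena(self, default_run):
        res, cfg = default_run
        assert np.all(res.phi >= -math.pi) and np.all(res.phi < math.pi)
        assert np.all(np.abs(res.Omega) <= 15.0)
        assert np.all(cfg.arena.contains(res.trajectory.x, res.trajectory.y))
        assert np.all(res.U >= 0.0)

    def test_stationary_moments_free_space(self):
        """Long uncoupled run: U relaxes to mu_u; Omega variance matches the
        AR(1) closed form sigma^2 / (theta * (2 - theta*dt))."""
        params = ModelParams(
            speed=OUParams(14.02, 0.59, 4.21), turn=TURN, coupled=False, A=0.0
        )
        cfg = _free_cfg(duration=2e4, seed=21, omega_clamp=math.inf)
        res = run_simulation(params, cfg)
        burn = 500
        u = res.U[burn:]
        # autocorrelation-aware standard error of the mean
        var_u = params.speed.sigma**2 / (params.speed.theta * (2 - params.speed.theta * 0.2))
        tau_u = 1.0 / params.speed.theta
        se = math.sqrt(2 * var_u * tau_u / (len(u) * 0.2))
        assert abs(u.mean() - 14.02) < 3 * se
        om = res.Omega[burn:]
        var_om = params.turn.sigma**2 / (params.turn.theta * (2 - params.turn.theta * 0.2))
        assert om.var() == pytest.approx(var_om, rel=0.05)

    def test_em_matches_exact_sampler_at_fine_step(self):
        """Euler-Maruyama converges in distribution to the exact O-U chain."""
        dt = 1e-3
        em = simulate_ou_em(TURN, n=1_000_000, dt=dt, seed=3)[::100]
        exact = gen_ou_exact(TURN, n=10_000, dt=0.1, seed=4)
        assert sps.ks_2samp(em, exact).pvalue > 0.01

    def test_coupling_narrows_fast_turning(self):
        """Conditional spread of Omega shrinks at high speed (joint-density
        asymmetry produced by the speed-dependent noise)."""
        params = ModelParams.default(A=0.0)
        cfg = _free_cfg(duration=4000.0, seed=17)
        res = run_simulation(params, cfg)
        fast = res.Omega[res.U > params.speed.mu]
        slow = res.Omega[res.U < params.speed.mu]
        assert fast.std() < slow.std()

    def test_thigmotaxis_ranking_by_noise_persistence_ratio(self):
        """Wall-following emerges for sigma_omega/theta_omega < 1: those
        walkers sit closer to the boundary on average."""
        arena = Arena()

        def mean_wall_distance(fish):
            params = ModelParams.for_fish(fish)
            cfg = SimulationConfig(duration=1500.0, seed=31, arena=arena)
            res = run_simulation(params, cfg)
            return np.mean(
                [
                    arena.boundary_distance(x, y)
                    for x, y in zip(res.trajectory.x[200:], res.trajectory.y[200:])
                ]
            )

        followers = np.mean([mean_wall_distance(f) for f in ("F6", "F7", "F10")])
        roamers = np.mean([mean_wall_distance(f) for f in ("F1", "F2", "F5")])
        assert followers < roamers
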