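import numpy as np
import pytest

from stemwave.manifold import solve_v_alpha
from stemwave.pde import (ContinuumParams, make_grid, solve_fast, solve_full,
                          solve_slow, solve_treatment)
from stemwave.treatment import build_schedule
from stemwave.waves import invasion_step, measure_speed, theoretical_speed


class TestFastSystem:
    def test_empty_state_is_fixed_point(self):
        ts, v = solve_fast(0.0, 0.0, alpha=0.7, t_end=50.0)
        assert np.all(v == 0.0)

    def test_relaxes_onto_manifold_from_below_and_above(self):
        target = solve_v_alpha(0.25, 0.5)
        for v0 in (0.1, 0.6):
            ts, v = solve_fast(0.25, v0, alpha=0.5, t_end=200.0)
            assert v[-1] == pytest.approx(target, abs=1e-6)
            # monotone relaxation toward the manifold
            drift = np.diff(v)
            assert np.all(drift >= -1e-9) if v0 < target else np.all(drift <= 1e-9)

    def test_rejects_overfull_state(self):
        with pytest.raises(ValueError):
            solve_fast(0.7, 0.5, alpha=1.0)


class TestSlowSystem:
    def test_extinction_is_invariant(self):
        x = make_grid(20, 0.2)
        res = solve_slow(ContinuumParams(alpha=0.5), x, np.zeros_like(x), 10.0)
        assert np.all(res.u == 0.0)
        assert np.all(res.v == 0.0)

    def test_mass_grows_and_bounds_hold(self):
        x = make_grid(60, 0.2)
        u0 = invasion_step(x, edge=10.0)
        res = solve_slow(ContinuumParams(alpha=0.8), x, u0, 15.0)
        mass = res.u.sum(axis=1)
        assert np.all(np.diff(mass) > 0.0)  # reaction term is a source
        assert res.u.min() >= -1e-6
        assert (res.u + res.v).max() <= 1.0 + 1e-3

    def test_front_speed_near_minimal_speed(self):
        x = make_grid(60, 0.2)
        u0 = invasion_step(x, edge=10.0)
        res = solve_slow(ContinuumParams(alpha=1.0), x, u0, 20.0,
                         np.linspace(0, 20, 41))
        est = measure_speed(res.t, res.x, res.u)
        # pulled fronts approach 2*sqrt(d) from below on finite windows
        assert 1.6 < est.speed < 2.0 + 1e-3

    def test_speed_scales_as_sqrt_diffusion(self):
        speeds = {}
        for d in (1.0, 4.0):
            x = make_grid(120, 0.25)
            u0 = invasion_step(x, edge=15.0)
            res = solve_slow(ContinuumParams(alpha=0.5, d=d), x, u0, 28.0,
                             np.linspace(0, 28, 29))
            speeds[d] = measure_speed(res.t, res.x, res.u).speed
        assert speeds[4.0] / speeds[1.0] == pytest.approx(2.0, rel=0.02)

    def test_mesh_refinement_convergence(self):
        speeds = {}
        for dx in (0.2, 0.1):
            x = make_grid(80, dx)
            u0 = invasion_step(x, edge=15.0)
            res = solve_slow(ContinuumParams(alpha=0.5), x, u0, 35.0,
                             np.linspace(0, 35, 36))
            speeds[dx] = measure_speed(res.t, res.x, res.u).speed
        assert abs(speeds[0.1] - speeds[0.2]) / speeds[0.1] < 0.005


class TestFullSystem:
    def test_homogeneous_state_converges_to_slow_manifold(self):
        x = make_grid(40, 0.2)
        u0 = np.full_like(x, 0.3)
        v0 = np.full_like(x, 0.1)
        res = solve_full(ContinuumParams(alpha=1.0, epsilon=0.01), x, u0, v0,
                         30.0, np.linspace(0, 30, 7))
        u_end = float(res.u[-1, len(x) // 2])
        v_end = float(res.v[-1, len(x) // 2])
        assert v_end == pytest.approx(solve_v_alpha(u_end, 1.0), abs=5e-3)

    def test_front_speed_approaches_slow_limit_as_epsilon_shrinks(self):
        x = make_grid(60, 0.25)
        u0 = invasion_step(x, edge=10.0)
        res = solve_slow(ContinuumParams(alpha=1.0), x, u0, 16.0,
                         np.linspace(0, 16, 33))
        s_slow = measure_speed(res.t, x, res.u).speed
        gaps = {}
        for eps in (0.2, 0.05):
            t_end = 16.0 / eps
            full = solve_full(ContinuumParams(alpha=1.0, epsilon=eps), x, u0,
                              np.zeros_like(u0), t_end,
                              np.linspace(0, t_end, 33))
            s_full = measure_speed(full.t, x, full.u).speed / eps
            gaps[eps] = abs(s_full - s_slow)
        assert gaps[0.05] < gaps[0.2]

    def test_requires_positive_epsilon(self):
        x = make_grid(10, 0.5)
        with pytest.raises(ValueError, match="epsilon"):
            solve_full(ContinuumParams(alpha=1.0, epsilon=0.0), x,
                       np.zeros_like(x), np.zeros_like(x), 1.0)


class TestTreatmentSystem:
    def test_empty_schedule_reduces_to_slow_system(self):
        x = make_grid(40, 0.2)
        u0 = invasion_step(x, edge=10.0)
        schedule = build_schedule("none", baseline_alpha=0.5)
        res_t = solve_treatment(ContinuumParams(alpha=0.5), schedule, x, u0,
                                12.0, np.linspace(0, 12, 13))
        res_s = solve_slow(ContinuumParams(alpha=0.5), x, u0, 12.0,
                           np.linspace(0, 12, 13))
        assert np.allclose(res_t.u[-1], res_s.u[-1], atol=1e-6)

    def test_switching_jumps_between_manifolds(self):
        # piecewise-constant fractionated hazard at a high dose rate:
        # v jumps onto the (much lower) treatment manifold when alpha_hat
        # switches, and back during treatment holidays
        from stemwave.treatment import HazardParams

        x = make_grid(10, 0.5)
        u0 = np.full_like(x, 0.3)
        hz = HazardParams(mode="fractionated", alpha_r=0.11, beta_r=0.019,
                          dose_per_fraction=8.0)
        schedule = build_schedule("frac-2-2", start=2.0, baseline_alpha=0.3,
                                  delta=0.1, hazard=hz)
        res = solve_treatment(ContinuumParams(alpha=0.3), schedule, x, u0,
                              10.0, np.linspace(0, 10, 101))
        i_node = 5
        t, v = res.t, res.v[:, i_node]
        on = np.array([schedule.T(tk) > 0 for tk in t])
        assert v[on].mean() < 0.5 * v[~on].mean()

    def test_nonlinear_crowding_rejected(self):
        x = make_grid(10, 0.5)
        schedule = build_schedule("none")
        with pytest.raises(NotImplementedError):
            solve_treatment(ContinuumParams(alpha=0.5, F="cosine"), schedule,
                            x, np.zeros_like(x), 1.0)
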