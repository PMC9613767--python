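import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemwave.crowding import CROWDING_FUNCTIONS, get_crowding
from stemwave.manifold import (ManifoldSingularityError, SlowManifold,
                               dv_dalpha_ordering, dv_du, solve_v_alpha,
                               v_alpha_linear, v_star)

from conftest import ALL_F


def brute_force_bisect(u, alpha, F, tol=1e-12):
    """Independent oracle: plain bisection of the implicit equation."""
    F = get_crowding(F)

    def g(v):
        Fn = F(u + v)
        return (alpha - Fn) * v - Fn * u

    lo, hi = 0.0, 1.0 - u
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if g(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestImplicitGraph:
    def test_capacity_edge_forces_zero(self):
        # F(1) = 0 makes alpha*v = 0 at u = 1
        assert solve_v_alpha(1.0, 0.5) == 0.0

    def test_closed_form_quadratic_value(self):
        # (alpha-1+u+v)v = (1-u-v)u at u=0.25, alpha=0.5 gives v^2 = 0.1875
        v = solve_v_alpha(0.25, 0.5)
        assert v == pytest.approx(np.sqrt(0.1875), abs=1e-10)
        assert v == pytest.approx(brute_force_bisect(0.25, 0.5, "linear"), abs=1e-9)

    def test_supercritical_death_connects_to_origin(self):
        # for alpha >= 1 the manifold endpoint is (0, 0)
        assert v_star(2.0) == 0.0
        assert solve_v_alpha(1e-8, 2.0) < 1e-7

    @pytest.mark.parametrize("name", ALL_F)
    def test_generic_root_agrees_with_bisection_oracle(self, name):
        rng = np.random.default_rng(7)
        for _ in range(25):
            u = float(rng.uniform(0.01, 0.99))
            alpha = float(rng.uniform(0.02, 4.0))
            v = solve_v_alpha(u, alpha, name)
            assert v == pytest.approx(
                brute_force_bisect(u, alpha, name), abs=1e-9
            )

    def test_closed_form_linear_matches_generic(self):
        u = np.linspace(0.001, 0.999, 201)
        for alpha in (0.05, 0.5, 1.0, 3.0):
            assert np.allclose(
                v_alpha_linear(u, alpha),
                solve_v_alpha(u, alpha, "linear"),
                atol=1e-10,
            )

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_v_alpha(1.2, 0.5)
        with pytest.raises(ValueError):
            solve_v_alpha(0.5, -1.0)
        with pytest.raises(ValueError):
            v_star(0.0)


class TestVStar:
    def test_is_root_of_crowding_equation(self):
        assert v_star(0.5) == pytest.approx(0.5, abs=1e-10)
        assert v_star(0.05) == pytest.approx(0.95, abs=1e-10)
        # bisection oracle on F(v) = alpha for a nonlinear family member
        F = CROWDING_FUNCTIONS["cosine"]
        vs = v_star(0.3, F)
        assert F(vs) == pytest.approx(0.3, abs=1e-9)

    def test_critical_and_supercritical_vanish(self):
        for name in ALL_F:
            assert v_star(1.0, name) == 0.0
            assert v_star(7.0, name) == 0.0


class TestSlope:
    def test_endpoint_slope_supercritical(self):
        # v'(0) = 1/(alpha-1) when alpha > 1
        assert dv_du(0.0, 2.0) == pytest.approx(1.0, abs=1e-9)

    def test_endpoint_slope_subcritical(self):
        # v'(0) = -(1 + alpha/(F'(v*)v*)); linear F, alpha=0.5 gives 0
        assert dv_du(0.0, 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_singular_endpoint_raises_or_reports_inf(self):
        with pytest.raises(ManifoldSingularityError):
            dv_du(0.0, 1.0)
        assert dv_du(0.0, 1.0, on_singularity="inf") == np.inf

    @pytest.mark.parametrize("name", ALL_F)
    def test_formula_matches_central_difference(self, name):
        h = 1e-7
        for alpha in (0.5, 2.0):
            for u in (0.1, 0.4, 0.75):
                fd = (
                    solve_v_alpha(u + h, alpha, name)
                    - solve_v_alpha(u - h, alpha, name)
                ) / (2 * h)
                assert dv_du(u, alpha, name) == pytest.approx(fd, abs=1e-6)

    def test_slope_always_above_minus_one(self):
        u = np.linspace(0.0, 1.0, 101)
        for name in ALL_F:
            for alpha in (0.05, 0.5, 1.5, 5.0):
                assert np.all(dv_du(u, alpha, name) > -1.0)


class TestAlphaOrdering:
    def test_larger_death_rate_lowers_manifold(self):
        v1, v2 = dv_dalpha_ordering(0.5, 1.0, 0.05)
        assert v1 < v2

    def test_equal_rates_give_equal_values(self):
        v1, v2 = dv_dalpha_ordering(0.5, 0.7, 0.7)
        assert v1 == v2

    def test_quadratic_roots_strictly_ordered(self):
        v1, v2 = dv_dalpha_ordering(0.25, 0.8, 0.5)
        assert v1 < v2
        assert v1 == pytest.approx(v_alpha_linear(0.25, 0.8), abs=1e-10)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    u=st.floats(0.001, 0.999),
    alpha=st.floats(0.02, 6.0),
    name=st.sampled_from(ALL_F),
)
def test_implicit_equation_residual_property(u, alpha, name):
    F = get_crowding(name)
    v = solve_v_alpha(u, alpha, F)
    residual = (alpha - F(u + v)) * v - F(u + v) * u
    assert abs(residual) < 1e-9
    assert 0.0 <= v <= 1.0 - u + 1e-12


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    u=st.floats(0.01, 0.99),
    a_small=st.floats(0.02, 5.0),
    bump=st.floats(0.01, 3.0),
    name=st.sampled_from(ALL_F),
)
def test_alpha_monotonicity_property(u, a_small, bump, name):
    v_hi, v_lo = dv_dalpha_ordering(u, a_small + bump, a_small, name)
    assert v_hi < v_lo


@pytest.mark.parametrize("name", ALL_F)
@pytest.mark.parametrize("alpha", [0.05, 0.5, 1.0, 5.0])
def test_total_density_increasing_and_linearly_determined(name, alpha):
    """n(u) = u + v_alpha(u) rises with u and stays above v*_alpha,
    which is exactly the sufficient condition for linear determinacy."""
    man = SlowManifold(alpha, name, n_table=513)
    u = man._grid
    n = u + man._values
    assert np.all(np.diff(n) > 0.0)
    assert np.all(n >= man.v_star - 1e-9)


def test_tabulated_interpolation_matches_exact_solution():
    for alpha in (0.5, 2.0):
        man = SlowManifold(alpha, "quartic")
        u = np.linspace(0.0, 1.0, 317)
        assert np.allclose(man.v(u), solve_v_alpha(u, alpha, "quartic"),
                           atol=1e-7)


def test_export_table_columns(tmp_path):
    man = SlowManifold(0.5, "linear", n_table=65)
    path = tmp_path / "manifold.csv"
    man.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "u,v_alpha,n,dv_du"
    df = man.tabulate()
    assert len(df) == 65
    assert df["v_alpha"].iloc[0] == pytest.approx(0.5, abs=1e-10)
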