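"""Method-of-lines solvers for the continuum CSC/TC system.

Four variants of the same two-species model are integrated on a uniform
1-D mesh with no-flux (reflecting) boundaries, which represent an
unbounded domain as long as the front stays interior:

``solve_full``      the scaled two-field system
                    u_t = eps d u_xx + eps F(n) u,
                    v_t = eps d v_xx + (1-eps) F(n) u + F(n) v - alpha v;
``solve_fast``      the fast subsystem at a single point (u frozen, v
                    relaxing onto the slow manifold);
``solve_slow``      the slow-time reduction on the manifold,
                    u_tau = d u_xx + F(u + v_alpha(u)) u, with v slaved;
``solve_treatment`` the slow reduction with time-dependent death rates
                    alpha_hat(t), b_hat(t) from a treatment schedule,
                    u_tau = d u_xx + F(u+v) u - b_hat u,
                    0 = F(u+v)(u+v) - alpha_hat v.

Spatial derivatives are second-order central differences; time stepping
is adaptive LSODA with a banded Jacobian, restarted at every treatment
breakpoint so the discontinuous switches never cross an integrator step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .crowding import CrowdingFunction, get_crowding
from .manifold import SlowManifold, solve_v_alpha, v_alpha_linear
from .treatment import TreatmentSchedule

__all__ = [
    "ContinuumParams",
    "ContinuumResult",
    "make_grid",
    "solve_slow",
    "solve_fast",
    "solve_full",
    "solve_treatment",
]

RTOL = 1e-8
ATOL = 1e-10
BOUND_TOL = 1e-6


@dataclass(frozen=True)
class ContinuumParams:
    """Parameters of the continuum model.

    ``d`` is the (order-one) diffusion coefficient of the slow scaling,
    ``alpha`` the spontaneous TC death rate, ``epsilon`` the
    scale-separation parameter (= the symmetric self-renewal probability
    p_s under the scaling; full system only) and ``delta`` the CSC
    radiosensitivity scale used by the treatment system.  The division
    rates gamma_u = gamma_v are fixed to 1, which transfers a unit of
    1/time onto F.
    """

    alpha: float = 0.5
    d: float = 1.0
    epsilon: float = 0.01
    F: CrowdingFunction = "linear"
    delta: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "F", get_crowding(self.F))
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    @property
    def p_s(self) -> float:
        return self.epsilon


@dataclass
class ContinuumResult:
    """Trajectory of the continuum fields on the mesh."""

    x: np.ndarray
    t: np.ndarray
    u: np.ndarray  # (nt, nx)
    v: np.ndarray  # (nt, nx)
    params: ContinuumParams
    kind: str = "slow"
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> np.ndarray:
        return self.u + self.v


def make_grid(length=200.0, dx=0.1):
    """Uniform mesh [0, length] with spacing dx (endpoint included)."""
    n = int(round(length / dx))
    return np.linspace(0.0, length, n + 1)


def _laplacian_factory(x):
    dx = x[1] - x[0]
    inv = 1.0 / dx ** 2

    def lap(u):
        out = np.empty_like(u)
        out[1:-1] = u[2:] - 2.0 * u[1:-1] + u[:-2]
        out[0] = 2.0 * (u[1] - u[0])  # no-flux ghosts
        out[-1] = 2.0 * (u[-2] - u[-1])
        return out * inv

    return lap


def _check_bounds(y, what, cap=1.0):
    lo, hi = float(np.min(y)), float(np.max(y))
    if lo < -BOUND_TOL or hi > cap + 1e-3:
        raise RuntimeError(
            f"density bounds violated in {what}: min={lo:.3e}, max={hi:.3e}"
        )


def _slaved_reaction(alpha, F, n_table=2049):
    """The reaction f(u) = F(u + v_alpha(u)) u on [0, 1].

    For the linear crowding function the slaved manifold has a closed
    form and f is evaluated exactly.  Otherwise f is tabulated once per
    (alpha, F) and interpolated with a monotone cubic on square-spaced
    nodes: v_alpha(u) ~ sqrt(u) near u = 0 for alpha >= 1, and the
    leading edge - which selects the pulled front speed - must be
    resolved there.  Outside [0, 1] the reaction vanishes (F clamps to 0
    at capacity, and negative round-off densities must not act as
    sources).
    """
    man = SlowManifold(alpha, F, n_table=n_table)
    if F.name == "linear":
        from .manifold import v_alpha_linear

        def f(u):
            uc = np.clip(u, 0.0, 1.0)
            n = uc + v_alpha_linear(uc, alpha)
            return np.where(
                (u <= 0.0) | (u >= 1.0), 0.0, np.maximum(1.0 - n, 0.0) * uc
            )

        return f, man

    grid = np.linspace(0.0, 1.0, n_table) ** 2
    vvals = solve_v_alpha(grid, alpha, F)
    fvals = F(grid + vvals) * grid
    fvals[-1] = 0.0
    interp = PchipInterpolator(grid, fvals, extrapolate=False)

    def f(u):
        uc = np.clip(u, 0.0, 1.0)
        return np.where((u <= 0.0) | (u >= 1.0), 0.0, interp(uc))

    return f, man


def _output_times(t_end, output_times, default_n=81):
    if output_times is None:
        return np.linspace(0.0, float(t_end), default_n)
    ot = np.asarray(output_times, dtype=float)
    if ot[0] > 0.0:
        ot = np.concatenate(([0.0], ot))
    return ot


def solve_slow(params, x, u0, tau_end, output_times=None):
    """Integrate the slow system on the manifold.

    Returns a :class:`ContinuumResult` whose ``v`` field is the slaved
    manifold value v_alpha(u); time is the slow time tau.
    """
    params = params if isinstance(params, ContinuumParams) else ContinuumParams(**params)
    x = np.asarray(x, dtype=float)
    u0 = np.asarray(u0, dtype=float)
    f, man = _slaved_reaction(params.alpha, params.F)
    lap = _laplacian_factory(x)
    d = params.d

    def rhs(t, u):
        return d * lap(u) + f(u)

    ts = _output_times(tau_end, output_times)
    sol = solve_ivp(
        rhs, (ts[0], ts[-1]), u0, method="LSODA", t_eval=ts,
        rtol=RTOL, atol=ATOL, lband=1, uband=1,
    )
    if not sol.success:
        raise RuntimeError(f"slow-system integration failed: {sol.message}")
    u = sol.y.T
    _check_bounds(u, "solve_slow")
    # the manifold limit v*(alpha) at u -> 0 only applies where stem cells
    # exist; report v = 0 on cell-free nodes
    v = np.where(u > 0.0, np.clip(man.v(np.clip(u, 0.0, 1.0)), 0.0, 1.0), 0.0)
    return ContinuumResult(x=x, t=ts, u=u, v=v, params=params, kind="slow")


def solve_fast(u_fixed, v0, alpha, F="linear", t_end=200.0, output_times=None):
    """Fast subsystem at one point: v' = F(u+v)(u+v) - alpha v, u frozen.

    The trajectory relaxes monotonically onto the slow manifold; the
    terminal value matches ``solve_v_alpha(u_fixed, alpha, F)``.
    Returns ``(t, v)`` arrays.
    """
    if not 0.0 <= u_fixed <= 1.0:
        raise ValueError("u_fixed must lie in [0, 1]")
    if u_fixed + v0 > 1.0 + 1e-12:
        raise ValueError("u_fixed + v0 must not exceed capacity 1")
    F = get_crowding(F)

    def rhs(t, v):
        n = u_fixed + v[0]
        return [F(n) * n - alpha * v[0]]

    ts = _output_times(t_end, output_times, default_n=201)
    sol = solve_ivp(rhs, (ts[0], ts[-1]), [v0], method="LSODA",
                    t_eval=ts, rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"fast-system integration failed: {sol.message}")
    return ts, sol.y[0]


def solve_full(params, x, u0, v0, t_end, output_times=None):
    """Integrate the full scaled two-field system (fast time t).

    The mesh must resolve the front width sqrt(eps d / max reaction rate);
    with eps small the (u, v) trajectories at each node approach the slow
    manifold.
    """
    params = params if isinstance(params, ContinuumParams) else ContinuumParams(**params)
    if params.epsilon <= 0:
        raise ValueError("solve_full requires epsilon > 0")
    x = np.asarray(x, dtype=float)
    nx = x.size
    lap = _laplacian_factory(x)
    F = params.F
    eps, d, alpha = params.epsilon, params.d, params.alpha

    # interleaved layout (u0, v0, u1, v1, ...) keeps the Jacobian banded
    def rhs(t, y):
        u = y[0::2]
        v = y[1::2]
        un = np.clip(u, 0.0, None)
        vn = np.clip(v, 0.0, None)
        Fn = F(un + vn)
        du = eps * d * lap(u) + eps * Fn * un
        dv = eps * d * lap(v) + (1.0 - eps) * Fn * un + Fn * vn - alpha * vn
        out = np.empty_like(y)
        out[0::2] = du
        out[1::2] = dv
        return out

    ts = _output_times(t_end, output_times)
    y0 = np.empty(2 * nx)
    y0[0::2] = np.asarray(u0, dtype=float)
    y0[1::2] = np.asarray(v0, dtype=float)
    sol = solve_ivp(rhs, (ts[0], ts[-1]), y0, method="LSODA", t_eval=ts,
                    rtol=RTOL, atol=ATOL, lband=2, uband=2)
    if not sol.success:
        raise RuntimeError(f"full-system integration failed: {sol.message}")
    u = sol.y[0::2].T
    v = sol.y[1::2].T
    _check_bounds(u + v, "solve_full")
    return ContinuumResult(x=x, t=ts, u=u, v=v, params=params, kind="full")


def _n_of_u_linear(u, alpha_hat):
    """Total density on the manifold for F = (1-n)+, closed form.

    From (1-n) n = alpha_hat (n - u):  n^2 + (alpha_hat - 1) n
    - alpha_hat u = 0.
    """
    u = np.clip(u, 0.0, 1.0)
    b = alpha_hat - 1.0
    n = 0.5 * (-b + np.sqrt(b * b + 4.0 * alpha_hat * u))
    return np.clip(n, u, 1.0)


def solve_treatment(params, schedule: TreatmentSchedule, x, u0, t_end,
                    output_times=None):
    """Integrate the slow treatment system.

    ``u_tau = d u_xx + F(u+v) u - b_hat(t) u`` with v slaved to the
    treatment manifold ``F(u+v)(u+v) = alpha_hat(t) v``; whenever the
    schedule switches, the states jump between the no-treatment and
    treatment manifolds.  Integration restarts at every window edge.
    Only the linear crowding function has a closed-form treated manifold;
    other F are rejected.
    """
    params = params if isinstance(params, ContinuumParams) else ContinuumParams(**params)
    if params.F.name != "linear":
        raise NotImplementedError(
            "solve_treatment supports the linear crowding function "
            "(closed-form treated manifold)"
        )
    x = np.asarray(x, dtype=float)
    lap = _laplacian_factory(x)
    d = params.d
    alpha = schedule.baseline_alpha

    def rhs(t, u):
        ah = schedule.alpha_hat(t)
        bh = schedule.b_hat(t)
        if ah <= 0:
            raise RuntimeError(f"alpha_hat(t={t}) = {ah} must stay positive")
        n = _n_of_u_linear(u, ah)
        Fn = np.maximum(1.0 - n, 0.0)
        un = np.clip(u, 0.0, None)
        return d * lap(u) + (Fn - bh) * un

    ts = _output_times(t_end, output_times)
    edges = schedule.breakpoints(float(ts[-1]))
    segments = list(zip(edges[:-1], edges[1:]))
    u_rows = [np.asarray(u0, dtype=float)]
    t_rows = [ts[0]]
    u_cur = np.asarray(u0, dtype=float)
    for (a, b) in segments:
        t_eval = ts[(ts > a) & (ts <= b)]
        # mid-window clock: evaluate hazards strictly inside (a, b)
        sol = solve_ivp(rhs, (a, b), u_cur, method="LSODA",
                        t_eval=t_eval if t_eval.size else None,
                        rtol=RTOL, atol=1e-12, lband=1, uband=1)
        if not sol.success:
            raise RuntimeError(
                f"treatment integration failed on [{a}, {b}]: {sol.message}"
            )
        u_cur = sol.y[:, -1] if sol.y.size else u_cur
        for tk, col in zip(sol.t, sol.y.T):
            if tk in t_rows:
                continue
            t_rows.append(tk)
            u_rows.append(col)
    t_arr = np.asarray(t_rows)
    u = np.vstack(u_rows)
    _check_bounds(u, "solve_treatment")
    ah = np.array([schedule.alpha_hat(tk) for tk in t_arr])
    n = _n_of_u_linear(np.clip(u, 0.0, 1.0), ah[:, None])
    v = np.clip(n - np.clip(u, 0.0, 1.0), 0.0, 1.0)
    v = np.where(u > 0.0, v, 0.0)
    res = ContinuumResult(x=x, t=t_arr, u=u, v=v, params=params,
                          kind="treatment",
                          meta={"protocol": schedule.protocol,
                                "delta": schedule.delta})
    return res
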