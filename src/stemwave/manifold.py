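"""The slow manifold of the fast CSC/TC dynamics.

On the fast time scale the stem-cell density u is frozen and the non-stem
density v relaxes onto the set

    M = {(u, v) : alpha * v = F(u + v) * (u + v)},

equivalently ``(alpha - F(u+v)) v = F(u+v) u``.  For every alpha > 0 the
set M is the graph of a function ``v_alpha(u)`` on [0, 1] with

* ``v_alpha(1) = 0`` and ``v_alpha(0) = v*_alpha``, where ``v*_alpha`` is 0
  for alpha >= 1 and otherwise the unique root of ``F(v) = alpha``;
* derivative ``v_alpha'(u) = (F'(n) n + F(n)) / (alpha - F'(n) n - F(n))``
  with ``n = u + v_alpha(u)``, always > -1, so the total density
  ``n(u) = u + v_alpha(u)`` is strictly increasing;
* pointwise monotonicity in alpha: a larger death rate pushes the
  manifold down (``alpha1 > alpha2  =>  v_alpha1(u) < v_alpha2(u)``).

The last two facts drive the invasion paradox: increasing alpha thins out
the non-stem population, which frees space and raises the effective
stem-cell growth rate F(v*_alpha) at the front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .crowding import CrowdingFunction, get_crowding

__all__ = [
    "solve_v_alpha",
    "v_alpha_linear",
    "v_star",
    "dv_du",
    "dv_dalpha_ordering",
    "SlowManifold",
    "ManifoldSingularityError",
]

#: absolute tolerance of the bracketed root finder
ROOT_TOL = 1e-12


class ManifoldSingularityError(ValueError):
    """The (alpha=1, u=0) endpoint, where the manifold slope diverges."""


def _validate(u, alpha):
    if not np.all((0.0 <= np.asarray(u)) & (np.asarray(u) <= 1.0)):
        raise ValueError(f"u must lie in [0, 1], got {u}")
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")


def v_star(alpha, F="linear"):
    """Endpoint value v*_alpha = lim_{u->0} v_alpha(u).

    Zero for alpha >= F(0) = 1; otherwise the unique root of F(v) = alpha
    in (0, 1).
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    F = get_crowding(F)
    if alpha >= 1.0:
        return 0.0
    return brentq(lambda v: F(v) - alpha, 0.0, 1.0, xtol=ROOT_TOL)


def v_alpha_linear(u, alpha):
    """Closed-form manifold graph for F = (1-n)+.

    Substituting F = 1-n into the implicit equation yields the quadratic
    v^2 + (alpha - 1 + 2u) v + u^2 - u = 0, whose admissible root is
    returned.  Vectorized; used as the fast path of the PDE solvers and as
    an independent cross-check of the generic root finder.
    """
    u = np.asarray(u, dtype=float)
    b = alpha - 1.0 + 2.0 * u
    v = 0.5 * (-b + np.sqrt(b * b + 4.0 * u * (1.0 - u)))
    v = np.clip(v, 0.0, 1.0 - np.clip(u, 0.0, 1.0))
    return v if v.ndim else float(v)


def solve_v_alpha(u, alpha, F="linear"):
    """Solve the implicit manifold equation for v_alpha(u).

    Brent's method on the bracket [0, 1-u]; the residual of
    ``(alpha - F(u+v)) v - F(u+v) u`` at the returned root is below
    ``ROOT_TOL`` scaled by the bracket.  At u = 0 the equation is
    degenerate and v*_alpha is returned by continuity.  Scalar or array u.
    """
    F = get_crowding(F)
    uu = np.asarray(u, dtype=float)
    _validate(uu, alpha)
    scalar = uu.ndim == 0
    uu = np.atleast_1d(uu)
    out = np.empty_like(uu)
    vs = None
    for i, ui in enumerate(uu):
        if ui == 0.0:
            if vs is None:
                vs = v_star(alpha, F)
            out[i] = vs
        elif ui >= 1.0:
            out[i] = 0.0
        else:
            def g(v, ui=ui):
                Fn = F(ui + v)
                return (alpha - Fn) * v - Fn * ui

            g0, g1 = g(0.0), g(1.0 - ui)
            if g0 > 0 or g1 < 0:
                raise ValueError(
                    "no sign change on [0, 1-u]: the crowding function "
                    "violates the monotone-decreasing assumptions"
                )
            out[i] = brentq(g, 0.0, 1.0 - ui, xtol=ROOT_TOL)
    return float(out[0]) if scalar else out


def dv_du(u, alpha, F="linear", on_singularity="raise"):
    """Slope of the manifold graph, by implicit differentiation.

    ``v_alpha'(u) = (F'(n) n + F(n)) / (alpha - F'(n) n - F(n))`` with
    ``n = u + v_alpha(u)``.  The slope is always > -1.  At the limiting
    endpoint (u=0, alpha=1) the slope diverges to +inf; by default this
    raises :class:`ManifoldSingularityError`, with
    ``on_singularity="inf"`` it returns ``numpy.inf`` (for plotting).
    """
    F = get_crowding(F)
    uu = np.asarray(u, dtype=float)
    _validate(uu, alpha)
    if np.any(uu == 0.0) and alpha == 1.0:
        if on_singularity == "inf":
            res = _dv_du_formula(np.maximum(uu, 1e-300), alpha, F)
            res = np.where(uu == 0.0, np.inf, res)
            return res if res.ndim else float(res)
        raise ManifoldSingularityError(
            "v_alpha'(0) diverges to +inf at alpha = 1"
        )
    return _dv_du_formula(uu, alpha, F)


def _dv_du_formula(u, alpha, F):
    v = solve_v_alpha(u, alpha, F)
    n = np.asarray(u, dtype=float) + v
    num = F.derivative(n) * n + F(n)
    den = alpha - num
    res = num / den
    return res if np.asarray(res).ndim else float(res)


def dv_dalpha_ordering(u, alpha1, alpha2, F="linear"):
    """Evaluate the manifold at two death rates and check the ordering.

    For ``alpha1 > alpha2`` the manifold for the larger death rate lies
    strictly lower: ``v_alpha1(u) < v_alpha2(u)`` for u in (0, 1).  Returns
    the pair ``(v_alpha1(u), v_alpha2(u))`` and raises if the ordering is
    violated (which would signal a root-finder defect, not a model
    property).
    """
    if not (0.0 < u < 1.0):
        raise ValueError(f"u must lie in (0, 1), got {u}")
    v1 = solve_v_alpha(u, alpha1, F)
    v2 = solve_v_alpha(u, alpha2, F)
    if alpha1 > alpha2 and not v1 < v2:
        raise AssertionError(
            f"manifold ordering violated: v_{alpha1}({u})={v1} !< v_{alpha2}({u})={v2}"
        )
    if alpha2 > alpha1 and not v2 < v1:
        raise AssertionError(
            f"manifold ordering violated: v_{alpha2}({u})={v2} !< v_{alpha1}({u})={v1}"
        )
    return v1, v2


@dataclass
class SlowManifold:
    """Tabulated manifold graph for a fixed (alpha, F) pair.

    Precomputes ``v_alpha`` on a uniform u-grid (2049 points by default)
    and interpolates with a monotone cubic (PCHIP), which preserves the
    monotonicity of n(u).  ``exact=True`` bypasses the table and re-solves
    the implicit equation per evaluation.
    """

    alpha: float
    F: CrowdingFunction = "linear"
    n_table: int = 2049
    _grid: np.ndarray = field(init=False, repr=False)
    _values: np.ndarray = field(init=False, repr=False)
    _interp: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self):
        self.F = get_crowding(self.F)
        self._grid = np.linspace(0.0, 1.0, self.n_table)
        if self.F.name == "linear":
            vals = v_alpha_linear(self._grid, self.alpha)
            vals[0] = v_star(self.alpha, self.F)
        else:
            vals = solve_v_alpha(self._grid, self.alpha, self.F)
        self._values = vals
        self._interp = PchipInterpolator(self._grid, vals, extrapolate=False)

    @property
    def v_star(self) -> float:
        return float(self._values[0])

    def v(self, u, exact=False):
        """v_alpha(u), from the table (default) or re-solved exactly."""
        if exact:
            return solve_v_alpha(u, self.alpha, self.F)
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        res = self._interp(u)
        return res if res.ndim else float(res)

    __call__ = v

    def n(self, u, exact=False):
        u = np.asarray(u, dtype=float)
        return np.clip(u, 0.0, 1.0) + self.v(u, exact=exact)

    def dv_du(self, u, on_singularity="raise"):
        return dv_du(u, self.alpha, self.F, on_singularity=on_singularity)

    def tabulate(self) -> pd.DataFrame:
        """Full table with columns u, v_alpha, n, dv_du."""
        with np.errstate(divide="ignore"):
            slope = np.array(
                [
                    dv_du(ui, self.alpha, self.F, on_singularity="inf")
                    for ui in self._grid
                ]
            )
        return pd.DataFrame(
            {
                "u": self._grid,
                "v_alpha": self._values,
                "n": self._grid + self._values,
                "dv_du": slope,
            }
        )

    def to_csv(self, path):
        self.tabulate().to_csv(path, index=False)
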