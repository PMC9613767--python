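"""Traveling-wave speeds: closed form and empirical front tracking.

On the slow manifold the stem-cell density obeys the scalar
reaction-diffusion equation

    u_tau = d u_xx + f(u),      f(u) = F(u + v_alpha(u)) u,

which is of Fisher-KPP (monostable) type: f(0) = f(1) = 0, f > 0 in
between, f'(0) = F(v*_alpha) > 0 and f'(1) < 0.  Because
f(u) <= f'(0) u (linear determinacy), invasion initial data converge to a
pulled front with the linearized minimal speed

    sigma* = 2 sqrt(d F(v*_alpha)) = { 2 sqrt(d),        alpha >= 1
                                     { 2 sqrt(d alpha),  alpha <  1.

For alpha < 1 the speed grows with the death rate alpha - the tumor
invasion paradox.

The empirical estimator tracks a level crossing of simulated density
profiles (PDE fields or ABM column populations) and fits front position
against time by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crowding import get_crowding
from .manifold import SlowManifold, v_star

__all__ = [
    "theoretical_speed",
    "WaveSpeedEstimate",
    "front_position",
    "measure_speed",
    "verify_kpp_form",
    "KppReport",
    "invasion_step",
    "synthetic_front",
]


def theoretical_speed(alpha, d=1.0, F="linear"):
    """Minimal wave speed 2*sqrt(d * F(v*_alpha)).

    Reduces to 2*sqrt(d) for alpha >= 1 and 2*sqrt(d*alpha) for alpha < 1
    (where F(v*_alpha) = alpha regardless of the shape of F); the two
    branches connect continuously at alpha = 1.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if not d > 0:
        raise ValueError(f"d must be positive, got {d}")
    F = get_crowding(F)
    return 2.0 * np.sqrt(d * F(v_star(alpha, F)))


def front_position(x, profile, threshold):
    """Rightmost crossing of ``threshold``, linearly interpolated.

    Returns ``nan`` when the profile never reaches the threshold, and
    ``x[-1]`` when the crossing sits on the right boundary (the caller
    decides whether that invalidates the estimate).  The rightmost (not
    leftmost) crossing is used so that non-monotone transients behind the
    front do not corrupt the position.
    """
    profile = np.asarray(profile, dtype=float)
    above = np.nonzero(profile >= threshold)[0]
    if above.size == 0:
        return np.nan
    i = above[-1]
    if i == len(x) - 1:
        return float(x[-1])
    y0, y1 = profile[i], profile[i + 1]
    if y0 == y1:  # flat segment at exactly the threshold
        return float(x[i])
    return float(x[i] + (y0 - threshold) / (y0 - y1) * (x[i + 1] - x[i]))


@dataclass
class WaveSpeedEstimate:
    """Least-squares front speed with its measurement context."""

    speed: float
    threshold: float
    window: tuple
    residual: float  # RMS of the linear fit, same units as x
    times: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    valid: bool = True
    message: str = ""


def measure_speed(times, x, profiles, threshold=None, window=None):
    """Estimate the front speed from a sequence of density profiles.

    Parameters
    ----------
    times : (nt,) array of snapshot times.
    x : (nx,) spatial grid.
    profiles : (nt, nx) array, one density profile per snapshot.
    threshold : level used for front detection; defaults to half the
        left-edge plateau of the final snapshot (mid-height crossing,
        robust against the slowly converging exponential leading edge).
    window : (t0, t1) fit interval; defaults to the final half of the
        simulation, after the wave has formed.

    Returns a :class:`WaveSpeedEstimate`.  Raises ``ValueError`` when
    fewer than 3 snapshots fall in the window or a profile in the window
    never crosses the threshold; a front that reaches the right boundary
    inside the window flags the estimate invalid (truncated domain)
    without raising.
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape != (times.size, x.size):
        raise ValueError("profiles must have shape (len(times), len(x))")
    if threshold is None:
        threshold = 0.5 * profiles[-1, 0]
    if window is None:
        window = (times[0] + 0.5 * (times[-1] - times[0]), times[-1])
    t0, t1 = window
    sel = (times >= t0) & (times <= t1)
    if sel.sum() < 3:
        raise ValueError(
            f"need at least 3 snapshots in the fit window {window}, have {sel.sum()}"
        )
    pos = np.array([front_position(x, p, threshold) for p in profiles[sel]])
    tt = times[sel]
    if np.any(np.isnan(pos)):
        raise ValueError(
            "a profile inside the fit window never crosses the threshold "
            f"{threshold}"
        )
    valid, message = True, ""
    if np.any(pos >= x[-1]):
        valid, message = False, "front reached the right boundary inside the window"
    coef = np.polyfit(tt, pos, 1)
    fit = np.polyval(coef, tt)
    residual = float(np.sqrt(np.mean((pos - fit) ** 2)))
    return WaveSpeedEstimate(
        speed=float(coef[0]),
        threshold=float(threshold),
        window=(float(t0), float(t1)),
        residual=residual,
        times=tt,
        positions=pos,
        valid=valid,
        message=message,
    )


@dataclass
class KppReport:
    """Outcome of the monostability / linear-determinacy check."""

    alpha: float
    F_name: str
    fprime0: float
    clauses: dict
    passed: bool


def verify_kpp_form(alpha, F="linear", n_grid=2001, tol=1e-9):
    """Check that f(u) = F(u + v_alpha(u)) u is of Fisher-KPP type.

    Evaluates, on a fine u-grid: f(0) = 0, f(1) = 0, f > 0 on (0, 1),
    f'(0) = F(v*_alpha) > 0, f'(1) < 0, and the linear-determinacy bound
    f(u) <= f'(0) u, equivalently n(u) >= v*_alpha.  Returns a
    :class:`KppReport` naming any failing clause.
    """
    F = get_crowding(F)
    man = SlowManifold(alpha, F)
    u = np.linspace(0.0, 1.0, n_grid)
    n = u + man.v(u, exact=False)
    f = F(n) * u
    fprime0 = float(F(man.v_star))
    # one-sided difference at u=1 for f'(1)
    h = u[1] - u[0]
    fprime1 = (f[-1] - f[-2]) / h
    clauses = {
        "f(0)=0": abs(f[0]) <= tol,
        "f(1)=0": abs(f[-1]) <= tol,
        "f>0 on (0,1)": bool(np.all(f[1:-1] > 0.0)),
        "f'(0)>0": fprime0 > 0.0,
        "f'(1)<0": fprime1 < 0.0,
        "linear determinacy f(u)<=f'(0)u": bool(
            np.all(f <= fprime0 * u + 1e-8)
        ),
    }
    return KppReport(
        alpha=alpha,
        F_name=F.name,
        fprime0=fprime0,
        clauses=clauses,
        passed=all(clauses.values()),
    )


def invasion_step(x, edge=20.0, level=1.0):
    """Step-shaped invasion initial condition: ``level`` for x <= edge."""
    x = np.asarray(x, dtype=float)
    return np.where(x <= edge, level, 0.0)


def synthetic_front(x, times, speed, width=1.0, x0=0.0, level=1.0):
    """Translating tanh front of exactly known speed.

    u(x, t) = level/2 * (1 - tanh((x - x0 - speed*t)/width)); used to
    validate the empirical speed estimator against ground truth.
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    return np.array(
        [0.5 * level * (1.0 - np.tanh((x - x0 - speed * t) / width)) for t in times]
    )
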