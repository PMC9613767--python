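"""Stochastic lattice model of stem-cell driven tumor growth.

Each site of a 500 x 50 grid holds at most one cell.  Cancer stem cells
(CSCs) are immortal and divide without limit; non-stem tumor cells (TCs)
carry a proliferative potential rho (15 at birth from an asymmetric CSC
division) that both daughters lose one unit of at every division, die
when an exhausted cell (rho = 0) draws a proliferation attempt, and are
additionally removed spontaneously at rate alpha/24 per Monte Carlo step
(one MCS = one hour, alpha given per day).

Per MCS every cell, in freshly shuffled order, (1) if a TC, dies
spontaneously with probability alpha/24; (2) with probability p = 1/24
attempts to proliferate - an exhausted TC dies, otherwise a daughter is
placed on a uniformly random vacant neighbor site if one exists (a CSC
daughter is a CSC with probability p_s, else a fresh TC); (3) migrates
with probability mu = 1 to a uniformly random vacant neighbor.  Each cell
acts at most once per MCS.  The neighborhood is 8-connected (Moore) by
default; rows wrap periodically (top/bottom), columns are closed.

Raising the TC death rate alpha frees space around the encased stem
cells, accelerating the invasion front - the tumor invasion paradox.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .waves import WaveSpeedEstimate, front_position, measure_speed

__all__ = [
    "EMPTY", "CSC", "TC",
    "AbmParams", "LatticeState", "AbmResult",
    "step", "run", "run_with_treatment",
    "continuous_protocol", "intermittent_protocol",
    "front_speed",
]

EMPTY, CSC, TC = 0, 1, 2


@dataclass(frozen=True)
class AbmParams:
    """Lattice-model parameters (rates per day are divided by 24 per MCS)."""

    nx: int = 500
    ny: int = 50
    mu: float = 1.0          # migration probability per MCS
    p_div: float = 1.0 / 24  # division probability per MCS
    rho_max: int = 15
    p_s: float = 0.01        # symmetric CSC self-renewal probability
    alpha: float = 0.0       # spontaneous TC death rate per DAY
    seed: int = 0
    neighborhood: str = "moore"

    def __post_init__(self):
        for name in ("mu", "p_div", "p_s"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.alpha < 0 or self.alpha / 24.0 > 1.0:
            raise ValueError("alpha must satisfy 0 <= alpha/24 <= 1")
        if self.neighborhood not in ("moore", "vonneumann"):
            raise ValueError("neighborhood must be 'moore' or 'vonneumann'")
        if self.rho_max < 0 or self.rho_max > 100:
            raise ValueError("rho_max out of range")


@dataclass
class LatticeState:
    """Occupancy grid plus per-MCS RNG stream.

    ``kind`` is 0 (empty), 1 (CSC) or 2 (TC); ``rho`` holds the remaining
    proliferative potential of TCs.  The single-occupancy invariant is
    structural: the grid representation cannot hold two cells per site.
    """

    kind: np.ndarray
    rho: np.ndarray
    mcs: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @classmethod
    def initial(cls, params: AbmParams) -> "LatticeState":
        """Seed one full column of CSCs at the left edge."""
        kind = np.zeros((params.nx, params.ny), dtype=np.int8)
        rho = np.zeros((params.nx, params.ny), dtype=np.int8)
        kind[0, :] = CSC
        return cls(kind=kind, rho=rho, mcs=0,
                   rng=np.random.default_rng(params.seed))

    def column_population(self) -> np.ndarray:
        return (self.kind != EMPTY).sum(axis=1).astype(np.int32)

    def counts(self):
        return int((self.kind == CSC).sum()), int((self.kind == TC).sum())


@njit(cache=True)
def _sweep(kind, rho, seed, mu, p_div, rho_max, p_s, alpha_mcs, moore):
    """One Monte Carlo step, in place.  Seeded per call for determinism."""
    np.random.seed(seed)
    nx, ny = kind.shape
    acted = np.zeros((nx, ny), dtype=np.uint8)
    xs = np.empty(nx * ny, dtype=np.int32)
    ys = np.empty(nx * ny, dtype=np.int32)
    nbx = np.empty(8, dtype=np.int32)
    nby = np.empty(8, dtype=np.int32)
    m = 0
    for x in range(nx):
        for y in range(ny):
            if kind[x, y] != EMPTY:
                xs[m] = x
                ys[m] = y
                m += 1
    # Fisher-Yates shuffle of the update order
    for i in range(m - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        xs[i], xs[j] = xs[j], xs[i]
        ys[i], ys[j] = ys[j], ys[i]
    for i in range(m):
        x = xs[i]
        y = ys[i]
        k = kind[x, y]
        if k == EMPTY or acted[x, y] == 1:
            continue  # the original occupant moved away or a mover sits here
        acted[x, y] = 1
        if k == TC and np.random.random() < alpha_mcs:
            kind[x, y] = EMPTY
            continue
        if np.random.random() < p_div:
            if k == TC and rho[x, y] == 0:
                kind[x, y] = EMPTY  # exhausted: apoptosis on this attempt
                continue
            nv = 0
            for dx in range(-1, 2):
                for dy in range(-1, 2):
                    if dx == 0 and dy == 0:
                        continue
                    if moore == 0 and dx != 0 and dy != 0:
                        continue
                    xx = x + dx
                    if xx < 0 or xx >= nx:
                        continue
                    yy = (y + dy) % ny
                    if kind[xx, yy] == EMPTY:
                        nbx[nv] = xx
                        nby[nv] = yy
                        nv += 1
            if nv > 0:
                c = np.random.randint(0, nv)
                tx = nbx[c]
                ty = nby[c]
                if k == CSC:
                    if np.random.random() < p_s:
                        kind[tx, ty] = CSC
                        rho[tx, ty] = 0
                    else:
                        kind[tx, ty] = TC
                        rho[tx, ty] = rho_max
                else:
                    rho[x, y] -= 1  # both daughters inherit rho - 1
                    kind[tx, ty] = TC
                    rho[tx, ty] = rho[x, y]
                acted[tx, ty] = 1  # newborns do not act this MCS
        if np.random.random() < mu:
            nv = 0
            for dx in range(-1, 2):
                for dy in range(-1, 2):
                    if dx == 0 and dy == 0:
                        continue
                    if moore == 0 and dx != 0 and dy != 0:
                        continue
                    xx = x + dx
                    if xx < 0 or xx >= nx:
                        continue
                    yy = (y + dy) % ny
                    if kind[xx, yy] == EMPTY:
                        nbx[nv] = xx
                        nby[nv] = yy
                        nv += 1
            if nv > 0:
                c = np.random.randint(0, nv)
                tx = nbx[c]
                ty = nby[c]
                kind[tx, ty] = kind[x, y]
                rho[tx, ty] = rho[x, y]
                kind[x, y] = EMPTY
                acted[tx, ty] = 1


def step(state: LatticeState, params: AbmParams, alpha=None) -> LatticeState:
    """Advance the lattice by one MCS (in place; the state is returned)."""
    a = params.alpha if alpha is None else alpha
    seed = int(state.rng.integers(0, 2 ** 31 - 1))
    _sweep(state.kind, state.rho, seed, params.mu, params.p_div,
           params.rho_max, params.p_s, a / 24.0,
           1 if params.neighborhood == "moore" else 0)
    state.mcs += 1
    return state


@dataclass
class AbmResult:
    """Snapshots of a lattice run."""

    times: np.ndarray            # MCS of each snapshot
    profiles: np.ndarray         # (n_snap, nx) column populations
    csc_count: np.ndarray
    tc_count: np.ndarray
    final_state: LatticeState
    params: AbmParams
    alpha_per_mcs: np.ndarray = None

    @property
    def total_count(self):
        return self.csc_count + self.tc_count


def run(params: AbmParams, n_mcs: int, snapshot_every: int = 50,
        alpha_per_mcs=None) -> AbmResult:
    """Simulate ``n_mcs`` Monte Carlo steps from the standard seeding.

    ``alpha_per_mcs`` optionally overrides the death rate per step (per
    day; used by the treatment protocols).  Reproducible: the trajectory
    is a pure function of ``params`` (including ``params.seed``).
    """
    if n_mcs < 0:
        raise ValueError("n_mcs must be non-negative")
    if alpha_per_mcs is not None:
        alpha_per_mcs = np.asarray(alpha_per_mcs, dtype=float)
        if alpha_per_mcs.size < n_mcs:
            raise ValueError("alpha_per_mcs must cover every MCS")
    state = LatticeState.initial(params)
    times = [0]
    profiles = [state.column_population()]
    c0 = state.counts()
    csc, tc = [c0[0]], [c0[1]]
    for k in range(1, n_mcs + 1):
        a = params.alpha if alpha_per_mcs is None else float(alpha_per_mcs[k - 1])
        step(state, params, alpha=a)
        if k % snapshot_every == 0 or k == n_mcs:
            times.append(k)
            profiles.append(state.column_population())
            ck = state.counts()
            csc.append(ck[0])
            tc.append(ck[1])
    return AbmResult(
        times=np.asarray(times), profiles=np.asarray(profiles),
        csc_count=np.asarray(csc), tc_count=np.asarray(tc),
        final_state=state, params=params, alpha_per_mcs=alpha_per_mcs,
    )


def continuous_protocol(n_mcs=7000, start=3000, end=5000,
                        alpha_base=0.05, alpha_treat=0.35):
    """Per-MCS death rates: one uninterrupted treatment block."""
    a = np.full(n_mcs, alpha_base)
    a[start:end] = alpha_treat
    return a


def intermittent_protocol(n_mcs=7000, start=3000, end=5000, block=200,
                          alpha_base=0.05, alpha_treat=0.35):
    """Alternating on/off blocks of ``block`` MCS between start and end.

    The default five 200-MCS on-blocks deliver half the exposure of the
    continuous protocol over the same 2000-MCS span.
    """
    a = np.full(n_mcs, alpha_base)
    t = start
    while t < end:
        a[t:min(t + block, end)] = alpha_treat
        t += 2 * block
    return a


def run_with_treatment(params: AbmParams, phases, n_mcs: int,
                       snapshot_every: int = 50) -> AbmResult:
    """Run with piecewise-constant death rates.

    ``phases`` is a list of ``(start_mcs, end_mcs, alpha_per_day)``
    triples; MCS not covered by any phase use ``params.alpha``.
    Overlapping phases are rejected.  An empty list reproduces
    :func:`run` exactly.
    """
    a = np.full(n_mcs, params.alpha, dtype=float)
    covered = np.zeros(n_mcs, dtype=bool)
    for (s, e, alpha) in phases:
        s, e = int(s), int(e)
        if not 0 <= s < e <= n_mcs:
            raise ValueError(f"phase ({s}, {e}) outside [0, {n_mcs}]")
        if covered[s:e].any():
            raise ValueError("treatment phases overlap")
        covered[s:e] = True
        a[s:e] = alpha
    return run(params, n_mcs, snapshot_every=snapshot_every, alpha_per_mcs=a)


def front_speed(result: AbmResult, threshold=None, window="all") -> WaveSpeedEstimate:
    """Front speed of the column-population profiles, in pixels/MCS.

    The front is the half-full-column crossing (threshold 25 of 50 by
    default).  Snapshots before the tumor first fills a column to the
    threshold, and snapshots after the front reaches the right boundary,
    are excluded; the linear fit runs over every remaining snapshot
    (``window="all"``) or over an explicit ``(t0, t1)`` interval.
    """
    if threshold is None:
        threshold = result.params.ny / 2.0
    x = np.arange(result.params.nx, dtype=float)
    keep_t, keep_p = [], []
    for t, prof in zip(result.times, result.profiles):
        p = front_position(x, prof, threshold)
        if np.isnan(p):
            continue
        if p >= x[-2]:
            break  # truncated domain from here on
        keep_t.append(t)
        keep_p.append(prof)
    if len(keep_t) < 3:
        raise ValueError("front detectable in fewer than 3 snapshots")
    win = (keep_t[0], keep_t[-1]) if window == "all" else window
    return measure_speed(np.asarray(keep_t, dtype=float), x,
                         np.asarray(keep_p, dtype=float),
                         threshold=threshold, window=win)
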