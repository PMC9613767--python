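"""Canonical study drivers.

These functions wire the solvers, schedules and the speed estimator into
the standard numerical experiments of the package: the benchmark table of
numerical-vs-theoretical minimal speeds, the crowding-family robustness
sweep, the stochastic lattice invasion-speed sweep, the lattice therapy
contrast, and the brachytherapy dose-rate comparison.  Tests, the CLI and
the acceptance script all call into here so that every consumer runs the
identical protocol.
"""

from __future__ import annotations

import numpy as np

from .abm import (AbmParams, continuous_protocol, front_speed,
                  intermittent_protocol, run, run_with_treatment)
from .pde import ContinuumParams, make_grid, solve_slow, solve_treatment
from .treatment import (BASELINE_ALPHA, PROSTATE, HazardParams,
                        TreatmentSchedule, build_schedule)
from .waves import invasion_step, measure_speed, theoretical_speed

__all__ = [
    "slow_front_speed",
    "speed_table",
    "crowding_family_speeds",
    "abm_speed_sweep",
    "abm_therapy_contrast",
    "brachytherapy_comparison",
]

TABLE_ALPHAS = (5.0, 1.0, 0.8, 0.5, 0.05)


def slow_front_speed(alpha, d=1.0, F="linear", *, length=200.0, dx=0.1,
                     tau_end=80.0, n_output=81, ic_edge=20.0,
                     threshold=None, window=None):
    """Measured front speed of the slow system with the standard protocol.

    Step invasion initial condition at ``ic_edge``, mid-height crossing,
    least-squares fit over the final half of the run (defaults follow the
    benchmark setup: d = 1, domain [0, 200], tau in [0, 80]).
    """
    x = make_grid(length, dx)
    u0 = invasion_step(x, edge=ic_edge)
    res = solve_slow(ContinuumParams(alpha=alpha, d=d, F=F), x, u0,
                     tau_end, np.linspace(0.0, tau_end, n_output))
    return measure_speed(res.t, res.x, res.u, threshold=threshold,
                         window=window)


def speed_table(alphas=TABLE_ALPHAS, d=1.0, **kwargs):
    """Numerical vs theoretical minimal speeds, one row per death rate."""
    rows = []
    for alpha in alphas:
        est = slow_front_speed(alpha, d=d, **kwargs)
        rows.append({
            "alpha": alpha,
            "numerical": est.speed,
            "theoretical": theoretical_speed(alpha, d),
            "residual": est.residual,
        })
    return rows


def crowding_family_speeds(F, alphas=(0.05, 0.5, 0.8, 1.0, 5.0), d=1.0,
                           **kwargs):
    """Measured speeds across death rates for one crowding function."""
    return {alpha: slow_front_speed(alpha, d=d, F=F, **kwargs).speed
            for alpha in alphas}


def abm_speed_sweep(alphas=(0.0, 0.05, 0.1, 0.15, 0.25, 0.35), seeds=(1, 2, 3, 4, 5),
                    n_mcs=7000, snapshot_every=50, p_s=0.01, **params_kw):
    """Replicate-mean lattice front speeds (pixels/MCS) per death rate.

    Returns ``{alpha: (mean_speed, [per-seed speeds])}``.  The front is
    the half-full-column crossing fitted over every usable snapshot.
    """
    out = {}
    for alpha in alphas:
        speeds = []
        for seed in seeds:
            res = run(AbmParams(alpha=alpha, p_s=p_s, seed=seed, **params_kw),
                      n_mcs, snapshot_every=snapshot_every)
            speeds.append(front_speed(res).speed)
        out[alpha] = (float(np.mean(speeds)), speeds)
    return out


def abm_therapy_contrast(seeds=(1, 2, 3, 4, 5), n_mcs=7000,
                         alpha_base=0.05, alpha_treat=0.35,
                         start=3000, end=5000, block=200, p_s=0.01):
    """Matched-seed continuous vs intermittent therapy on the lattice.

    Continuous: one 2000-MCS block at the elevated death rate.
    Intermittent: five alternating on/off blocks of 200 MCS (half the
    exposure).  Returns per-seed records with final total populations and
    final front extents, plus the pre/during-treatment front speeds of
    the continuous arm.
    """
    records = []
    for seed in seeds:
        rec = {"seed": seed}
        for label, protocol in (
            ("continuous", continuous_protocol(n_mcs, start, end,
                                               alpha_base, alpha_treat)),
            ("intermittent", intermittent_protocol(n_mcs, start, end, block,
                                                   alpha_base, alpha_treat)),
        ):
            params = AbmParams(alpha=alpha_base, p_s=p_s, seed=seed)
            res = run(params, n_mcs, snapshot_every=50,
                      alpha_per_mcs=protocol)
            prof = res.profiles[-1]
            occupied = np.nonzero(prof > 0)[0]
            rec[f"{label}_total"] = int(res.total_count[-1])
            rec[f"{label}_extent"] = int(occupied[-1]) if occupied.size else 0
            rec[f"{label}_result"] = res
        records.append(rec)
    return records


def brachytherapy_comparison(r0_values=(5.71, 50.0), delta=0.3,
                             alpha=BASELINE_ALPHA, t_end=80.0, start=20.0,
                             length=8.0, dx=0.005, ic_edge=1.0,
                             width_level=0.01):
    """Continuous decaying-source therapy at several dose rates.

    Prostate-like parameters (d = 8.64e-4 mm^2/day, alpha_r = 0.15 / Gy,
    beta_r = 0.048 / Gy^2), treatment from day ``start``.  For each dose
    rate (0 = untreated) the CSC burden (integral of u over the domain,
    mm) and the invaded width (measure of u > ``width_level``, mm) at the
    final day are reported.
    """
    rows = []
    x = make_grid(length, dx)
    u0 = invasion_step(x, edge=ic_edge)
    for r0 in (0.0, *r0_values):
        params = ContinuumParams(alpha=alpha, d=PROSTATE["d"], delta=delta)
        if r0 == 0.0:
            schedule = build_schedule("none", baseline_alpha=alpha,
                                      delta=delta)
        else:
            hz = HazardParams(mode="decaying-source", R0=r0,
                              alpha_r=PROSTATE["alpha_r"],
                              beta_r=PROSTATE["beta_r"])
            schedule = build_schedule("continuous", start=start, delta=delta,
                                      baseline_alpha=alpha, hazard=hz)
        res = solve_treatment(params, schedule, x, u0, t_end,
                              np.linspace(0.0, t_end, 81))
        u_final = res.u[-1]
        rows.append({
            "R0": r0,
            "burden": float(np.trapezoid(u_final, x)),
            "width": float((u_final > width_level).sum() * dx),
            "peak": float(u_final.max()),
        })
    return rows
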