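"""Radiotherapy hazard functions and treatment calendars.

Treatment raises the non-stem death rate from alpha to
``alpha_hat(t) = alpha + T(t)`` and adds a (much weaker) stem-cell kill
term ``b_hat(t) = delta * T(t)``, both only while treatment is on.  The
hazard T(t) is a tractable linear-quadratic surrogate with two modes:

* decaying source (brachytherapy seed implant):
  ``T(t) = a_r R0 e^{-lam t} + 2 b_r (R0^2/lam)(e^{-2 lam t + lam w} - e^{-2 lam t})``
  with t the time since the source was placed;
* fractionated delivery: ``T = (a_r + b_r D) * D / w`` during a fraction
  window of length w delivering dose D, zero outside.  For whole-day
  fractions (w = 1 day) this is the familiar ``(a_r + b_r d) d`` per-day
  hazard.

Two literature radiosensitivity sets are bundled: a prostate-like set
used with the decaying source and a glioma-like set used with
fractionation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HazardParams",
    "TreatmentSchedule",
    "hazard_continuous",
    "hazard_fractionated",
    "build_schedule",
    "PROSTATE",
    "GLIOMA",
    "BASELINE_ALPHA",
]

#: prostate-like parameter set (diffusion mm^2/day, radiosensitivities)
PROSTATE = {"d": 8.64e-4, "alpha_r": 0.15, "beta_r": 0.048}
#: glioma-like parameter set
GLIOMA = {"d": 0.65, "alpha_r": 0.11, "beta_r": 0.019}
#: baseline spontaneous TC death rate used in the treatment experiments (1/day)
BASELINE_ALPHA = 0.012

MINUTE = 1.0 / 1440.0  # days


@dataclass(frozen=True)
class HazardParams:
    """Parameters of the treatment hazard.

    ``mode`` selects which fields are read: a ``decaying-source`` hazard
    uses (R0, lam, omega, alpha_r, beta_r); a ``fractionated`` hazard uses
    (alpha_r, beta_r, dose_per_fraction, fraction_duration).
    """

    mode: str = "decaying-source"
    R0: float = 5.71  # initial dose rate, Gy/day
    lam: float = 0.0408  # source decay rate, 1/day
    omega: float = 1.0 / 90.0  # interaction window, day
    alpha_r: float = PROSTATE["alpha_r"]  # Gy^-1
    beta_r: float = PROSTATE["beta_r"]  # Gy^-2
    dose_per_fraction: float = 2.0  # Gy
    fraction_duration: float = 1.0  # day

    def __post_init__(self):
        if self.mode not in ("decaying-source", "fractionated"):
            raise ValueError(f"unknown hazard mode {self.mode!r}")
        for name in ("R0", "lam", "omega", "alpha_r", "beta_r",
                     "dose_per_fraction", "fraction_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"hazard parameter {name} must be non-negative")


def hazard_continuous(t, p: HazardParams):
    """Decaying-source hazard T(t), t in days since the source was placed.

    Strictly decreasing and -> 0 as t -> inf.  ``lam = 0`` is rejected
    (the quadratic term divides by the decay rate).
    """
    if p.lam == 0:
        raise ValueError("decaying-source hazard requires lam > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (time since treatment start)")
    lin = p.alpha_r * p.R0 * np.exp(-p.lam * t)
    quad = (
        2.0
        * p.beta_r
        * (p.R0 ** 2 / p.lam)
        * (np.exp(-2.0 * p.lam * t + p.lam * p.omega) - np.exp(-2.0 * p.lam * t))
    )
    out = lin + quad
    return out if out.ndim else float(out)


def hazard_fractionated(p: HazardParams):
    """Constant hazard during a fraction window (zero outside).

    ``(alpha_r + beta_r * D) * D / w`` for a fraction of dose D delivered
    over w days, so that the integrated kill per fraction equals the
    linear-quadratic exponent alpha_r*D + beta_r*D^2.  For w = 1 day this
    is ``(alpha_r + beta_r d) d`` with d the daily dose rate.
    """
    if p.fraction_duration <= 0:
        raise ValueError("fraction_duration must be positive")
    return (
        (p.alpha_r + p.beta_r * p.dose_per_fraction)
        * p.dose_per_fraction
        / p.fraction_duration
    )


@dataclass(frozen=True)
class TreatmentSchedule:
    """On/off treatment calendar with its hazard.

    ``windows`` is an ordered list of disjoint (start, end) intervals in
    days; ``end`` may be ``inf`` for an open-ended window.  Inside a
    window ``alpha_hat = baseline_alpha + T`` and ``b_hat = delta * T``;
    outside, ``alpha_hat = baseline_alpha`` and ``b_hat = 0``.  For the
    decaying-source mode the hazard clock restarts at each window start
    (each on-block is a fresh source).
    """

    windows: tuple = ()
    baseline_alpha: float = BASELINE_ALPHA
    delta: float = 0.3
    hazard: HazardParams = field(default_factory=HazardParams)
    total_dose_cap: float = math.inf
    protocol: str = "custom"

    def __post_init__(self):
        prev_end = -math.inf
        for (a, b) in self.windows:
            if b <= a:
                raise ValueError(f"window ({a}, {b}) has non-positive length")
            if a < prev_end:
                raise ValueError("treatment windows overlap or are unordered")
            prev_end = b
        if self.baseline_alpha <= 0:
            raise ValueError("baseline_alpha must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")

    # -- hazard evaluation -------------------------------------------------
    def active_window(self, t):
        for w in self.windows:
            if w[0] <= t < w[1]:
                return w
        return None

    def T(self, t) -> float:
        w = self.active_window(t)
        if w is None:
            return 0.0
        if self.hazard.mode == "decaying-source":
            return hazard_continuous(t - w[0], self.hazard)
        return hazard_fractionated(self.hazard)

    def alpha_hat(self, t) -> float:
        return self.baseline_alpha + self.T(t)

    def b_hat(self, t) -> float:
        return self.delta * self.T(t)

    def breakpoints(self, t_end):
        """Sorted window edges inside [0, t_end] (integration restarts)."""
        pts = {0.0, float(t_end)}
        for (a, b) in self.windows:
            if 0.0 < a < t_end:
                pts.add(float(a))
            if 0.0 < b < t_end:
                pts.add(float(b))
        return sorted(pts)

    def cumulative_dose(self, t=math.inf) -> float:
        """Delivered physical dose (Gy) up to time t."""
        dose = 0.0
        for (a, b) in self.windows:
            hi = min(b, t)
            if hi <= a:
                continue
            if self.hazard.mode == "decaying-source":
                p = self.hazard
                dose += p.R0 / p.lam * (1.0 - math.exp(-p.lam * (hi - a)))
            else:
                p = self.hazard
                rate = p.dose_per_fraction / p.fraction_duration
                dose += rate * (hi - a)
        return dose


def _blocks(start, on, off, n_on_days, block_len=None):
    """Alternating on/off windows delivering ``n_on_days`` days of treatment."""
    windows = []
    t = start
    remaining = n_on_days
    while remaining > 1e-12:
        this_on = min(on, remaining)
        windows.append((t, t + this_on))
        remaining -= this_on
        t += this_on + off
    return tuple(windows)


def build_schedule(protocol, *, start=None, delta=0.3,
                   baseline_alpha=BASELINE_ALPHA, hazard=None,
                   on=None, off=None, horizon=None,
                   total_dose_cap=None) -> TreatmentSchedule:
    """Construct one of the named treatment protocols.

    ``continuous``        open-ended decaying source from ``start`` (default
                          day 20).
    ``intermittent``      alternating on/off blocks of a decaying source;
                          defaults: start after 4 weeks, 36 weeks on / 36
                          weeks off, horizon 250 weeks.
    ``frac-20-20``        20 days on / 20 days off at 1.5 Gy/day.
    ``frac-2-2``          2 days on / 2 days off at 2 Gy/day.
    ``frac-daily-bursts`` one 10-minute 2 Gy burst per day, weekdays only.
    ``none``              empty calendar (alpha_hat = alpha everywhere).

    All fractionated protocols start on day 20 and stop once the
    cumulative dose reaches 60 Gy.
    """
    if protocol == "none":
        return TreatmentSchedule(
            windows=(), baseline_alpha=baseline_alpha, delta=delta,
            hazard=hazard or HazardParams(), protocol="none",
        )
    if protocol == "continuous":
        start = 20.0 if start is None else start
        hz = hazard or HazardParams(mode="decaying-source")
        return TreatmentSchedule(
            windows=((start, math.inf),), baseline_alpha=baseline_alpha,
            delta=delta, hazard=hz, protocol="continuous",
        )
    if protocol == "intermittent":
        start = 28.0 if start is None else start
        on = 252.0 if on is None else on  # 36 weeks
        off = 252.0 if off is None else off
        horizon = 1750.0 if horizon is None else horizon  # 250 weeks
        windows = []
        t = start
        while t < horizon:
            windows.append((t, min(t + on, horizon)))
            t += on + off
        hz = hazard or HazardParams(mode="decaying-source")
        return TreatmentSchedule(
            windows=tuple(windows), baseline_alpha=baseline_alpha,
            delta=delta, hazard=hz, protocol="intermittent",
        )

    # fractionated family: start day 20, 60 Gy cap
    start = 20.0 if start is None else start
    cap = 60.0 if total_dose_cap is None else total_dose_cap
    if protocol == "frac-20-20":
        hz = hazard or HazardParams(
            mode="fractionated", alpha_r=GLIOMA["alpha_r"],
            beta_r=GLIOMA["beta_r"], dose_per_fraction=1.5,
            fraction_duration=1.0,
        )
        n_on = cap / (hz.dose_per_fraction / hz.fraction_duration)
        windows = _blocks(start, 20.0, 20.0, n_on)
    elif protocol == "frac-2-2":
        hz = hazard or HazardParams(
            mode="fractionated", alpha_r=GLIOMA["alpha_r"],
            beta_r=GLIOMA["beta_r"], dose_per_fraction=2.0,
            fraction_duration=1.0,
        )
        n_on = cap / (hz.dose_per_fraction / hz.fraction_duration)
        windows = _blocks(start, 2.0, 2.0, n_on)
    elif protocol == "frac-daily-bursts":
        hz = hazard or HazardParams(
            mode="fractionated", alpha_r=GLIOMA["alpha_r"],
            beta_r=GLIOMA["beta_r"], dose_per_fraction=2.0,
            fraction_duration=10.0 * MINUTE,
        )
        n_frac = int(round(cap / hz.dose_per_fraction))
        windows = []
        day = 0
        while len(windows) < n_frac:
            if day % 7 < 5:  # weekdays
                t0 = start + day
                windows.append((t0, t0 + hz.fraction_duration))
            day += 1
        windows = tuple(windows)
    else:
        raise ValueError(f"unknown treatment protocol {protocol!r}")
    return TreatmentSchedule(
        windows=tuple(windows), baseline_alpha=baseline_alpha, delta=delta,
        hazard=hz, total_dose_cap=cap, protocol=protocol,
    )
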