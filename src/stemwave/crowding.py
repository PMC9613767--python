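"""Volume-limitation (crowding) functions F(n).

A crowding function multiplies every proliferation term of the model and
encodes how division slows as the total cell density n = u + v approaches
the carrying capacity (normalized to 1).  Admissible functions satisfy

    F(0) = 1,   F(1) = 0,   F continuous and strictly decreasing on [0, 1],

and are clamped to their non-negative part for n >= 1.  Because the division
rates gamma_u = gamma_v are set to 1, F carries an implicit unit of
1/time, so quantities such as 2*sqrt(d*F(v*)) are genuine speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["CrowdingFunction", "CROWDING_FUNCTIONS", "get_crowding"]


@dataclass(frozen=True)
class CrowdingFunction:
    """A crowding function F with analytic derivative.

    Calling the object evaluates ``F(n)`` with the non-negative-part
    convention ``F(n) = 0`` for ``n >= 1``; :meth:`derivative` evaluates
    ``F'(n)`` (zero beyond capacity).
    """

    name: str
    _f: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    _df: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def __call__(self, n):
        n = np.asarray(n, dtype=float)
        out = np.where(n < 1.0, self._f(np.minimum(n, 1.0)), 0.0)
        out = np.maximum(out, 0.0)
        return out if out.ndim else float(out)

    def derivative(self, n):
        n = np.asarray(n, dtype=float)
        out = np.where(n < 1.0, self._df(np.minimum(n, 1.0)), 0.0)
        return out if out.ndim else float(out)

    @classmethod
    def from_callable(cls, f, df=None, name="custom", validate=True):
        """Wrap a user-supplied F.

        ``df`` defaults to a central finite difference.  ``validate``
        spot-checks the endpoint and monotonicity assumptions.
        """
        if df is None:
            h = 1e-7

            def df(n, _f=f):  # noqa: E731 - simple closure
                lo = np.maximum(np.asarray(n, dtype=float) - h, 0.0)
                hi = np.minimum(np.asarray(n, dtype=float) + h, 1.0)
                return (_f(hi) - _f(lo)) / (hi - lo)

        cf = cls(name, f, df)
        if validate:
            if abs(float(f(0.0)) - 1.0) > 1e-9 or abs(float(f(1.0))) > 1e-9:
                raise ValueError(
                    f"crowding function {name!r} must satisfy F(0)=1 and F(1)=0"
                )
            grid = np.linspace(0.0, 1.0, 257)
            vals = np.asarray(f(grid), dtype=float)
            if np.any(np.diff(vals) > 1e-12):
                raise ValueError(
                    f"crowding function {name!r} must be non-increasing on [0,1]"
                )
        return cf


_E = float(np.e)

#: The four-member family used throughout: (1-n), (1-n^4),
#: (e^{-(n-1)}-1)/(e-1) and cos(pi n / 2), each taken as its
#: non-negative part.  ``linear`` is the default everywhere.
CROWDING_FUNCTIONS = {
    "linear": CrowdingFunction("linear", lambda n: 1.0 - n, lambda n: -np.ones_like(np.asarray(n, dtype=float))),
    "quartic": CrowdingFunction("quartic", lambda n: 1.0 - n ** 4, lambda n: -4.0 * n ** 3),
    "exponential": CrowdingFunction(
        "exponential",
        lambda n: (np.exp(-(n - 1.0)) - 1.0) / (_E - 1.0),
        lambda n: -np.exp(-(n - 1.0)) / (_E - 1.0),
    ),
    "cosine": CrowdingFunction(
        "cosine",
        lambda n: np.cos(np.pi * n / 2.0),
        lambda n: -(np.pi / 2.0) * np.sin(np.pi * n / 2.0),
    ),
}


def get_crowding(spec="linear") -> CrowdingFunction:
    """Resolve a crowding function from a name or pass one through."""
    if isinstance(spec, CrowdingFunction):
        return spec
    if isinstance(spec, str):
        try:
            return CROWDING_FUNCTIONS[spec]
        except KeyError:
            raise KeyError(
                f"unknown crowding function {spec!r}; "
                f"choose from {sorted(CROWDING_FUNCTIONS)}"
            ) from None
    raise TypeError(f"cannot interpret {spec!r} as a crowding function")
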