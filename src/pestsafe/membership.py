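"""Membership-function primitives for the fuzzy safety model.

Four shapes are supported, the ones the model's linguistic variables use:

* ``triangular(a, b, c)`` — degree 0 at and outside ``a``/``c``, peak 1 at
  ``b``, linear sides.
* ``trapezoidal(a, b, c, d)`` — linear rise on ``[a, b]``, plateau 1 on
  ``[b, c]``, linear fall on ``[c, d]``; ``a == b`` or ``c == d`` gives a
  shouldered (saturating) set.
* ``s_shaped(a, b)`` — smooth quadratic-spline saturation from 0 at ``a``
  to 1 at ``b``, value 1/2 at the midpoint.
* ``z_shaped(a, b)`` — the mirror image, ``z(x) = 1 - s(x)``.

The smooth pair follows the spline convention common in fuzzy-control
toolboxes, so ``z_shaped(a, b) + s_shaped(a, b) == 1`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "MembershipFunction",
    "triangular",
    "trapezoidal",
    "s_shaped",
    "z_shaped",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """A model component (membership function, rule base, weights) is malformed."""


_SHAPE_ARITY = {
    "triangular": 3,
    "trapezoidal": 4,
    "z_shaped": 2,
    "s_shaped": 2,
}


@dataclass(frozen=True)
class MembershipFunction:
    """A fuzzy set on a one-dimensional universe.

    Parameters
    ----------
    shape
        One of ``triangular``, ``trapezoidal``, ``z_shaped``, ``s_shaped``.
    breakpoints
        Non-decreasing abscissae defining the shape: 3 for triangular,
        4 for trapezoidal, 2 for the smooth pair.
    """

    shape: str
    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape not in _SHAPE_ARITY:
            raise ConfigurationError(f"unknown membership shape {self.shape!r}")
        bp = tuple(float(b) for b in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        if len(bp) != _SHAPE_ARITY[self.shape]:
            raise ConfigurationError(
                f"{self.shape} needs {_SHAPE_ARITY[self.shape]} breakpoints, got {len(bp)}"
            )
        if any(b2 < b1 for b1, b2 in zip(bp, bp[1:])):
            raise ConfigurationError(f"breakpoints must be non-decreasing: {bp}")
        if self.shape in ("z_shaped", "s_shaped") and bp[0] == bp[1]:
            raise ConfigurationError("z/s shapes need a strictly increasing pair")

    def __call__(self, x: float) -> float:
        """Degree of membership of the crisp value ``x``, in [0, 1]."""
        return float(self.evaluate(np.asarray(x, dtype=float)))

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Vectorised membership degree; same rules as ``__call__``."""
        x = np.asarray(x, dtype=float)
        bp = self.breakpoints
        if self.shape == "triangular":
            a, b, c = bp
            return _piecewise_linear(x, (a, b, c), (0.0, 1.0, 0.0))
        if self.shape == "trapezoidal":
            a, b, c, d = bp
            return _piecewise_linear(x, (a, b, c, d), (0.0, 1.0, 1.0, 0.0))
        a, b = bp
        s = _smf(x, a, b)
        return 1.0 - s if self.shape == "z_shaped" else s

    @property
    def is_piecewise_linear(self) -> bool:
        return self.shape in ("triangular", "trapezoidal")

    def support(self) -> tuple[float, float]:
        """Closed interval outside which the degree is identically 0 or saturated."""
        return (self.breakpoints[0], self.breakpoints[-1])


def _piecewise_linear(
    x: np.ndarray, xs: Iterable[float], ys: Iterable[float]
) -> np.ndarray:
    """Interpolate through (xs, ys) knots, handling repeated knots as jumps.

    Vertical edges (repeated abscissae, e.g. the left shoulder of
    ``trapezoidal(0, 0, 30, 65)``) take the saturated value at the shared
    knot, so a left-shouldered trapezoid is 1 at its left endpoint.
    """
    xs = list(xs)
    ys = list(ys)
    keep_x, keep_y = [], []
    for xv, yv in zip(xs, ys):
        if keep_x and xv == keep_x[-1]:
            keep_y[-1] = max(keep_y[-1], yv)
        else:
            keep_x.append(xv)
            keep_y.append(yv)
    if len(keep_x) == 1:  # degenerate spike
        return np.where(x == keep_x[0], 1.0, 0.0)
    return np.interp(x, keep_x, keep_y, left=0.0, right=0.0)


def _smf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    m = (a + b) / 2.0
    t = (x - a) / (b - a)
    u = (x - b) / (b - a)
    out = np.where(
        x <= a,
        0.0,
        np.where(x >= b, 1.0, np.where(x <= m, 2.0 * t * t, 1.0 - 2.0 * u * u)),
    )
    return out


def triangular(a: float, b: float, c: float) -> MembershipFunction:
    return MembershipFunction("triangular", (a, b, c))


def trapezoidal(a: float, b: float, c: float, d: float) -> MembershipFunction:
    return MembershipFunction("trapezoidal", (a, b, c, d))


def s_shaped(a: float, b: float) -> MembershipFunction:
    return MembershipFunction("s_shaped", (a, b))


def z_shaped(a: float, b: float) -> MembershipFunction:
    return MembershipFunction("z_shaped", (a, b))
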