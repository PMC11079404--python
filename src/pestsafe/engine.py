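"""Mamdani inference and centroid defuzzification.

The pipeline implemented here is the classic min/max Mamdani scheme:

1. *Fuzzification* — each crisp parameter value is converted to a degree of
   truth in every category of its linguistic variable.
2. *Rule evaluation* — a rule's activation is the **minimum** (conjunction)
   of its five antecedent category degrees.
3. *Aggregation* — per consequent (``Safe`` / ``NotSafe``), the **maximum**
   (disjunction) over the activations of all rules with that consequent.
4. *Implication + defuzzification* — each output membership function is
   clipped at its consequent's aggregate degree, the clipped curves are
   combined by pointwise maximum, and the crisp score is the centroid
   (first moment over area) of the combined curve on the 0–10 universe.

Two defuzzification routes are provided: :func:`defuzzify_centroid`
integrates on a discretized grid (the production path), while
:func:`centroid_oracle` evaluates the same centroid in closed form from
exact polygon moments of the clipped piecewise-linear curves. The two are
independent and must agree; the assessor uses that agreement as its
verification value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .membership import MembershipFunction

SAFE = "Safe"
NOT_SAFE = "NotSafe"

__all__ = [
    "SAFE",
    "NOT_SAFE",
    "AggregatedConsequent",
    "NoRuleFiredError",
    "fuzzify",
    "conjunction",
    "disjunction",
    "infer",
    "defuzzify_centroid",
    "centroid_oracle",
]


class NoRuleFiredError(RuntimeError):
    """Both aggregate consequent degrees are zero — the rule base has a hole."""


@dataclass(frozen=True)
class AggregatedConsequent:
    """Aggregate degrees of the two output fuzzy sets after inference."""

    safe: float
    not_safe: float
    universe: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        for name, d in (("safe", self.safe), ("not_safe", self.not_safe)):
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{name} degree {d} outside [0, 1]")

    def degree(self, consequent: str) -> float:
        return self.safe if consequent == SAFE else self.not_safe


def fuzzify(
    values: Mapping[str, float], parameters: Sequence
) -> dict[str, dict[str, float]]:
    """Convert clamped crisp values to per-category degrees of truth.

    ``parameters`` is a sequence of :class:`~pestsafe.model.FuzzyParameter`;
    the result maps parameter name -> {category label -> degree}.
    """
    out: dict[str, dict[str, float]] = {}
    for param in parameters:
        if param.name not in values or values[param.name] is None:
            raise ValueError(f"missing value for parameter {param.name!r}")
        x = float(values[param.name])
        out[param.name] = {
            cat: param.membership[cat](x) for cat in param.categories
        }
    return out


def conjunction(degrees: Iterable[float]) -> float:
    """Fuzzy AND: the minimum of the degrees. Errors on an empty collection."""
    degrees = list(degrees)
    if not degrees:
        raise ValueError("conjunction of no degrees is undefined")
    if any(d < 0.0 or d > 1.0 for d in degrees):
        raise ValueError(f"degrees outside [0, 1]: {degrees}")
    return min(degrees)


def disjunction(degrees: Iterable[float]) -> float:
    """Fuzzy OR: the maximum of the degrees; 0 for the empty collection."""
    degrees = list(degrees)
    if any(d < 0.0 or d > 1.0 for d in degrees):
        raise ValueError(f"degrees outside [0, 1]: {degrees}")
    return max(degrees, default=0.0)


def infer(
    fuzzy: Mapping[str, Mapping[str, float]], rule_base
) -> tuple[AggregatedConsequent, list]:
    """Evaluate every rule and aggregate activations per consequent.

    Returns the aggregate consequent degrees together with a trace of the
    fired rules: ``(rule, activation)`` pairs for every activation > 0.
    """
    best: dict[str, float] = {SAFE: 0.0, NOT_SAFE: 0.0}
    fired: list = []
    for rule in rule_base:
        act = conjunction(
            fuzzy[param][cat] for param, cat in rule.antecedent.items()
        )
        if act > 0.0:
            fired.append((rule, act))
        if act > best[rule.consequent]:
            best[rule.consequent] = act
    return (
        AggregatedConsequent(safe=best[SAFE], not_safe=best[NOT_SAFE]),
        fired,
    )


def _clipped_max_on_grid(
    xs: np.ndarray,
    agg: AggregatedConsequent,
    output_mfs: Mapping[str, MembershipFunction],
) -> np.ndarray:
    mu_ns = np.minimum(output_mfs[NOT_SAFE].evaluate(xs), agg.not_safe)
    mu_s = np.minimum(output_mfs[SAFE].evaluate(xs), agg.safe)
    return np.maximum(mu_ns, mu_s)


def defuzzify_centroid(
    agg: AggregatedConsequent,
    output_mfs: Mapping[str, MembershipFunction],
    step: float = 0.01,
) -> float:
    """Centroid of the aggregated output curve on a discretized universe.

    ``step`` is the grid spacing on the output universe; 0.01 resolves the
    published scores to two decimal places.
    """
    if step <= 0.0:
        raise ValueError(f"step must be positive, got {step}")
    if agg.safe == 0.0 and agg.not_safe == 0.0:
        raise NoRuleFiredError(
            "no rule fired: both aggregate consequent degrees are zero"
        )
    lo, hi = agg.universe
    xs = np.arange(lo, hi + step / 2.0, step)
    mu = _clipped_max_on_grid(xs, agg, output_mfs)
    return float(np.sum(xs * mu) / np.sum(mu))


# ---------------------------------------------------------------------------
# Closed-form oracle
# ---------------------------------------------------------------------------


def _plf_knots(mf: MembershipFunction) -> tuple[list[float], list[float]]:
    """Knot representation of a piecewise-linear membership function."""
    if not mf.is_piecewise_linear:
        raise ValueError(
            "the closed-form centroid requires piecewise-linear output sets"
        )
    bp = mf.breakpoints
    ys = (0.0, 1.0, 0.0) if mf.shape == "triangular" else (0.0, 1.0, 1.0, 0.0)
    keep_x: list[float] = []
    keep_y: list[float] = []
    for xv, yv in zip(bp, ys):
        if keep_x and xv == keep_x[-1]:
            keep_y[-1] = max(keep_y[-1], yv)
        else:
            keep_x.append(xv)
            keep_y.append(yv)
    return keep_x, keep_y


def _plf_eval(knots: tuple[list[float], list[float]], x: float) -> float:
    return float(np.interp(x, knots[0], knots[1], left=0.0, right=0.0))


def _clip_crossings(
    knots: tuple[list[float], list[float]], h: float
) -> list[float]:
    """Abscissae where the function crosses the clip level ``h``."""
    xs, ys = knots
    out = []
    for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
        if (y0 - h) * (y1 - h) < 0.0:
            out.append(x0 + (h - y0) * (x1 - x0) / (y1 - y0))
    return out


def centroid_oracle(
    agg: AggregatedConsequent,
    output_mfs: Mapping[str, MembershipFunction],
) -> float:
    """Exact centroid of the clipped-and-aggregated output curve.

    Builds the piecewise-linear union of the two Mamdani-clipped output
    trapezoids and integrates area and first moment segment by segment in
    closed form — no discretization, independent of
    :func:`defuzzify_centroid`.
    """
    if agg.safe == 0.0 and agg.not_safe == 0.0:
        raise NoRuleFiredError(
            "no rule fired: both aggregate consequent degrees are zero"
        )
    lo, hi = agg.universe
    kn_ns = _plf_knots(output_mfs[NOT_SAFE])
    kn_s = _plf_knots(output_mfs[SAFE])
    h_ns, h_s = agg.not_safe, agg.safe

    def mu_ns(x: float) -> float:
        return min(_plf_eval(kn_ns, x), h_ns)

    def mu_s(x: float) -> float:
        return min(_plf_eval(kn_s, x), h_s)

    grid = set([lo, hi])
    grid.update(x for x in kn_ns[0] + kn_s[0] if lo <= x <= hi)
    grid.update(x for x in _clip_crossings(kn_ns, h_ns) if lo <= x <= hi)
    grid.update(x for x in _clip_crossings(kn_s, h_s) if lo <= x <= hi)
    # Within each cell both clipped curves are linear; add their crossing so
    # the pointwise max is linear on every integration segment.
    pts = sorted(grid)
    extra = []
    for x0, x1 in zip(pts, pts[1:]):
        d0 = mu_ns(x0) - mu_s(x0)
        d1 = mu_ns(x1) - mu_s(x1)
        if d0 * d1 < 0.0:
            extra.append(x0 + d0 * (x1 - x0) / (d0 - d1))
    pts = sorted(set(pts) | set(extra))

    area = 0.0
    moment = 0.0
    for x0, x1 in zip(pts, pts[1:]):
        y0 = max(mu_ns(x0), mu_s(x0))
        y1 = max(mu_ns(x1), mu_s(x1))
        dx = x1 - x0
        area += 0.5 * (y0 + y1) * dx
        moment += dx * (x0 * (2.0 * y0 + y1) + x1 * (y0 + 2.0 * y1)) / 6.0
    return moment / area
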