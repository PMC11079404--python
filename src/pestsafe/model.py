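"""The five-parameter pesticide safety model and its weighted rule base.

The model scores a pesticide on five ecotoxicological parameters:

========================  ==========  ==================================
parameter                 universe    categories (best -> worst)
========================  ==========  ==================================
persistency (days)        [0, 200]    non-persistent / moderate / persistent
aeq (dimensionless)       [0, 20]     low / moderate / high contaminate
ld50_bee (ug/bee)         [0, 200]    low / moderate / high toxicity
likely_exposure (score)   [0, 4]      no likely exposure / high exposure
mrl (mg/kg)               [0, 400]    high residue limit / low residue limit
========================  ==========  ==================================

Each category carries a categorization code (0 best, 1 worst, 0.5 the
middle of a three-way split) and each parameter an expert-elicited weight.
A rule is one category choice per parameter; its consequent is NotSafe
exactly when the weighted sum of its codes exceeds 0.5 (a tie at exactly
0.5 is Safe). Enumerating the full category product yields the complete
108-rule base (3 x 3 x 3 x 2 x 2).

Codes and weights are kept as exact fractions so threshold ties are
decided exactly; two-decimal values appear only in display output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Mapping, Sequence

import yaml

from .engine import NOT_SAFE, SAFE
from .membership import (
    ConfigurationError,
    MembershipFunction,
    s_shaped,
    trapezoidal,
    triangular,
    z_shaped,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FuzzyParameter",
    "ExpertWeights",
    "Rule",
    "RuleBase",
    "Model",
    "normalize_weights",
    "generate_rule_base",
    "clamp_input",
    "build_default_model",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "PARAMETER_ORDER",
]

#: Canonical parameter order (the order the model tables list them in).
PARAMETER_ORDER = ("persistency", "aeq", "ld50_bee", "likely_exposure", "mrl")


@dataclass(frozen=True)
class FuzzyParameter:
    """One linguistic variable: universe, categories, memberships, codes, weight."""

    name: str
    universe: tuple[float, float]
    categories: tuple[str, ...]  # ordered best -> worst
    membership: Mapping[str, MembershipFunction]
    codes: Mapping[str, Fraction]
    weight: Fraction
    units: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ConfigurationError(f"{self.name}: universe min must be < max")
        if set(self.categories) != set(self.membership):
            raise ConfigurationError(f"{self.name}: categories/membership mismatch")
        if set(self.categories) != set(self.codes):
            raise ConfigurationError(f"{self.name}: categories/codes mismatch")
        expected = (
            {Fraction(0), Fraction(1, 2), Fraction(1)}
            if len(self.categories) == 3
            else {Fraction(0), Fraction(1)}
        )
        if set(self.codes.values()) != expected:
            raise ConfigurationError(
                f"{self.name}: codes must be exactly {sorted(expected)}"
            )


@dataclass(frozen=True)
class ExpertWeights:
    """Per-expert importance ratings and the averaged parameter weights.

    Ratings use a 0-5 importance scale per parameter per expert. Each
    expert's ratings are normalized to fractions of 1 (rating over the
    expert's rating sum) and the final weight of a parameter is the mean
    of its normalized weights across experts.
    """

    parameters: tuple[str, ...]
    ratings: tuple[tuple[Fraction, ...], ...]  # one row per expert
    per_expert: tuple[tuple[Fraction, ...], ...] = field(init=False)
    averaged: tuple[Fraction, ...] = field(init=False)

    def __post_init__(self) -> None:
        per_expert = []
        for row in self.ratings:
            if len(row) != len(self.parameters):
                raise ConfigurationError("rating row length != parameter count")
            if any(r < 0 for r in row):
                raise ConfigurationError("ratings must be non-negative")
            total = sum(row)
            if total == 0:
                raise ConfigurationError("an expert's ratings are all zero")
            per_expert.append(tuple(r / total for r in row))
        n = Fraction(len(per_expert))
        averaged = tuple(
            sum(col) / n for col in zip(*per_expert)
        )
        object.__setattr__(self, "per_expert", tuple(per_expert))
        object.__setattr__(self, "averaged", averaged)

    def as_mapping(self) -> dict[str, Fraction]:
        return dict(zip(self.parameters, self.averaged))


@dataclass(frozen=True)
class Rule:
    """One antecedent category per parameter plus the thresholded consequent."""

    antecedent: Mapping[str, str]
    weighted_score: Fraction
    consequent: str


class RuleBase(tuple):
    """Ordered, complete enumeration of the category product."""

    def __new__(cls, rules: Sequence[Rule]):
        antecedents = [tuple(sorted(r.antecedent.items())) for r in rules]
        if len(set(antecedents)) != len(antecedents):
            raise ConfigurationError("duplicate rules in rule base")
        return super().__new__(cls, rules)


def normalize_weights(
    ratings: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    parameters: Sequence[str] = PARAMETER_ORDER,
) -> ExpertWeights:
    """Turn raw per-expert importance ratings into averaged weights.

    ``ratings`` is either a list of rating rows (one per expert, in
    parameter order) or a mapping ``{expert: row}``. Arithmetic is exact;
    round only for display.
    """
    if isinstance(ratings, Mapping):
        rows = list(ratings.values())
    else:
        rows = list(ratings)
    frac_rows = tuple(
        tuple(Fraction(r).limit_denominator(10**9) for r in row) for row in rows
    )
    return ExpertWeights(parameters=tuple(parameters), ratings=frac_rows)


def generate_rule_base(
    parameters: Sequence[FuzzyParameter],
    weights: Mapping[str, Fraction] | ExpertWeights,
) -> RuleBase:
    """Enumerate the full category product and threshold each combination.

    Combinations are enumerated with parameters in their given (canonical)
    order and categories best-code-first. The consequent is NotSafe when
    the weighted code sum exceeds 1/2, Safe otherwise (ties -> Safe).
    """
    if isinstance(weights, ExpertWeights):
        weights = weights.as_mapping()
    total = sum(weights[p.name] for p in parameters)
    if abs(float(total) - 1.0) > 1e-9:
        raise ConfigurationError(f"weights sum to {float(total)}, expected 1")
    rules = []
    for combo in product(*[p.categories for p in parameters]):
        score = sum(
            (p.codes[cat] * weights[p.name] for p, cat in zip(parameters, combo)),
            start=Fraction(0),
        )
        consequent = NOT_SAFE if score > Fraction(1, 2) else SAFE
        rules.append(
            Rule(
                antecedent={p.name: cat for p, cat in zip(parameters, combo)},
                weighted_score=score,
                consequent=consequent,
            )
        )
    return RuleBase(rules)


def clamp_input(value: float, param: FuzzyParameter) -> float:
    """Clamp a crisp value onto the parameter universe, warning when it moves.

    Out-of-range field data is common (a soil half-life of 2000 days far
    exceeds the 200-day universe); the model truncates it to the nearest
    universe bound rather than rejecting the record.
    """
    try:
        v = float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{param.name}: non-numeric value {value!r}") from exc
    if v != v or v in (float("inf"), float("-inf")):
        raise ValueError(f"{param.name}: value must be finite, got {value!r}")
    lo, hi = param.universe
    if v > hi:
        logger.warning("%s: %g above universe max, clamped to %g", param.name, v, hi)
        return hi
    if v < lo:
        logger.warning("%s: %g below universe min, clamped to %g", param.name, v, lo)
        return lo
    return v


@dataclass(frozen=True)
class Model:
    """A complete assessment model: parameters, output sets, rule base."""

    parameters: tuple[FuzzyParameter, ...]
    output_mfs: Mapping[str, MembershipFunction]
    expert_weights: ExpertWeights | None
    rule_base: RuleBase
    output_universe: tuple[float, float] = (0.0, 10.0)

    def parameter(self, name: str) -> FuzzyParameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def weights(self) -> dict[str, Fraction]:
        if self.expert_weights is not None:
            return self.expert_weights.as_mapping()
        return {p.name: p.weight for p in self.parameters}


#: Raw expert importance ratings behind the default weights
#: (two environmental-health experts, 0-5 scale, parameter order as above).
DEFAULT_EXPERT_RATINGS = (
    (2, 3, 5, 4, 1),
    (5, 3, 2, 1, 4),
)


def build_default_model() -> Model:
    """The calibrated five-parameter model with its 108-rule base.

    Persistency and bee-exposure membership functions follow the published
    calibration directly; the AEQ, LD50 and MRL functions are
    reconstructions constrained by the published category boundaries and
    worked assessments (see the model card in ``docs/methods.md``). Output
    sets are the symmetric trapezoid pair NotSafe (0, 0, 3, 7) and
    Safe (3, 7, 10, 10) on the 0-10 score universe.
    """
    weights = normalize_weights(DEFAULT_EXPERT_RATINGS)
    wmap = weights.as_mapping()

    def fracs(*vals):
        return {k: Fraction(v) for k, v in vals}

    parameters = (
        FuzzyParameter(
            name="persistency",
            universe=(0.0, 200.0),
            categories=("non_persistent", "moderate_persistent", "persistent"),
            membership={
                "non_persistent": trapezoidal(0, 0, 30, 65),
                "moderate_persistent": triangular(15, 65, 150),
                "persistent": trapezoidal(65, 100, 200, 200),
            },
            codes=fracs(
                ("non_persistent", 0),
                ("moderate_persistent", Fraction(1, 2)),
                ("persistent", 1),
            ),
            weight=wmap["persistency"],
            units="days",
        ),
        FuzzyParameter(
            name="aeq",
            universe=(0.0, 20.0),
            categories=("low_contaminate", "moderate_contaminate", "high_contaminate"),
            membership={
                "low_contaminate": trapezoidal(1.5, 2, 20, 20),
                "moderate_contaminate": triangular(0.5, 1.5, 2.5),
                "high_contaminate": trapezoidal(0, 0, 1, 1.25),
            },
            codes=fracs(
                ("low_contaminate", 0),
                ("moderate_contaminate", Fraction(1, 2)),
                ("high_contaminate", 1),
            ),
            weight=wmap["aeq"],
            units="dimensionless",
        ),
        FuzzyParameter(
            name="ld50_bee",
            universe=(0.0, 200.0),
            categories=("low_toxicity", "moderate_toxicity", "high_toxicity"),
            membership={
                "low_toxicity": trapezoidal(50.5, 100, 200, 200),
                "moderate_toxicity": triangular(0.5, 50.5, 125),
                "high_toxicity": trapezoidal(0, 0, 1, 50.5),
            },
            codes=fracs(
                ("low_toxicity", 0),
                ("moderate_toxicity", Fraction(1, 2)),
                ("high_toxicity", 1),
            ),
            weight=wmap["ld50_bee"],
            units="ug/bee",
        ),
        FuzzyParameter(
            name="likely_exposure",
            universe=(0.0, 4.0),
            categories=("no_likely_exposure", "high_exposure"),
            membership={
                "no_likely_exposure": z_shaped(1, 3),
                "high_exposure": s_shaped(1, 3),
            },
            codes=fracs(("no_likely_exposure", 0), ("high_exposure", 1)),
            weight=wmap["likely_exposure"],
            units="likelihood score",
        ),
        FuzzyParameter(
            name="mrl",
            universe=(0.0, 400.0),
            categories=("high_residue_limit", "low_residue_limit"),
            membership={
                "high_residue_limit": s_shaped(100, 400),
                "low_residue_limit": z_shaped(100, 400),
            },
            codes=fracs(("high_residue_limit", 0), ("low_residue_limit", 1)),
            weight=wmap["mrl"],
            units="mg/kg",
        ),
    )
    output_mfs = {
        NOT_SAFE: trapezoidal(0, 0, 3, 7),
        SAFE: trapezoidal(3, 7, 10, 10),
    }
    rule_base = generate_rule_base(parameters, weights)
    return Model(
        parameters=parameters,
        output_mfs=output_mfs,
        expert_weights=weights,
        rule_base=rule_base,
    )


# ---------------------------------------------------------------------------
# Serialization (YAML model configuration)
# ---------------------------------------------------------------------------


def _frac_str(f: Fraction) -> str:
    return f"{f.numerator}/{f.denominator}"


def _frac_parse(s) -> Fraction:
    if isinstance(s, str) and "/" in s:
        num, den = s.split("/")
        return Fraction(int(num), int(den))
    return Fraction(s).limit_denominator(10**9)


def model_to_dict(model: Model) -> dict:
    """Plain-data representation of a model; round-trips bit-exactly."""
    d: dict = {"parameters": [], "output": {}}
    for p in model.parameters:
        d["parameters"].append(
            {
                "name": p.name,
                "units": p.units,
                "universe": list(p.universe),
                "categories": [
                    {
                        "label": cat,
                        "shape": p.membership[cat].shape,
                        "breakpoints": list(p.membership[cat].breakpoints),
                        "code": _frac_str(p.codes[cat]),
                    }
                    for cat in p.categories
                ],
                "weight": _frac_str(p.weight),
            }
        )
    d["output"] = {
        "universe": list(model.output_universe),
        "membership": {
            label: {"shape": mf.shape, "breakpoints": list(mf.breakpoints)}
            for label, mf in model.output_mfs.items()
        },
    }
    if model.expert_weights is not None:
        d["expert_ratings"] = [
            [_frac_str(r) for r in row] for row in model.expert_weights.ratings
        ]
    return d


def model_from_dict(d: Mapping) -> Model:
    """Rebuild a model from :func:`model_to_dict` output."""
    parameters = []
    for pd in d["parameters"]:
        cats = tuple(c["label"] for c in pd["categories"])
        membership = {
            c["label"]: MembershipFunction(c["shape"], tuple(c["breakpoints"]))
            for c in pd["categories"]
        }
        codes = {c["label"]: _frac_parse(c["code"]) for c in pd["categories"]}
        parameters.append(
            FuzzyParameter(
                name=pd["name"],
                universe=tuple(pd["universe"]),
                categories=cats,
                membership=membership,
                codes=codes,
                weight=_frac_parse(pd["weight"]),
                units=pd.get("units", ""),
            )
        )
    parameters = tuple(parameters)
    output_mfs = {
        label: MembershipFunction(spec["shape"], tuple(spec["breakpoints"]))
        for label, spec in d["output"]["membership"].items()
    }
    expert_weights = None
    if "expert_ratings" in d:
        expert_weights = ExpertWeights(
            parameters=tuple(p.name for p in parameters),
            ratings=tuple(
                tuple(_frac_parse(r) for r in row) for row in d["expert_ratings"]
            ),
        )
    weights = (
        expert_weights.as_mapping()
        if expert_weights is not None
        else {p.name: p.weight for p in parameters}
    )
    rule_base = generate_rule_base(parameters, weights)
    return Model(
        parameters=parameters,
        output_mfs=output_mfs,
        expert_weights=expert_weights,
        rule_base=rule_base,
        output_universe=tuple(d["output"]["universe"]),
    )


def save_model(model: Model, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> Model:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(yaml.safe_load(fh))
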