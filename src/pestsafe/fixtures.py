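"""Published sample data embedded for tests and examples.

Ten pesticides with their five model inputs, the field doses used to derive
their AEQ values, the two experts' importance ratings behind the default
weights, and the published safety scores (code and manual-centroid routes).
All values are digit-for-digit as published; nothing is fetched.

"Methiodathion" appears once in the published verification table as a
spelling variant of methidathion; it is normalized here and recorded in
:data:`NAME_ALIASES`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_fixture", "FIXTURE_NAMES", "NAME_ALIASES"]

NAME_ALIASES = {"Methiodathion": "Methidathion"}

_EXPERT_RATINGS = pd.DataFrame(
    {
        "parameter": ["persistency", "aeq", "ld50_bee", "likely_exposure", "mrl"],
        "expert_1": [2, 3, 5, 4, 1],
        "expert_2": [5, 3, 2, 1, 4],
    }
)

# name, persistency (days), aeq, ld50 (ug/bee), likely exposure, mrl (mg/kg)
_PESTICIDES = pd.DataFrame(
    [
        ("Abamectin", 28, 0.002, 0.03, 3, 0.02),
        ("Dodine", 20, 3.267, 145, 3, 5),
        ("Dimethoate", 7, 0.0081, 0.12, 3, 0.05),
        ("Clofentezine", 40, 6.06, 48, 3, 0.05),
        ("Iprodione", 14, 17.28, 400, 3, 10),
        ("DDT", 2000, 0.198, 8.8, 3, 0.2),
        ("Fenthion", 34, 1.11, 0.22, 3, 2),
        ("Acephate", 3, 0.117, 1.8, 3, 1),
        ("Chlorpyrifos", 30, 0.00214, 0.072, 3, 0.05),
        ("Methidathion", 7, 0.025, 0.27, 3, 0.5),
    ],
    columns=[
        "name",
        "persistency_days",
        "aeq",
        "ld50_ug_per_bee",
        "likely_exposure",
        "mrl_mg_per_kg",
    ],
)

_DOSES = pd.DataFrame(
    [
        ("Abamectin", 750),
        ("Dodine", 2242),
        ("Dimethoate", 750),
        ("Clofentezine", 400),
        ("Iprodione", 1169),
        ("DDT", 2242),
        ("Fenthion", 10),
        ("Acephate", 780),
        ("Chlorpyrifos", 1700),
        ("Methidathion", 535.117),
    ],
    columns=["pesticide", "dose_ml_per_ha"],
)

_EXPECTED_SCORES = pd.DataFrame(
    [
        ("Abamectin", 2.63),
        ("Dodine", 7.37),
        ("Dimethoate", 2.63),
        ("Clofentezine", 5.44),
        ("Iprodione", 7.37),
        ("DDT", 2.75),
        ("Fenthion", 2.93),
        ("Acephate", 2.65),
        ("Chlorpyrifos", 2.63),
        ("Methidathion", 2.63),
    ],
    columns=["name", "safety_level_point"],
)

_EXPECTED_ORACLE = pd.DataFrame(
    [
        ("Abamectin", 2.63, 2.63, 1),
        ("Dodine", 7.37, 7.37, 1),
        ("Dimethoate", 2.63, 2.63, 1),
        ("Clofentezine", 5.44, 5.44, 1),
        ("Iprodione", 7.37, 7.37, 1),
        ("DDT", 2.75, 2.75, 1),
        ("Fenthion", 2.93, 2.93, 1),
        ("Acephate", 2.65, 2.65, 1),
        ("Chlorpyrifos", 2.63, 2.63, 1),
        ("Methidathion", 2.63, 2.63, 1),
    ],
    columns=["name", "centroid_calculation", "code_result", "verification_value"],
)

_FIXTURES = {
    "expert_ratings": _EXPERT_RATINGS,
    "pesticides": _PESTICIDES,
    "doses": _DOSES,
    "expected_scores": _EXPECTED_SCORES,
    "expected_oracle": _EXPECTED_ORACLE,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def load_fixture(name: str) -> pd.DataFrame:
    """Return a copy of one embedded table.

    ``name`` is one of ``expert_ratings``, ``pesticides``, ``doses``,
    ``expected_scores``, ``expected_oracle``.
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return _FIXTURES[name].copy()
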