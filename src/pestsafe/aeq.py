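"""Agroecology environment quality quotient (AEQ) from dose and bee LD50.

The AEQ is the reciprocal of the honey-bee toxic unit: the per-bee exposure
concentration a field application implies, divided by the contact LD50
toward honey bees, inverted. Small AEQ (< 1) means a single application
already delivers a median-lethal-scale dose per bee — high contamination;
AEQ >= 2 means the colony is essentially unaffected.

Chain of quantities for one pesticide:

    concentration = dose_per_ha * off_target_fraction * dose_unit_factor
                    / colony_size                      [per-bee dose]
    TU_bee        = concentration / ld50_bee
    AEQ           = 1 / TU_bee

Defaults: 99 % of a spray misses the target pest (``off_target_fraction``
0.99) and a colony holds 50,000 bees. ``dose_unit_factor`` (default 1000)
converts the dose table's mL-scale volumes onto the ug/bee scale of the
LD50; it is a calibration constant fixed against the published quotients
and deliberately exposed rather than interpreted (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AEQInputs",
    "concentration_per_bee",
    "toxic_unit",
    "compute_aeq",
    "read_dose_table",
    "aeq_from_dose_table",
    "DEFAULT_OFF_TARGET_FRACTION",
    "DEFAULT_COLONY_SIZE",
    "DEFAULT_DOSE_UNIT_FACTOR",
]

DEFAULT_OFF_TARGET_FRACTION = 0.99
DEFAULT_COLONY_SIZE = 50_000.0
DEFAULT_DOSE_UNIT_FACTOR = 1000.0


@dataclass(frozen=True)
class AEQInputs:
    """Inputs for one pesticide's AEQ computation."""

    dose_per_ha: float  # mL/ha
    ld50_bee: float  # ug/bee
    off_target_fraction: float = DEFAULT_OFF_TARGET_FRACTION
    colony_size: float = DEFAULT_COLONY_SIZE
    dose_unit_factor: float = DEFAULT_DOSE_UNIT_FACTOR

    def __post_init__(self) -> None:
        for name in ("dose_per_ha", "ld50_bee", "colony_size", "dose_unit_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.off_target_fraction <= 1.0:
            raise ValueError("off_target_fraction must be in (0, 1]")


def concentration_per_bee(inputs: AEQInputs) -> float:
    """Per-bee dose implied by a per-hectare application."""
    return (
        inputs.dose_per_ha
        * inputs.off_target_fraction
        * inputs.dose_unit_factor
        / inputs.colony_size
    )


def toxic_unit(concentration: float, ld50_bee: float) -> float:
    """Bee toxic unit: exposure concentration as a multiple of the LD50."""
    if ld50_bee <= 0:
        raise ValueError(f"ld50_bee must be strictly positive, got {ld50_bee}")
    return concentration / ld50_bee


def compute_aeq(inputs: AEQInputs) -> float:
    """AEQ = 1 / TU_bee for a single pesticide residue."""
    return 1.0 / toxic_unit(concentration_per_bee(inputs), inputs.ld50_bee)


def read_dose_table(path) -> pd.DataFrame:
    """Read a CSV dose table with columns ``pesticide, dose_ml_per_ha``."""
    df = pd.read_csv(path)
    missing = {"pesticide", "dose_ml_per_ha"} - set(df.columns)
    if missing:
        raise ValueError(f"dose table missing columns: {sorted(missing)}")
    if df["dose_ml_per_ha"].isna().any() or (df["dose_ml_per_ha"] <= 0).any():
        raise ValueError("dose_ml_per_ha must be positive and non-missing")
    return df


def aeq_from_dose_table(
    doses: pd.DataFrame,
    ld50: "pd.Series | dict[str, float]",
    **overrides,
) -> pd.Series:
    """AEQ per pesticide, joining a dose table onto LD50 values by name."""
    ld50 = pd.Series(ld50)
    out = {}
    for _, row in doses.iterrows():
        name = row["pesticide"]
        if name not in ld50.index:
            raise KeyError(f"no LD50 for pesticide {name!r}")
        out[name] = compute_aeq(
            AEQInputs(
                dose_per_ha=float(row["dose_ml_per_ha"]),
                ld50_bee=float(ld50[name]),
                **overrides,
            )
        )
    return pd.Series(out, name="aeq")
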