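"""Reading pesticide tables and writing assessment reports.

Input tables are plain UTF-8 CSV with a header row::

    name,persistency_days,aeq,ld50_ug_per_bee,likely_exposure,mrl_mg_per_kg

The ``aeq`` column may be blank when a ``dose_ml_per_ha`` column is
present; the quotient is then computed from the dose and the record's
LD50 with the default exposure assumptions.

Report writers mirror the two published result tables: the ranked safety
scores and the dual-route centroid parity check.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .aeq import AEQInputs, compute_aeq
from .assessor import AssessmentResult, PesticideRecord

__all__ = [
    "RunConfig",
    "REQUIRED_COLUMNS",
    "read_pesticide_table",
    "records_to_csv",
    "format_report",
    "format_verification_report",
    "results_to_csv",
    "results_to_json",
]

REQUIRED_COLUMNS = (
    "name",
    "persistency_days",
    "aeq",
    "ld50_ug_per_bee",
    "likely_exposure",
    "mrl_mg_per_kg",
)


@dataclass(frozen=True)
class RunConfig:
    """Options governing one assessment run."""

    model_path: str | None = None  # None -> built-in calibrated model
    step: float = 0.01
    off_target_fraction: float = 0.99
    colony_size: float = 50_000.0
    dose_unit_factor: float = 1000.0
    output_format: str = "text"  # text | csv | json

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 0.0 < self.off_target_fraction <= 1.0:
            raise ValueError("off_target_fraction must be in (0, 1]")
        if self.output_format not in ("text", "csv", "json"):
            raise ValueError(f"unknown output format {self.output_format!r}")


def read_pesticide_table(path, config: RunConfig | None = None) -> list[PesticideRecord]:
    """Parse a pesticide CSV into validated records.

    A blank ``aeq`` cell is filled from ``dose_ml_per_ha`` when that
    column exists; any other missing or non-numeric cell raises an error
    naming the row and column.
    """
    config = config or RunConfig()
    df = pd.read_csv(path, dtype={"name": str})
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = set(REQUIRED_COLUMNS) - {"aeq"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_aeq = "aeq" in df.columns
    has_dose = "dose_ml_per_ha" in df.columns
    if not has_aeq and not has_dose:
        raise ValueError(f"{path}: need an 'aeq' or 'dose_ml_per_ha' column")

    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, after the header
        vals = {}
        for col in ("persistency_days", "ld50_ug_per_bee", "likely_exposure", "mrl_mg_per_kg"):
            v = row[col]
            if pd.isna(v):
                raise ValueError(f"{path}: row {rownum}, column {col!r}: empty cell")
            try:
                vals[col] = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {rownum}, column {col!r}: non-numeric value {v!r}"
                ) from None
        aeq_val = row["aeq"] if has_aeq else float("nan")
        if pd.isna(aeq_val):
            if not has_dose or pd.isna(row["dose_ml_per_ha"]):
                raise ValueError(
                    f"{path}: row {rownum}: blank aeq and no dose to compute it from"
                )
            aeq_val = compute_aeq(
                AEQInputs(
                    dose_per_ha=float(row["dose_ml_per_ha"]),
                    ld50_bee=vals["ld50_ug_per_bee"],
                    off_target_fraction=config.off_target_fraction,
                    colony_size=config.colony_size,
                    dose_unit_factor=config.dose_unit_factor,
                )
            )
        records.append(
            PesticideRecord(
                name=str(row["name"]),
                persistency=vals["persistency_days"],
                aeq=float(aeq_val),
                ld50_bee=vals["ld50_ug_per_bee"],
                likely_exposure=vals["likely_exposure"],
                mrl=vals["mrl_mg_per_kg"],
            )
        )
    return records


def records_to_csv(records: Sequence[PesticideRecord]) -> str:
    """Serialize records back to the input CSV dialect (numeric fields exact)."""
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(REQUIRED_COLUMNS)
    for r in records:
        w.writerow(
            [r.name, _num(r.persistency), _num(r.aeq), _num(r.ld50_bee),
             _num(r.likely_exposure), _num(r.mrl)]
        )
    return buf.getvalue()


def _num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def format_report(results: Sequence[AssessmentResult]) -> str:
    """Ranked aligned-text report of safety level points (safest first)."""
    width = max(len(r.name) for r in results)
    lines = [f"{'Pesticide':{width}}  Safety Level Point"]
    for r in results:
        lines.append(f"{r.name:{width}}  {r.score_2dp:.2f}")
    best = [r.name for r in results if r.score_2dp == results[0].score_2dp]
    worst_score = results[-1].score_2dp
    worst = [r.name for r in results if r.score_2dp == worst_score]
    lines.append("")
    lines.append(f"Best option(s):  {', '.join(best)}")
    lines.append(f"Worst option(s): {', '.join(worst)}")
    return "\n".join(lines) + "\n"


def format_verification_report(results: Sequence[AssessmentResult]) -> str:
    """Aligned-text dual-route parity report (oracle vs discretized code path)."""
    width = max(len(r.name) for r in results)
    lines = [f"{'Pesticide':{width}}  Centroid Calculation  Result from Code  Verification Value"]
    for r in results:
        lines.append(
            f"{r.name:{width}}  {r.oracle_2dp:>20.2f}  {r.score_2dp:>16.2f}"
            f"  {r.verification_value:>18d}"
        )
    return "\n".join(lines) + "\n"


def results_to_csv(results: Sequence[AssessmentResult]) -> str:
    """Compact CSV: name, score, oracle score, verification value."""
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["name", "safety_level_point", "oracle_score", "verification_value"])
    for r in results:
        w.writerow([r.name, f"{r.score_2dp:.2f}", f"{r.oracle_2dp:.2f}", r.verification_value])
    return buf.getvalue()


def results_to_json(results: Sequence[AssessmentResult]) -> str:
    """Full JSON report including the rule-activation trace."""
    return json.dumps([r.to_dict() for r in results], indent=2, sort_keys=False)
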