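"""CSV readers/writers for cohorts, questions and effect tables; JSON reports.

Cohort CSV schema (comma-separated, UTF-8, header required, percentages as
plain numbers on 0-100): ``participant_id, condition, completed, looked_up,
defocused, sex, age, q1_g1..qK_g1, q1_g2..qK_g2``.  An empty guess cell is a
blank answer (NaN); out-of-range values load fine and are left to the
question-level cleaning rule.  An optional ``column_map`` renames external
layouts onto this schema at read time.

Reports serialize to JSON with sorted keys, full-precision values plus
display-rounded twins, and a schema-version stamp, so identical reports
produce identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import BayesFactorResult
from .effects import EffectSizeEstimate, StudyEffect, TestResult
from .pipeline import (
    ExclusionLog,
    ParticipantRecord,
    QuestionSet,
    ReplicationReport,
)

__all__ = [
    "SchemaError",
    "read_cohort_csv",
    "read_effect_table_csv",
    "read_questions_csv",
    "read_report_json",
    "report_to_dict",
    "write_cohort_csv",
    "write_report_json",
]


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _as_bool(value: Any, row: int, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)) and not (
        isinstance(value, float) and math.isnan(value)
    ):
        return bool(value)
    try:
        return _BOOL[str(value).strip().lower()]
    except KeyError:
        raise SchemaError(f"row {row}: cannot parse {column}={value!r} as a boolean") from None


def _guess_columns(columns: Sequence[str]) -> tuple[list[str], list[str]]:
    k = 1
    g1, g2 = [], []
    while f"q{k}_g1" in columns:
        g1.append(f"q{k}_g1")
        k += 1
    for i in range(1, k):
        g2.append(f"q{i}_g2")
    return g1, g2


def read_cohort_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[ParticipantRecord]:
    """Load a cohort CSV into participant records.

    ``column_map`` maps external column names onto the canonical schema
    (e.g. ``{"subject": "participant_id"}``).
    """
    df = pd.read_csv(path, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if len(df) == 0:
        raise SchemaError(f"{path}: no participant rows")
    required = ["participant_id", "condition", "completed", "looked_up", "defocused"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    g1_cols, g2_cols = _guess_columns(df.columns)
    if not g1_cols:
        raise SchemaError(f"{path}: no guess columns (expected q1_g1, q1_g2, ...)")
    for col in g2_cols:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")

    def parse_guess(value: Any, row: int, col: str) -> float:
        if value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == "":
            return math.nan
        try:
            return float(value)
        except ValueError:
            raise SchemaError(f"row {row}, column {col}: non-numeric guess {value!r}") from None

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        age = d.get("age")
        records.append(
            ParticipantRecord(
                participant_id=str(d["participant_id"]),
                condition=str(d["condition"]),
                completed=_as_bool(d["completed"], i, "completed"),
                looked_up=_as_bool(d["looked_up"], i, "looked_up"),
                defocused=_as_bool(d["defocused"], i, "defocused"),
                sex=None if pd.isna(d.get("sex")) else str(d.get("sex")),
                age=None if age is None or pd.isna(age) else float(age),
                guess1=np.array([parse_guess(d[c], i, c) for c in g1_cols]),
                guess2=np.array([parse_guess(d[c], i, c) for c in g2_cols]),
            )
        )
    return records


def write_cohort_csv(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    """Write participant records in the canonical cohort CSV schema."""
    if not records:
        raise ValueError("no records to write")
    k = records[0].guess1.size
    rows = []
    for r in records:
        row: dict[str, Any] = {
            "participant_id": r.participant_id,
            "condition": r.condition,
            "completed": r.completed,
            "looked_up": r.looked_up,
            "defocused": r.defocused,
            "sex": r.sex if r.sex is not None else "",
            "age": r.age if r.age is not None else "",
        }
        for i in range(k):
            row[f"q{i + 1}_g1"] = "" if math.isnan(r.guess1[i]) else repr(float(r.guess1[i]))
        for i in range(k):
            row[f"q{i + 1}_g2"] = "" if math.isnan(r.guess2[i]) else repr(float(r.guess2[i]))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_questions_csv(path: str | Path) -> QuestionSet:
    """Load a question table (columns: question_id, truth)."""
    df = pd.read_csv(path)
    for col in ("question_id", "truth"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return QuestionSet(tuple(str(q) for q in df["question_id"]), tuple(float(t) for t in df["truth"]))


def read_effect_table_csv(path: str | Path) -> list[StudyEffect]:
    """Load a pooling table (columns: label, t, n, r), converting t to d_z."""
    df = pd.read_csv(path)
    for col in ("label", "t", "n", "r"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return [
        StudyEffect.from_t(str(row.label), float(row.t), int(row.n), float(row.r))
        for row in df.itertuples(index=False)
    ]


_DISPLAY_DP = {
    "t": 2,
    "p_two_tailed": 3,
    "mean_diff": 1,
    "value": 2,
    "ci_low": 2,
    "ci_high": 2,
    "bf01": 3,
    "d33": 2,
}


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, ExclusionLog):
        return obj.counts()
    if isinstance(obj, (TestResult, EffectSizeEstimate, BayesFactorResult)):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            out[f.name] = _jsonify(v)
            if f.name in _DISPLAY_DP and isinstance(v, (int, float)) and math.isfinite(v):
                out[f.name + "_display"] = round(v, _DISPLAY_DP[f.name])
        if isinstance(obj, BayesFactorResult):
            out["bf10"] = obj.bf10
        return out
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            out[f.name] = _jsonify(v)
            if f.name in _DISPLAY_DP and isinstance(v, (int, float)) and math.isfinite(v):
                out[f.name + "_display"] = round(v, _DISPLAY_DP[f.name])
        return out
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def report_to_dict(report: ReplicationReport) -> dict[str, Any]:
    """Serialize a report to plain JSON-ready types.

    Detectability verdicts that could not be computed (no original sample
    size) appear as the explicit string ``"unavailable"``.
    """
    d = _jsonify(report)
    for cond in d.get("conditions", {}).values():
        if cond.get("detectability_success") is None:
            cond["detectability_success"] = "unavailable"
    return d


def write_report_json(report: ReplicationReport | dict[str, Any], path: str | Path) -> None:
    """Write a report (or an already-serialized report dict) as canonical JSON."""
    d = report_to_dict(report) if isinstance(report, ReplicationReport) else report
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_report_json(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
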