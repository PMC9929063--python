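"""Cohort CSV and tool JSON interchange.

Cohort CSV layout: one row per record with columns
``record_id, period, <item ids in schema order>, admin_cooperation,
hospital_support, epds_total``; indicators are 0/1 with empty cells for
missing.  Tool definitions serialize to versioned JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .derive import ScoreEntry, ScoringTable, ScreeningToolDefinition, StepRule
from .errors import CohortParseError, ToolValidationError
from .schema import Cohort, Period, PeriodSchema, Record

TOOL_SCHEMA_VERSION = 1

PathLike = Union[str, Path]


def cohort_to_frame(cohort: Cohort, schema: PeriodSchema) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        row: dict = {"record_id": rec.record_id, "period": rec.period.value}
        for item in schema.item_ids:
            row[item] = rec.indicators.get(item)
        row["admin_cooperation"] = rec.admin_cooperation
        row["hospital_support"] = rec.hospital_support
        row["epds_total"] = rec.epds_total
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: Cohort, schema: PeriodSchema, path: PathLike) -> None:
    cohort_to_frame(cohort, schema).to_csv(path, index=False)


def _parse_binary(value, row: int, column: str):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        i = int(float(value))
    except (TypeError, ValueError):
        raise CohortParseError(f"row {row}: column {column!r}: {value!r} is not 0/1") from None
    if i not in (0, 1):
        raise CohortParseError(f"row {row}: column {column!r}: {value!r} is not 0/1")
    return i


def read_cohort_csv(path: PathLike, schema: PeriodSchema) -> Cohort:
    """Parse a cohort CSV; empty cells become missing; errors carry row numbers."""
    try:
        frame = pd.read_csv(path, dtype=object)
    except pd.errors.EmptyDataError:
        raise CohortParseError(f"{path}: empty cohort file") from None
    if frame.empty:
        raise CohortParseError(f"{path}: cohort file has a header but no records")

    expected = ["record_id", "period", *schema.item_ids, "admin_cooperation", "hospital_support", "epds_total"]
    unknown = set(frame.columns) - set(expected)
    if unknown:
        raise CohortParseError(f"{path}: unknown columns {sorted(unknown)}")
    missing_cols = {"record_id", "period", *schema.item_ids} - set(frame.columns)
    if missing_cols:
        raise CohortParseError(f"{path}: missing columns {sorted(missing_cols)}")

    records = []
    for pos, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        data = dict(zip(frame.columns, row))
        period = data["period"]
        if period != schema.period.value:
            raise CohortParseError(f"row {pos}: period {period!r} does not match schema {schema.period.value!r}")
        indicators = {item: _parse_binary(data.get(item), pos, item) for item in schema.item_ids}
        epds = data.get("epds_total")
        if epds is None or (isinstance(epds, float) and pd.isna(epds)) or epds == "":
            epds_total = None
        else:
            try:
                epds_total = int(float(epds))
            except (TypeError, ValueError):
                raise CohortParseError(f"row {pos}: epds_total {epds!r} is not an integer") from None
            if not (0 <= epds_total <= 30):
                raise CohortParseError(f"row {pos}: epds_total {epds_total} outside 0-30")
        records.append(
            Record(
                record_id=str(data["record_id"]),
                period=schema.period,
                indicators=indicators,
                admin_cooperation=_parse_binary(data.get("admin_cooperation"), pos, "admin_cooperation"),
                hospital_support=_parse_binary(data.get("hospital_support"), pos, "hospital_support"),
                epds_total=epds_total,
            )
        )
    return Cohort(records=records, period=schema.period, provenance=str(path))


# ---------------------------------------------------------------------------
# tool JSON


def tool_to_dict(tool: ScreeningToolDefinition) -> dict:
    return {
        "schema_version": TOOL_SCHEMA_VERSION,
        "period": tool.period.value,
        "provenance": tool.provenance,
        "rounding_mode": tool.scoring.rounding_mode,
        "scoring": {k: {"sprc": e.sprc, "score": e.score} for k, e in tool.scoring.entries.items()},
        "step1_threshold": tool.step1_threshold,
        "step2": {"rule": "any_of" if tool.step2.min_count == 1 else f"min_{tool.step2.min_count}",
                  "min_count": tool.step2.min_count, "items": list(tool.step2.items)},
        "step3": {"min_count": tool.step3.min_count, "items": list(tool.step3.items)},
        "step_semantics": tool.step_semantics,
        "mandatory_referral_items": list(tool.mandatory_referral_items),
    }


def tool_from_dict(data: dict) -> ScreeningToolDefinition:
    version = data.get("schema_version")
    if version != TOOL_SCHEMA_VERSION:
        raise ToolValidationError(f"unsupported tool schema version {version!r}")
    threshold = data["step1_threshold"]
    if not isinstance(threshold, (int, float)) or isinstance(threshold, bool):
        raise ToolValidationError(f"step1_threshold must be numeric, got {threshold!r}")
    period = Period.coerce(data["period"])
    try:
        scoring = ScoringTable(
            period=period,
            entries={k: ScoreEntry(sprc=float(v["sprc"]), score=float(v["score"]))
                     for k, v in data["scoring"].items()},
            rounding_mode=data["rounding_mode"],
        )
        tool = ScreeningToolDefinition(
            period=period,
            scoring=scoring,
            step1_threshold=float(threshold),
            step2=StepRule(items=tuple(data["step2"]["items"]),
                           min_count=int(data["step2"].get("min_count", 1))),
            step3=StepRule(items=tuple(data["step3"]["items"]),
                           min_count=int(data["step3"]["min_count"])),
            step_semantics=data.get("step_semantics", "sequential_narrowing"),
            mandatory_referral_items=tuple(data.get("mandatory_referral_items", ())),
            provenance=data.get("provenance", "unknown"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ToolValidationError(f"malformed tool definition: {exc!r}") from exc
    tool.validate()
    return tool


def write_tool_json(tool: ScreeningToolDefinition, path: PathLike) -> None:
    Path(path).write_text(json.dumps(tool_to_dict(tool), indent=2, ensure_ascii=False), "utf-8")


def read_tool_json(path: PathLike) -> ScreeningToolDefinition:
    try:
        data = json.loads(Path(path).read_text("utf-8"))
    except json.JSONDecodeError as exc:
        raise ToolValidationError(f"{path}: not valid JSON: {exc}") from exc
    return tool_from_dict(data)
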