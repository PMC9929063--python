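"""Questionnaire schemas and risk coding.

The antenatal interview sheet asks a fixed set of items per contact
period (first visit, ~28 weeks, ~36 weeks, postpartum).  Every item has
a *positive* (non-risk) answer set and a *negative* (risk) answer set;
a record stores the risk indicator: 1 = risk-side answer, 0 = non-risk,
``None`` = unanswered.  Missingness is a first-class third state and is
never imputed here — downstream consumers decide how to handle it.

The packaged schema file transcribes the published item lists verbatim;
item ids are frozen snake_case slugs so that tool definitions remain
stable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Callable, Iterable, Iterator, Mapping, Optional

from .errors import CodingError, SchemaError

Indicator = Optional[int]  # 1 risk, 0 non-risk, None missing


class Period(str, Enum):
    FIRST_VISIT = "first_visit"
    SECOND_TRIMESTER = "second_trimester"
    THIRD_TRIMESTER = "third_trimester"
    POSTPARTUM = "postpartum"

    @classmethod
    def coerce(cls, value: "Period | str") -> "Period":
        if isinstance(value, Period):
            return value
        try:
            return cls(value)
        except ValueError as exc:
            raise SchemaError(f"unknown period {value!r}") from exc


def _normalize(answer: str) -> str:
    return " ".join(str(answer).split()).casefold()


@dataclass(frozen=True)
class ItemSchema:
    """One interview item with its risk coding."""

    item_id: str
    period: Period
    label: str
    positive_answers: frozenset[str]
    negative_answers: frozenset[str]

    def __post_init__(self) -> None:
        pos = frozenset(_normalize(a) for a in self.positive_answers)
        neg = frozenset(_normalize(a) for a in self.negative_answers)
        if not pos or not neg:
            raise SchemaError(f"{self.item_id}: positive and negative answer sets must be non-empty")
        if pos & neg:
            raise SchemaError(f"{self.item_id}: answers on both sides: {sorted(pos & neg)}")
        object.__setattr__(self, "_pos_norm", pos)
        object.__setattr__(self, "_neg_norm", neg)

    def encode_answer(self, answer: str) -> int:
        """Map a raw answer string to its risk indicator (1 = risk)."""
        key = _normalize(answer)
        if key in self._neg_norm:
            return 1
        if key in self._pos_norm:
            return 0
        raise CodingError(
            f"item {self.item_id!r}: answer {answer!r} is neither a positive nor a negative answer"
        )

    def indicator_to_answer(self, indicator: int) -> str:
        """A representative raw answer for an indicator value (inverse of encoding)."""
        answers = self.negative_answers if indicator == 1 else self.positive_answers
        return sorted(answers)[0]


@dataclass(frozen=True)
class PeriodSchema:
    """The ordered item list of one contact period."""

    period: Period
    items: tuple[ItemSchema, ...]

    def __post_init__(self) -> None:
        ids = [i.item_id for i in self.items]
        if len(ids) != len(set(ids)):
            raise SchemaError(f"duplicate item ids in {self.period.value}")
        for item in self.items:
            if item.period != self.period:
                raise SchemaError(f"item {item.item_id} has period {item.period}, schema is {self.period}")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i.item_id for i in self.items)

    def __getitem__(self, item_id: str) -> ItemSchema:
        for item in self.items:
            if item.item_id == item_id:
                return item
        raise SchemaError(f"unknown item {item_id!r} for period {self.period.value}")

    def __iter__(self) -> Iterator[ItemSchema]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class Record:
    """One woman's risk indicators plus outcome labels.

    ``admin_cooperation`` is the derivation outcome: whether the case was
    judged to need coordinated support from a public health center.
    ``hospital_support`` marks socially high-risk cases supported within
    the obstetric institution.  ``epds_total`` (0-30) is only meaningful
    when a postpartum depression-scale assessment is linked.
    """

    record_id: str
    period: Period
    indicators: dict[str, Indicator]
    admin_cooperation: Optional[int] = None
    hospital_support: Optional[int] = None
    epds_total: Optional[int] = None


@dataclass
class Cohort:
    """A period-tagged collection of records."""

    records: list[Record]
    period: Period
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def outcome_values(self, outcome: "str | Callable[[Record], Optional[int]]") -> list[Optional[int]]:
        """Extract an outcome vector; ``outcome`` is a field name or a callable."""
        if callable(outcome):
            return [outcome(r) for r in self.records]
        if outcome not in ("admin_cooperation", "hospital_support"):
            raise SchemaError(f"unknown outcome field {outcome!r}")
        return [getattr(r, outcome) for r in self.records]


# ---------------------------------------------------------------------------
# packaged schema


def _load_raw_schema() -> dict:
    text = resources.files("obscreen.data").joinpath("interview_schema.json").read_text("utf-8")
    return json.loads(text)


def load_period_schema(period: Period | str) -> PeriodSchema:
    """Load the packaged interview-sheet schema for one period."""
    period = Period.coerce(period)
    raw = _load_raw_schema()[period.value]
    items = tuple(
        ItemSchema(
            item_id=entry["item_id"],
            period=period,
            label=entry["label"],
            positive_answers=frozenset(entry["positive"]),
            negative_answers=frozenset(entry["negative"]),
        )
        for entry in raw
    )
    return PeriodSchema(period=period, items=items)


def load_all_schemas() -> dict[Period, PeriodSchema]:
    return {p: load_period_schema(p) for p in Period}


# ---------------------------------------------------------------------------
# operations


def encode_record(
    raw_answers: Mapping[str, str],
    schema: PeriodSchema,
    record_id: str = "r0",
    **outcomes,
) -> Record:
    """Encode raw answer strings into a risk-indicator record.

    Unanswered items become missing.  Unknown item ids raise
    :class:`SchemaError`; answers matching neither side raise
    :class:`CodingError` naming the item and answer.  Matching is
    case-insensitive after whitespace normalization.
    """
    known = set(schema.item_ids)
    unknown = set(raw_answers) - known
    if unknown:
        raise SchemaError(f"unknown item ids for {schema.period.value}: {sorted(unknown)}")
    indicators: dict[str, Indicator] = {i: None for i in schema.item_ids}
    for item_id, answer in raw_answers.items():
        indicators[item_id] = schema[item_id].encode_answer(answer)
    return Record(record_id=record_id, period=schema.period, indicators=indicators, **outcomes)


@dataclass
class ValidationReport:
    """Report-only summary of a cohort against its period schema."""

    n_records: int
    missing_counts: dict[str, int]
    flagged_records: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flagged_records


def validate_cohort(cohort: Cohort, schema: PeriodSchema) -> ValidationReport:
    """Count per-item missingness and flag records violating invariants.

    Never mutates the cohort; a flagged record is reported, not dropped.
    """
    missing = {i: 0 for i in schema.item_ids}
    flagged: list[tuple[str, str]] = []
    known = set(schema.item_ids)
    for rec in cohort:
        if rec.period != cohort.period:
            flagged.append((rec.record_id, f"period {rec.period.value} != cohort {cohort.period.value}"))
        extra = set(rec.indicators) - known
        if extra:
            flagged.append((rec.record_id, f"unknown indicator keys {sorted(extra)}"))
        for item_id in schema.item_ids:
            value = rec.indicators.get(item_id)
            if value is None:
                missing[item_id] += 1
            elif value not in (0, 1):
                flagged.append((rec.record_id, f"{item_id}: indicator {value!r} not in {{0, 1, missing}}"))
        if rec.epds_total is not None and not (0 <= rec.epds_total <= 30):
            flagged.append((rec.record_id, f"epds_total {rec.epds_total} outside 0-30"))
    return ValidationReport(n_records=len(cohort), missing_counts=missing, flagged_records=flagged)
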