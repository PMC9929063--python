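"""Applying a frozen screening tool to records and cohorts.

Sequential semantics (the default): a record is STEP-1 positive when its
total item score reaches the threshold; STEP-1 positives are narrowed by
STEP-2 (any configured risk item present) and then STEP-3 (at least
``min_count`` of the configured items present).  A risk answer on a
mandatory-referral item (e.g. illegal drug use) short-circuits to
positive regardless of score.  Missing indicators contribute zero
points — the screen stays usable on partial forms — and the number of
missing scored items is reported per record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from ._util import percent
from .derive import ScreeningToolDefinition, StepRule
from .errors import ObscreenError
from .schema import Cohort, Record


class Stage(str, Enum):
    NEGATIVE_STEP1 = "negative_step1"
    NEGATIVE_STEP2 = "negative_step2"
    NEGATIVE_STEP3 = "negative_step3"
    POSITIVE = "positive"


@dataclass
class ScreeningResult:
    record_id: str
    total_score: float
    stage_reached: Stage
    mandatory_referral: bool = False
    missing_items_used: int = 0


@dataclass
class StageSummary:
    name: str
    survivors: int
    outcome_positive: int

    def pct_outcome(self, decimals: int = 0) -> float:
        """Outcome-positive share among this stage's survivors."""
        return percent(self.outcome_positive, self.survivors, decimals)


@dataclass
class FunnelReport:
    """Stage-by-stage counts with outcome overlap.

    ``stages`` counts survivors of each step among non-mandatory
    records; mandatory referrals are tallied separately and included in
    the final positive count.
    """

    n_screened: int
    stages: list[StageSummary]
    n_mandatory: int
    final_positive: int
    final_outcome_positive: int
    stage_counts: dict[str, int] = field(default_factory=dict)  # partition by stage_reached

    def pct_positive(self, decimals: int = 1) -> float:
        return percent(self.final_positive, self.n_screened, decimals)

    def stage(self, name: str) -> StageSummary:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)


def total_score(record: Record, tool: ScreeningToolDefinition) -> float:
    """Sum of points over risk-positive scored items (missing -> 0 points)."""
    return round(
        sum(e.score for item, e in tool.scoring.entries.items() if record.indicators.get(item) == 1),
        10,
    )


def _rule_hits(record: Record, rule: StepRule) -> int:
    return sum(1 for item in rule.items if record.indicators.get(item) == 1)


def apply_tool(record: Record, tool: ScreeningToolDefinition) -> ScreeningResult:
    """Evaluate one record against the tool's steps."""
    if record.period != tool.period:
        raise ObscreenError(
            f"record period {record.period.value} does not match tool period {tool.period.value}"
        )
    score = total_score(record, tool)
    missing_used = sum(1 for item in tool.scoring.entries if record.indicators.get(item) is None)

    if any(record.indicators.get(item) == 1 for item in tool.mandatory_referral_items):
        return ScreeningResult(record.record_id, score, Stage.POSITIVE, True, missing_used)

    step1 = score >= tool.step1_threshold
    step2 = _rule_hits(record, tool.step2) >= tool.step2.min_count
    step3 = _rule_hits(record, tool.step3) >= tool.step3.min_count

    if tool.step_semantics == "union":
        stage = Stage.POSITIVE if (step1 or step2 or step3) else Stage.NEGATIVE_STEP1
        return ScreeningResult(record.record_id, score, stage, False, missing_used)

    if not step1:
        stage = Stage.NEGATIVE_STEP1
    elif not step2:
        stage = Stage.NEGATIVE_STEP2
    elif not step3:
        stage = Stage.NEGATIVE_STEP3
    else:
        stage = Stage.POSITIVE
    return ScreeningResult(record.record_id, score, stage, False, missing_used)


_SURVIVES = {
    "step1": (Stage.NEGATIVE_STEP2, Stage.NEGATIVE_STEP3, Stage.POSITIVE),
    "step2": (Stage.NEGATIVE_STEP3, Stage.POSITIVE),
    "step3": (Stage.POSITIVE,),
}


def screen_cohort(
    cohort: Cohort,
    tool: ScreeningToolDefinition,
    outcome: str = "admin_cooperation",
) -> tuple[list[ScreeningResult], FunnelReport]:
    """Screen every record and aggregate the stage funnel.

    Stage percentages use the stage's own survivor count as denominator
    (the convention of published funnels); ``pct_positive`` uses
    ``n_screened``.
    """
    results = [apply_tool(rec, tool) for rec in cohort]
    ys = cohort.outcome_values(outcome)

    stages = []
    for name, surviving in _SURVIVES.items():
        idx = [i for i, r in enumerate(results) if not r.mandatory_referral and r.stage_reached in surviving]
        stages.append(
            StageSummary(
                name=name,
                survivors=len(idx),
                outcome_positive=sum(1 for i in idx if ys[i] == 1),
            )
        )

    mandatory_idx = [i for i, r in enumerate(results) if r.mandatory_referral]
    positive_idx = [i for i, r in enumerate(results) if r.stage_reached is Stage.POSITIVE]
    counts: dict[str, int] = {s.value: 0 for s in Stage}
    for r in results:
        counts[r.stage_reached.value] += 1

    report = FunnelReport(
        n_screened=len(cohort),
        stages=stages,
        n_mandatory=len(mandatory_idx),
        final_positive=len(positive_idx),
        final_outcome_positive=sum(1 for i in positive_idx if ys[i] == 1),
        stage_counts=counts,
    )
    return results, report
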