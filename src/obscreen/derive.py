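"""Derivation of a stepwise screening tool from a cohort.

Pipeline, mirroring how the published tools were built:

1. Fit a crude (univariate) logistic model per item and one joint model
   over all analyzable items.
2. Exclude items whose crude and adjusted associations point in
   opposite directions (sign reversal), items flagged as mandatory
   referrals (a risk answer short-circuits the screen regardless of
   score), and items that cannot be analyzed (separation, zero
   variance).
3. Refit the joint model on the retained items ("Model-2"); its
   standardized partial regression coefficients times 100 become the
   item points.
4. Pick the STEP-1 score cutoff from the ROC curve (Youden's index,
   ties toward the lower, more sensitive threshold).
5. Build STEP-2 either from item prevalence among outcome-positive
   cases (>= 30% of that group) or, when STEP-1 is weakly specific,
   from Spearman correlations on the STEP-1-positive subset (rho x 10
   >= 2 points).
6. STEP-3 (a minimum count over a configured item set) is a config
   input: the published tools state the item sets without a selection
   criterion.
7. Accept the tool iff the STEP-1 AUC clears ``min_auc`` (default
   0.70); the published third-trimester derivation fails this gate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._util import round_half_up
from .errors import DegenerateInputError, ParameterError, PipelineOrderError, ToolValidationError
from .schema import Cohort, Period, PeriodSchema, load_period_schema
from .stats import (
    CutoffResult,
    FitResult,
    fit_crude,
    fit_linear_standardized,
    fit_logistic_ml,
    roc_curve,
    select_cutoff,
    spearman_rho,
)

ROUNDING_MODES = ("times100_one_decimal", "times100_nearest_integer")


# ---------------------------------------------------------------------------
# frozen tool types


@dataclass
class ScoreEntry:
    sprc: float
    score: float


@dataclass
class ScoringTable:
    period: Period
    entries: dict[str, ScoreEntry]
    rounding_mode: str

    def __post_init__(self) -> None:
        if self.rounding_mode not in ROUNDING_MODES:
            raise ToolValidationError(f"unknown rounding mode {self.rounding_mode!r}")
        for item, e in self.entries.items():
            if e.score < 0:
                raise ToolValidationError(f"negative score for {item}")

    @property
    def max_score(self) -> float:
        return round(sum(e.score for e in self.entries.values()), 10)


@dataclass
class StepRule:
    items: tuple[str, ...]
    min_count: int = 1  # any_of is min_count == 1


@dataclass
class ScreeningToolDefinition:
    """A frozen, serializable screening tool."""

    period: Period
    scoring: ScoringTable
    step1_threshold: float
    step2: StepRule
    step3: StepRule
    step_semantics: str = "sequential_narrowing"
    mandatory_referral_items: tuple[str, ...] = ()
    provenance: str = "derived"

    def validate(self, schema: Optional[PeriodSchema] = None) -> None:
        if self.step_semantics not in ("sequential_narrowing", "union"):
            raise ToolValidationError(f"unknown step semantics {self.step_semantics!r}")
        for rule, name in ((self.step2, "step2"), (self.step3, "step3")):
            if rule.min_count < 1:
                raise ToolValidationError(f"{name}.min_count must be >= 1")
            if self.step_semantics == "sequential_narrowing" and not rule.items:
                raise ToolValidationError(f"{name} item set empty under sequential semantics")
        if schema is not None:
            known = set(schema.item_ids)
            for rule, name in ((self.step2, "step2"), (self.step3, "step3")):
                unknown = set(rule.items) - known
                if unknown:
                    raise ToolValidationError(f"{name} items not in {self.period.value} schema: {sorted(unknown)}")


@dataclass
class DerivationConfig:
    period: Period
    outcome: str = "admin_cooperation"
    rounding_mode: str = "times100_one_decimal"
    step2_strategy: str = "prevalence"  # or "weighted_spearman"
    step2_prevalence_threshold: float = 0.30
    step2_inclusive: bool = True
    step2_weight: float = 10.0
    step2_min_points: float = 2.0
    step3_items: tuple[str, ...] = ()
    step3_min_count: int = 1
    mandatory_referral_items: tuple[str, ...] = ()
    min_auc: float = 0.70
    step_semantics: str = "sequential_narrowing"


@dataclass
class DerivationReport:
    period: Period
    excluded_sign_reversal: list[str]
    excluded_other: list[tuple[str, str]]  # (item_id, reason)
    model1: FitResult
    model2: FitResult
    roc: Optional[CutoffResult]
    step2_items: tuple[str, ...]
    step3_items: tuple[str, ...]
    accepted: bool
    rejection_reason: Optional[str] = None


# ---------------------------------------------------------------------------
# stages


def exclude_sign_reversals(model1: FitResult, model2: FitResult) -> list[str]:
    """Items whose crude and adjusted associations point in opposite directions.

    Crude OR > 1 with adjusted OR < 1 (or vice versa) excludes the item;
    an OR of exactly 1 has no direction and never triggers exclusion.
    Items missing an odds ratio fall back to coefficient signs.
    """
    excluded = []
    m2 = {t.item_id: t for t in model2.terms}
    for t1 in model1.terms:
        t2 = m2.get(t1.item_id)
        if t2 is None:
            continue

        def _direction(t):
            if t.odds_ratio is not None and math.isfinite(t.odds_ratio):
                return (t.odds_ratio > 1.0) - (t.odds_ratio < 1.0)
            return (t.coefficient > 0.0) - (t.coefficient < 0.0)

        d1, d2 = _direction(t1), _direction(t2)
        if d1 * d2 < 0:
            excluded.append(t1.item_id)
    return excluded


def score_items(model2: FitResult, rounding_mode: str, period: Optional[Period] = None) -> ScoringTable:
    """Turn SPRCs into item points: score = SPRC x 100 under the rounding mode.

    A negative SPRC reaching this stage means sign-reversal exclusion
    was skipped, which is a pipeline-order error.
    """
    if rounding_mode not in ROUNDING_MODES:
        raise ToolValidationError(f"unknown rounding mode {rounding_mode!r}")
    decimals = 1 if rounding_mode == "times100_one_decimal" else 0
    entries: dict[str, ScoreEntry] = {}
    for t in model2.terms:
        sprc = t.standardized_coefficient
        if sprc is None:
            raise PipelineOrderError(f"{t.item_id}: no standardized coefficient; fit a standardized linear model")
        if sprc < 0:
            raise PipelineOrderError(f"{t.item_id}: negative SPRC {sprc}; sign reversals must be excluded first")
        entries[t.item_id] = ScoreEntry(sprc=float(sprc), score=round_half_up(sprc * 100.0, decimals))
    return ScoringTable(period=period or Period.FIRST_VISIT, entries=entries, rounding_mode=rounding_mode)


def total_scores(cohort: Cohort, scoring: ScoringTable) -> np.ndarray:
    """Per-record totals; missing indicators contribute 0 points."""
    return np.array(
        [
            sum(e.score for item, e in scoring.entries.items() if rec.indicators.get(item) == 1)
            for rec in cohort
        ],
        dtype=float,
    )


def derive_cutoff(cohort: Cohort, scoring: ScoringTable, outcome: str = "admin_cooperation") -> CutoffResult:
    """STEP-1 cutoff: ROC over per-record totals, Youden-optimal threshold."""
    totals = total_scores(cohort, scoring)
    ys = cohort.outcome_values(outcome)
    mask = np.array([y is not None for y in ys])
    labels = np.array([int(y) for y in ys if y is not None])
    curve = roc_curve(totals[mask], labels)
    return select_cutoff(curve)


def step2_items_by_prevalence(
    cohort: Cohort,
    outcome: str,
    candidate_items: Sequence[str],
    threshold: float = 0.30,
    inclusive: bool = True,
) -> list[str]:
    """Items present in >= ``threshold`` of outcome-positive records.

    Candidates may include items that were excluded from scoring.  A
    missing indicator counts as non-risk; the denominator is all
    outcome-positive records.
    """
    positives = [r for r, y in zip(cohort, cohort.outcome_values(outcome)) if y == 1]
    if not positives:
        raise DegenerateInputError("no outcome-positive records; STEP-2 prevalence undefined")
    selected = []
    for item in candidate_items:
        frac = sum(1 for r in positives if r.indicators.get(item) == 1) / len(positives)
        if (frac >= threshold) if inclusive else (frac > threshold):
            selected.append(item)
    return selected


def step2_items_by_weighted_spearman(
    cohort: Cohort,
    outcome: str,
    items: Sequence[str],
    weight: float = 10.0,
    min_points: float = 2.0,
) -> list[str]:
    """Items whose rank correlation with the outcome, on the given subset,
    clears ``min_points`` after weighting (rho x weight >= min_points).

    Intended for the STEP-1-positive subset.  Zero-variance items on the
    subset are skipped with a warning.
    """
    ys = cohort.outcome_values(outcome)
    selected = []
    for item in items:
        pairs = [(r.indicators.get(item), y) for r, y in zip(cohort, ys)
                 if y is not None and r.indicators.get(item) is not None]
        if len(pairs) < 3:
            warnings.warn(f"STEP-2: too few complete pairs for {item}; skipped", stacklevel=2)
            continue
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        try:
            rho = spearman_rho(x, y)
        except DegenerateInputError:
            warnings.warn(f"STEP-2: zero variance for {item} on the subset; skipped", stacklevel=2)
            continue
        if rho * weight >= min_points:
            selected.append(item)
    return selected


def assemble_tool(
    scoring: ScoringTable,
    threshold: float,
    step2: StepRule,
    step3: StepRule,
    semantics: str = "sequential_narrowing",
    mandatory_referral_items: Sequence[str] = (),
    provenance: str = "derived",
    schema: Optional[PeriodSchema] = None,
) -> ScreeningToolDefinition:
    """Freeze validated components into a serializable tool definition."""
    tool = ScreeningToolDefinition(
        period=scoring.period,
        scoring=scoring,
        step1_threshold=threshold,
        step2=step2,
        step3=step3,
        step_semantics=semantics,
        mandatory_referral_items=tuple(mandatory_referral_items),
        provenance=provenance,
    )
    tool.validate(schema)
    return tool


def accept_or_reject_tool(metrics: CutoffResult, min_auc: float = 0.70) -> tuple[bool, Optional[str]]:
    """Accept iff the STEP-1 AUC reaches ``min_auc`` (inclusive boundary)."""
    if metrics.auc >= min_auc:
        return True, None
    return False, f"AUC {metrics.auc:.2f} < {min_auc:.2f}: inappropriate for screening"


# ---------------------------------------------------------------------------
# orchestrated pipeline


def _analyzable_items(cohort: Cohort, outcome: str, items: Sequence[str]) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop items a regression cannot use: zero variance or no complete cases."""
    keep, dropped = [], []
    ys = cohort.outcome_values(outcome)
    for item in items:
        vals = [r.indicators.get(item) for r, y in zip(cohort, ys) if y is not None]
        observed = [v for v in vals if v is not None]
        if len(observed) < 2 or len(set(observed)) < 2:
            dropped.append((item, "degenerate: constant or unobserved indicator"))
        else:
            keep.append(item)
    return keep, dropped


def derive_tool(
    cohort: Cohort,
    config: DerivationConfig,
    schema: Optional[PeriodSchema] = None,
) -> tuple[Optional[ScreeningToolDefinition], DerivationReport]:
    """Run the full derivation; returns ``(tool, report)``, tool ``None`` on rejection."""
    schema = schema or load_period_schema(config.period)
    all_items = [i for i in schema.item_ids if i != "epds"]

    excluded_other: list[tuple[str, str]] = []
    items, dropped = _analyzable_items(cohort, config.outcome, all_items)
    excluded_other.extend(dropped)

    model1 = fit_crude(cohort, config.outcome, items)
    for t in model1.terms:
        if t.separation and t.item_id not in config.mandatory_referral_items:
            excluded_other.append((t.item_id, "separation in the crude fit"))
    separated = {i for i, reason in excluded_other if "separation" in reason}

    for item in config.mandatory_referral_items:
        if item in items:
            excluded_other.append((item, "mandatory referral: excluded from scoring"))
    mandatory = set(config.mandatory_referral_items)

    joint_items = [i for i in items if i not in separated and i not in mandatory]
    joint = fit_logistic_ml(cohort, config.outcome, joint_items)
    reversed_items = exclude_sign_reversals(model1, joint)

    # Single Model-2 refit after all exclusions; if standardization still
    # leaves a negative SPRC (a reversal only visible in the reduced
    # model), exclude it and refit until the score table is non-negative.
    retained = [i for i in joint_items if i not in reversed_items]
    while True:
        if not retained:
            raise DegenerateInputError("no items retained for Model-2")
        model2_lin = fit_linear_standardized(cohort, config.outcome, retained)
        negative = [t.item_id for t in model2_lin.terms if t.standardized_coefficient < 0]
        if not negative:
            break
        reversed_items.extend(negative)
        retained = [i for i in retained if i not in negative]
    model2_log = fit_logistic_ml(cohort, config.outcome, retained)
    for t_lin in model2_lin.terms:  # merge OR columns into the linear fit's terms
        t_log = model2_log.term(t_lin.item_id)
        t_lin.odds_ratio, t_lin.ci_low, t_lin.ci_high = t_log.odds_ratio, t_log.ci_low, t_log.ci_high
        t_lin.separation = t_log.separation

    scoring = score_items(model2_lin, config.rounding_mode, period=config.period)
    metrics = derive_cutoff(cohort, scoring, config.outcome)
    accepted, reason = accept_or_reject_tool(metrics, config.min_auc)

    step2_items: tuple[str, ...] = ()
    step3_items = tuple(config.step3_items)
    tool = None
    if accepted:
        if config.step2_strategy == "prevalence":
            step2_items = tuple(
                step2_items_by_prevalence(
                    cohort, config.outcome, all_items,
                    threshold=config.step2_prevalence_threshold,
                    inclusive=config.step2_inclusive,
                )
            )
        elif config.step2_strategy == "weighted_spearman":
            totals = total_scores(cohort, scoring)
            subset = Cohort(
                records=[r for r, t in zip(cohort.records, totals) if t >= metrics.threshold],
                period=cohort.period,
                provenance=cohort.provenance + " | step1-positives",
            )
            step2_items = tuple(
                step2_items_by_weighted_spearman(
                    subset, config.outcome, all_items,
                    weight=config.step2_weight, min_points=config.step2_min_points,
                )
            )
        else:
            raise ParameterError(f"unknown step2 strategy {config.step2_strategy!r}")
        if not step2_items:
            accepted, reason = False, "no STEP-2 items selected"
    if accepted:
        tool = assemble_tool(
            scoring,
            metrics.threshold,
            StepRule(items=step2_items, min_count=1),
            StepRule(items=step3_items, min_count=config.step3_min_count),
            semantics=config.step_semantics,
            mandatory_referral_items=config.mandatory_referral_items,
            provenance=f"derived from {cohort.provenance or 'cohort'}",
            schema=schema,
        )

    report = DerivationReport(
        period=config.period,
        excluded_sign_reversal=sorted(set(reversed_items)),
        excluded_other=excluded_other,
        model1=model1,
        model2=model2_lin,
        roc=metrics,
        step2_items=step2_items,
        step3_items=step3_items,
        accepted=accepted,
        rejection_reason=reason,
    )
    return tool, report
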