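"""Published reference artifacts and engineered check cohorts.

The original derivation cohorts are not deposited, so this module ships
two kinds of stand-ins:

* The *reference tools* and *reference fits* — the published score
  tables, thresholds, STEP rules and regression coefficients,
  transcribed into packaged JSON.  These are real published numbers,
  usable for screening new records.

* *Synthetic funnel cohorts* — cohorts engineered record-by-record so
  that screening them with the reference tools reproduces the published
  stage counts exactly (first visit: 558 screened -> 54 -> 20 -> 14
  positives with 6 and 5 needing administrative cooperation at the last
  two stages; second trimester: 483 -> 110 -> 21 -> 12 with 34 and 12).
  They carry no information beyond those marginal counts and are for
  verifying funnel arithmetic, not for refitting models.
"""

from __future__ import annotations

import json
from importlib import resources

from .errors import SchemaError
from .schema import Cohort, Period, Record, load_period_schema
from .stats import FitResult, TermFit
from . import io as _io


def _data_json(name: str) -> dict:
    return json.loads(resources.files("obscreen.data").joinpath(name).read_text("utf-8"))


def reference_tool(period: Period | str):
    """The published screening tool for a period (first visit or second trimester)."""
    period = Period.coerce(period)
    name = {
        Period.FIRST_VISIT: "tool_first_visit.json",
        Period.SECOND_TRIMESTER: "tool_second_trimester.json",
    }.get(period)
    if name is None:
        raise SchemaError(f"no reference tool exists for period {period.value} "
                          "(the third-trimester derivation was rejected; postpartum has no tool)")
    return _io.tool_from_dict(_data_json(name))


def reference_fit(period: Period | str, model: str = "model2") -> FitResult:
    """Published regression coefficients as a :class:`FitResult` fixture.

    ``model`` is ``"model1"`` (crude univariate) or ``"model2"``
    (adjusted; carries the SPRCs the scoring rule consumes).
    """
    period = Period.coerce(period)
    block = _data_json("reference_fits.json")[period.value]
    if model not in block:
        raise SchemaError(f"no {model} fixture for {period.value}")
    terms = []
    for item, row in block[model]["terms"].items():
        ci = row.get("ci", [None, None])
        terms.append(
            TermFit(
                item_id=item,
                standardized_coefficient=row.get("sprc"),
                odds_ratio=row.get("or"),
                ci_low=ci[0],
                ci_high=ci[1],
                p_value=row.get("p", float("nan")),
                vif=row.get("vif"),
                separation=bool(row.get("separation", False)),
            )
        )
    kind = "linear_standardized" if model == "model2" else "logistic_ml"
    return FitResult(terms=terms, model_kind=kind, n_used=block[model]["n"])


def reference_roc(period: Period | str) -> dict:
    """Published STEP-1 cutoff metrics {threshold, auc, sensitivity, specificity}."""
    period = Period.coerce(period)
    return dict(_data_json("reference_fits.json")[period.value]["roc"])


def epds_effect_table(period: Period | str) -> dict:
    """Published crude/adjusted odds-ratio table for the EPDS >= 9 outcome."""
    period = Period.coerce(period)
    return _data_json("epds_effects.json")[period.value]


def support_status_counts(period: Period | str) -> dict:
    """Published response and support-status counts per period (descriptive only)."""
    period = Period.coerce(period)
    return _data_json("support_status_counts.json")[period.value]


# ---------------------------------------------------------------------------
# engineered funnel cohorts (synthetic)


def _records(period: Period, n: int, start: int, pattern: dict[str, int], admin: int) -> list[Record]:
    schema = load_period_schema(period)
    out = []
    for k in range(n):
        indicators = {i: 0 for i in schema.item_ids}
        if "epds" in indicators:
            indicators["epds"] = None
        indicators.update(pattern)
        out.append(
            Record(
                record_id=f"f{start + k:04d}",
                period=period,
                indicators=indicators,
                admin_cooperation=admin,
                hospital_support=0,
            )
        )
    return out


def reference_funnel_cohort(period: Period | str) -> Cohort:
    """Synthetic cohort reproducing the published screening funnel.

    Records are built from four archetypes (screen-negative, fails
    STEP-2, fails STEP-3, fully positive) in the published proportions,
    with administrative-cooperation labels matching the published
    stage overlaps.  Only the funnel margins are faithful; item
    patterns within each archetype are arbitrary.
    """
    period = Period.coerce(period)
    if period == Period.FIRST_VISIT:
        groups = [
            # (n, pattern, admin): scores use the published point table
            (496, {}, 0),                                            # 0 points
            (8, {}, 1),                                              # screen-negative but needing support
            (34, {"maternal_age_lt25": 1, "economic_status": 1}, 0),  # 28.8 pts, no STEP-2 item
            (5, {"maternal_age_lt25": 1, "worries_older_child": 1}, 0),   # 24.0 pts, STEP-2 only
            (1, {"maternal_age_lt25": 1, "worries_older_child": 1}, 1),
            (9, {"maternal_age_lt25": 1, "maternal_mental_disorder": 1, "depression_symptoms": 1}, 0),
            (5, {"maternal_age_lt25": 1, "maternal_mental_disorder": 1, "depression_symptoms": 1}, 1),
        ]
    elif period == Period.SECOND_TRIMESTER:
        groups = [
            (366, {}, 0),
            (7, {}, 1),
            (67, {"maternity_life": 1}, 0),          # 17 pts, no STEP-2 item
            (22, {"maternity_life": 1}, 1),
            (9, {"smoking": 1}, 0),                  # 17 pts, STEP-2 via smoking, no STEP-3 item
            (12, {"smoking": 1, "depression_symptoms": 1}, 1),  # 23 pts, fully positive
        ]
    else:
        raise SchemaError(f"no published funnel exists for period {period.value}")
    records: list[Record] = []
    for n, pattern, admin in groups:
        records.extend(_records(period, n, len(records), pattern, admin))
    return Cohort(records=records, period=period, provenance="synthetic: engineered to the published funnel margins")


def reference_epds_prevalence_cohort() -> Cohort:
    """Synthetic first-visit cohort with the published postpartum EPDS margin.

    415 records with an observed depression-scale total, 28 of them at
    or above the >= 9 cutoff — the published prevalence of suspected
    postpartum depression among first-visit responders.  Totals are
    arbitrary within each band.
    """
    period = Period.FIRST_VISIT
    schema = load_period_schema(period)
    records = []
    for k in range(415):
        records.append(
            Record(
                record_id=f"e{k:04d}",
                period=period,
                indicators={i: 0 for i in schema.item_ids},
                admin_cooperation=0,
                hospital_support=0,
                epds_total=12 if k < 28 else 3,
            )
        )
    return Cohort(records=records, period=period, provenance="synthetic: engineered EPDS >= 9 margin 28/415")
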