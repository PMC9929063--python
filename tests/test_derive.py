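"""Tool-derivation stages and the orchestrated pipeline."""

import numpy as np
import pytest

from obscreen import Cohort, Period, Record, load_period_schema
from obscreen.derive import (
    DerivationConfig,
    ScoringTable,
    ScoreEntry,
    StepRule,
    accept_or_reject_tool,
    assemble_tool,
    derive_cutoff,
    derive_tool,
    exclude_sign_reversals,
    score_items,
    step2_items_by_prevalence,
    step2_items_by_weighted_spearman,
    total_scores,
)
from obscreen.errors import DegenerateInputError, PipelineOrderError, ToolValidationError
from obscreen.io import tool_to_dict
from obscreen.reference import reference_fit, reference_tool
from obscreen.simulate import default_params, generate_cohort
from obscreen.stats import FitResult, TermFit


def _fit(kind, **ors):
    terms = [TermFit(item_id=k, odds_ratio=v, coefficient=np.log(v) if v > 0 else -10.0) for k, v in ors.items()]
    return FitResult(terms=terms, model_kind=kind, n_used=100)


# ---------------------------------------------------------------------------
# sign reversal


def test_sign_reversal_excluded_kept_and_boundary():
    m1 = _fit("logistic_ml", a=5.57, b=2.0, c=1.0)
    m2 = _fit("logistic_ml", a=0.35, b=1.5, c=0.7)
    excluded = exclude_sign_reversals(m1, m2)
    assert excluded == ["a"]  # crude 5.57 vs adjusted 0.35: direction flipped
    # b keeps direction; c has crude OR exactly 1 -> no direction to reverse


# ---------------------------------------------------------------------------
# scoring


def test_score_items_published_rounding_examples():
    m2 = FitResult(
        terms=[
            TermFit(item_id="age", standardized_coefficient=0.212),
            TermFit(item_id="smoke", standardized_coefficient=0.165),
            TermFit(item_id="zero", standardized_coefficient=0.0),
        ],
        model_kind="linear_standardized",
        n_used=500,
    )
    one_dec = score_items(m2, "times100_one_decimal")
    assert one_dec.entries["age"].score == 21.2
    integer = score_items(m2, "times100_nearest_integer")
    assert integer.entries["smoke"].score == 17  # 16.5 rounds half-up, not banker's
    assert integer.entries["zero"].score == 0


def test_score_items_rejects_negative_sprc():
    m2 = FitResult(
        terms=[TermFit(item_id="bad", standardized_coefficient=-0.05)],
        model_kind="linear_standardized",
        n_used=100,
    )
    with pytest.raises(PipelineOrderError):
        score_items(m2, "times100_one_decimal")


# ---------------------------------------------------------------------------
# cutoff


def _cohort(period, rows):
    """rows: list of (indicator dict, admin outcome)."""
    schema = load_period_schema(period)
    records = []
    for i, (pattern, admin) in enumerate(rows):
        ind = {k: 0 for k in schema.item_ids}
        if "epds" in ind:
            ind["epds"] = None
        ind.update(pattern)
        records.append(Record(f"r{i}", Period.coerce(period), ind, admin_cooperation=admin, hospital_support=0))
    return Cohort(records=records, period=Period.coerce(period))


def test_derive_cutoff_on_a_separable_cohort():
    scoring = ScoringTable(
        period=Period.FIRST_VISIT,
        entries={"maternal_mental_disorder": ScoreEntry(0.3, 30.0), "economic_status": ScoreEntry(0.1, 10.0)},
        rounding_mode="times100_one_decimal",
    )
    rows = [({"maternal_mental_disorder": 1}, 1)] * 5 + [({"economic_status": 1}, 0)] * 20 + [({}, 0)] * 20
    result = derive_cutoff(_cohort("first_visit", rows), scoring)
    assert result.auc == 1.0
    assert 10 < result.threshold <= 30
    assert 0 < result.threshold <= scoring.max_score


def test_derive_cutoff_missing_scores_zero():
    scoring = ScoringTable(
        period=Period.FIRST_VISIT,
        entries={"economic_status": ScoreEntry(0.1, 10.0)},
        rounding_mode="times100_one_decimal",
    )
    cohort = _cohort("first_visit", [({"economic_status": None}, 0), ({"economic_status": 1}, 1)])
    assert list(total_scores(cohort, scoring)) == [0.0, 10.0]


def test_shuffled_outcome_gives_chance_auc():
    rng = np.random.default_rng(0)
    scoring = ScoringTable(
        period=Period.FIRST_VISIT,
        entries={"economic_status": ScoreEntry(0.1, 10.0), "worries_older_child": ScoreEntry(0.05, 5.0)},
        rounding_mode="times100_one_decimal",
    )
    aucs = []
    for _ in range(20):
        rows = [
            ({"economic_status": int(rng.random() < 0.3), "worries_older_child": int(rng.random() < 0.3)},
             int(rng.random() < 0.2))
            for _ in range(400)
        ]
        aucs.append(derive_cutoff(_cohort("first_visit", rows), scoring).auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# STEP-2 rules


def test_step2_prevalence_thresholds_inclusive_boundary():
    rows = [({"economic_status": 1, "worries_older_child": 1}, 1)] * 3
    rows += [({"worries_older_child": 1}, 1)] * 1
    rows += [({}, 1)] * 6
    rows += [({}, 0)] * 40
    cohort = _cohort("first_visit", rows)
    selected = step2_items_by_prevalence(cohort, "admin_cooperation", ["economic_status", "worries_older_child"])
    # 3/10 = 30% exactly: inclusive boundary keeps it; 4/10 = 40% clearly in
    assert selected == ["economic_status", "worries_older_child"]
    strict = step2_items_by_prevalence(
        cohort, "admin_cooperation", ["economic_status", "worries_older_child"], inclusive=False
    )
    assert strict == ["worries_older_child"]
    lonely = step2_items_by_prevalence(cohort, "admin_cooperation", ["maternal_feelings"])
    assert lonely == []  # 0/10
    with pytest.raises(DegenerateInputError):
        step2_items_by_prevalence(_cohort("first_visit", [({}, 0)]), "admin_cooperation", ["economic_status"])


def test_step2_weighted_spearman_selects_engineered_items():
    """Engineer a subset where exactly items A and B reach rho*10 >= 2."""
    from obscreen.stats import spearman_rho

    rng = np.random.default_rng(7)
    n = 200
    y = rng.integers(0, 2, n)
    a = np.where(rng.random(n) < 0.75, y, rng.integers(0, 2, n))       # strongly aligned
    b = np.where(rng.random(n) < 0.55, y, rng.integers(0, 2, n))       # moderately aligned
    c = rng.integers(0, 2, n)                                          # independent
    rows = [
        ({"maternal_feelings": int(a[i]), "depression_symptoms": int(b[i]), "economic_status": int(c[i])},
         int(y[i]))
        for i in range(n)
    ]
    cohort = _cohort("first_visit", rows)
    # oracle check of the engineered correlations
    assert spearman_rho(a, y) * 10 >= 2 and spearman_rho(b, y) * 10 >= 2
    assert spearman_rho(c, y) * 10 < 2
    selected = step2_items_by_weighted_spearman(
        cohort, "admin_cooperation", ["maternal_feelings", "depression_symptoms", "economic_status"]
    )
    assert selected == ["maternal_feelings", "depression_symptoms"]


def test_step2_weighted_spearman_skips_zero_variance_items():
    rows = [({"maternal_feelings": 1, "economic_status": 1}, 1), ({"maternal_feelings": 1}, 0),
            ({"maternal_feelings": 1, "economic_status": 1}, 1), ({"maternal_feelings": 1}, 0)]
    cohort = _cohort("first_visit", rows)
    with pytest.warns(UserWarning, match="zero variance"):
        selected = step2_items_by_weighted_spearman(
            cohort, "admin_cooperation", ["maternal_feelings", "economic_status"]
        )
    assert selected == ["economic_status"]


# ---------------------------------------------------------------------------
# assembly and acceptance


def test_assemble_tool_reference_thresholds():
    fv = reference_tool("first_visit")
    assert fv.step1_threshold == 22
    st = reference_tool("second_trimester")
    assert st.step1_threshold == 14
    # reassembling from components keeps the threshold
    rebuilt = assemble_tool(
        fv.scoring, fv.step1_threshold, fv.step2, fv.step3,
        mandatory_referral_items=fv.mandatory_referral_items,
        schema=load_period_schema("first_visit"),
    )
    assert rebuilt.step1_threshold == 22


def test_assemble_tool_rejects_invalid_steps():
    fv = reference_tool("first_visit")
    with pytest.raises(ToolValidationError):
        assemble_tool(fv.scoring, 22, fv.step2, StepRule(items=fv.step3.items, min_count=0))
    with pytest.raises(ToolValidationError):
        assemble_tool(fv.scoring, 22, StepRule(items=()), fv.step3)
    with pytest.raises(ToolValidationError):
        assemble_tool(fv.scoring, 22, StepRule(items=("no_such_item",)), fv.step3,
                      schema=load_period_schema("first_visit"))


def test_accept_or_reject_published_aucs_and_boundary():
    from obscreen.stats import CutoffResult

    ok, reason = accept_or_reject_tool(CutoffResult(14, 0.82, 0.62, 0.77))
    assert ok and reason is None
    bad, reason = accept_or_reject_tool(CutoffResult(7, 0.43, 0.57, 0.46))
    assert not bad and "0.46" in reason
    boundary, _ = accept_or_reject_tool(CutoffResult(10, 0.7, 0.7, 0.70))
    assert boundary  # inclusive


# ---------------------------------------------------------------------------
# orchestrated pipeline


FV_CONFIG = DerivationConfig(
    period=Period.FIRST_VISIT,
    rounding_mode="times100_one_decimal",
    step2_strategy="prevalence",
    step3_items=("depression_symptoms", "maternal_mental_disorder", "consultation_request"),
    step3_min_count=2,
    mandatory_referral_items=("drug_use_mother", "drug_use_partner"),
)


def test_derive_tool_end_to_end_on_synthetic_cohort():
    cohort = generate_cohort(default_params("first_visit", n=4000, seed=7))
    tool, report = derive_tool(cohort, FV_CONFIG)
    assert report.accepted and tool is not None
    assert report.roc.auc >= 0.70
    # mandatory items never scored; scores non-negative; cutoff within range
    assert not set(tool.mandatory_referral_items) & set(tool.scoring.entries)
    assert all(e.score >= 0 for e in tool.scoring.entries.values())
    assert 0 < tool.step1_threshold <= tool.scoring.max_score
    assert tool.step2.items  # STEP-2 selected something


def test_derive_tool_deterministic():
    cohort = generate_cohort(default_params("first_visit", n=2000, seed=11))
    t1, _ = derive_tool(cohort, FV_CONFIG)
    t2, _ = derive_tool(cohort, FV_CONFIG)
    assert tool_to_dict(t1) == tool_to_dict(t2)


def test_derive_tool_rejects_uninformative_cohort():
    """Outcome independent of every item: the ROC gate must reject."""
    rng = np.random.default_rng(13)
    p = default_params("third_trimester", n=3000, seed=13)
    p.item_effects = {k: 1.0 for k in p.item_effects}
    cohort = generate_cohort(p)
    config = DerivationConfig(period=Period.THIRD_TRIMESTER, step3_items=("depression_symptoms",))
    tool, report = derive_tool(cohort, config)
    assert tool is None
    assert not report.accepted
    assert report.rejection_reason is not None


def test_derive_tool_excludes_engineered_sign_reversal():
    """An item protective after adjustment but harmful crude is excluded
    and never reaches the score table."""
    rng = np.random.default_rng(19)
    n = 8000
    y = (rng.random(n) < 0.2).astype(int)
    driver = np.where(rng.random(n) < 0.7, y, rng.integers(0, 2, n))
    # confounded: tracks the driver strongly, but protective given it
    confounded = np.where(
        driver == 1, (rng.random(n) < 0.6).astype(int), (rng.random(n) < 0.05).astype(int)
    )
    confounded = np.where((driver == 1) & (y == 1) & (rng.random(n) < 0.45), 0, confounded)
    rows = [
        ({"maternal_feelings": int(driver[i]), "partner_feelings": int(confounded[i])}, int(y[i]))
        for i in range(n)
    ]
    cohort = _cohort("first_visit", rows)
    config = DerivationConfig(
        period=Period.FIRST_VISIT,
        step3_items=("depression_symptoms", "maternal_mental_disorder", "consultation_request"),
        step3_min_count=1,
    )
    tool, report = derive_tool(cohort, config)
    assert "partner_feelings" in report.excluded_sign_reversal
    assert "partner_feelings" not in {t.item_id for t in report.model2.terms}
    if tool is not None:
        assert "partner_feelings" not in tool.scoring.entries
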