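"""Synthetic questionnaire cohorts.

No per-case data from the original derivation cohorts are available, so
everything downstream is exercised on simulated cohorts with the
statistical structure the analysis assumes: a latent binary outcome
(need for public-health-center cooperation) drawn at the published
prevalence, and binary risk indicators that are conditionally
independent given the outcome, with stratum probabilities linked by a
per-item odds ratio on the logit scale:

    odds(p1) = OR * odds(p0)

where ``p0`` is the indicator prevalence in the outcome-negative
stratum.  The packaged defaults use the published crude odds ratios as
generating effects; the (unpublished) baseline prevalences are a frozen,
approximate calibration chosen so the reference screening tools flag a
realistic share of records at STEP-1.

Postpartum depression-scale totals are generated from a logistic model
in the record's indicators whose intercept is calibrated by bisection so
the marginal P(total >= 9) matches the requested prevalence; the integer
total is then drawn uniformly within the band (>= 9 or < 9).

All randomness flows from the single ``seed`` in the parameter object.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from scipy.special import expit

from .errors import ParameterError
from .schema import Cohort, Period, PeriodSchema, Record, load_period_schema


@dataclass
class EpdsModelParams:
    """Logistic model for the binarized postpartum depression outcome."""

    prevalence_ge9: float = 0.067
    effect_ors: dict[str, float] = field(default_factory=dict)
    threshold: int = 9


@dataclass
class SimulationParams:
    n: int
    period: Period
    outcome_prevalence: float
    item_effects: dict[str, float]
    baseline_item_prevalence: dict[str, float]
    missing_rate: float = 0.0
    hospital_support_prevalence: float = 0.0
    epds_model: EpdsModelParams = field(default_factory=EpdsModelParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        probs = [self.outcome_prevalence, self.missing_rate, self.hospital_support_prevalence,
                 self.epds_model.prevalence_ge9, *self.baseline_item_prevalence.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ParameterError("all probabilities must lie in [0, 1]")
        if any(o <= 0.0 for o in self.item_effects.values()):
            raise ParameterError("all odds ratios must be > 0")
        if any(o <= 0.0 for o in self.epds_model.effect_ors.values()):
            raise ParameterError("all odds ratios must be > 0")


def default_params(period: Period | str, n: int = 1000, seed: int = 0) -> SimulationParams:
    """Packaged per-period defaults (published prevalences and crude ORs)."""
    period = Period.coerce(period)
    raw = json.loads(
        resources.files("obscreen.data").joinpath("simulation_defaults.json").read_text("utf-8")
    )[period.value]
    return SimulationParams(
        n=n,
        period=period,
        outcome_prevalence=raw["outcome_prevalence"],
        item_effects={k: v["or"] for k, v in raw["items"].items()},
        baseline_item_prevalence={k: v["baseline"] for k, v in raw["items"].items()},
        hospital_support_prevalence=raw["hospital_support_prevalence"],
        epds_model=EpdsModelParams(
            prevalence_ge9=raw["epds"]["prevalence_ge9"],
            effect_ors=dict(raw["epds"]["effect_ors"]),
        ),
        seed=seed,
    )


def _risk_probability(p0: float, odds_ratio: float) -> float:
    """p1 with odds(p1) = OR * odds(p0); the logit link keeps p1 < 1."""
    if p0 <= 0.0:
        return 0.0
    if p0 >= 1.0:
        return 1.0
    odds = odds_ratio * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def generate_cohort(params: SimulationParams, schema: Optional[PeriodSchema] = None) -> Cohort:
    """Draw a cohort; deterministic given ``params.seed``.

    The postpartum depression-scale item (when the period schema carries
    one) is left missing here; :func:`generate_epds` fills it together
    with the integer total.
    """
    params.validate()
    schema = schema or load_period_schema(params.period)
    sim_items = [i for i in schema.item_ids if i != "epds"]
    rng = np.random.default_rng(params.seed)

    outcome = rng.random(params.n) < params.outcome_prevalence
    hospital = (~outcome) & (rng.random(params.n) < params.hospital_support_prevalence)

    columns: dict[str, np.ndarray] = {}
    for item in sim_items:
        p0 = params.baseline_item_prevalence.get(item, 0.0)
        p1 = _risk_probability(p0, params.item_effects.get(item, 1.0))
        p = np.where(outcome, p1, p0)
        columns[item] = (rng.random(params.n) < p).astype(int)

    records = []
    for idx in range(params.n):
        indicators = {item: int(columns[item][idx]) for item in sim_items}
        if "epds" in schema.item_ids:
            indicators["epds"] = None
        records.append(
            Record(
                record_id=f"s{idx:06d}",
                period=params.period,
                indicators=indicators,
                admin_cooperation=int(outcome[idx]),
                hospital_support=int(hospital[idx]),
            )
        )
    provenance = f"synthetic seed={params.seed} n={params.n} period={params.period.value}"
    cohort = Cohort(records=records, period=params.period, provenance=provenance)
    if params.missing_rate > 0.0:
        cohort = inject_missingness(cohort, params.missing_rate, seed=params.seed + 1)
    return cohort


def _calibrate_intercept(eta: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisect the intercept so mean(expit(b0 + eta)) hits the target prevalence."""
    lo, hi = -40.0, 40.0
    f = lambda b0: float(np.mean(expit(b0 + eta))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ParameterError("EPDS prevalence calibration unsatisfiable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * 1e-2:
            break
    return 0.5 * (lo + hi)


def generate_epds(cohort: Cohort, params: SimulationParams) -> Cohort:
    """Fill postpartum depression-scale totals on a copy of the cohort.

    P(total >= threshold) follows a logistic model in the record's risk
    indicators (missing indicators contribute nothing); the intercept is
    calibrated so the marginal prevalence matches
    ``params.epds_model.prevalence_ge9`` to within ~0.002 in
    expectation.  Totals are drawn uniformly within the implied band.
    """
    if len(cohort) == 0:
        raise ParameterError("cannot generate EPDS totals for an empty cohort")
    em = params.epds_model
    if not (0.0 <= em.prevalence_ge9 <= 1.0):
        raise ParameterError("prevalence_ge9 must lie in [0, 1]")
    rng = np.random.default_rng(params.seed + 2)
    thr = em.threshold

    if em.prevalence_ge9 in (0.0, 1.0):
        positive = np.full(len(cohort), em.prevalence_ge9 == 1.0)
    else:
        betas = {item: np.log(o) for item, o in em.effect_ors.items()}
        eta = np.array(
            [
                sum(b for item, b in betas.items() if rec.indicators.get(item) == 1)
                for rec in cohort
            ],
            dtype=float,
        )
        b0 = _calibrate_intercept(eta, em.prevalence_ge9)
        positive = rng.random(len(cohort)) < expit(b0 + eta)

    out = copy.deepcopy(cohort)
    for rec, pos in zip(out, positive):
        total = int(rng.integers(thr, 31)) if pos else int(rng.integers(0, thr))
        rec.epds_total = total
        if "epds" in rec.indicators:
            rec.indicators["epds"] = int(total >= thr)
    out.provenance = cohort.provenance + " +epds"
    return out


def inject_missingness(cohort: Cohort, missing_rate: float, seed: int = 0) -> Cohort:
    """Mask each indicator independently (MCAR); outcomes are never masked."""
    if not (0.0 <= missing_rate < 1.0):
        raise ParameterError("missing_rate must lie in [0, 1)")
    out = copy.deepcopy(cohort)
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    for rec in out:
        for item in rec.indicators:
            if rec.indicators[item] is not None and rng.random() < missing_rate:
                rec.indicators[item] = None
    out.provenance = cohort.provenance + f" +missing({missing_rate})"
    return out
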