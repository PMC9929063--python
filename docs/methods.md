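# Methods

## Setting and data model

The package models antenatal social-risk screening at obstetric
institutions in Japan. At four contact periods (first visit, ~28 weeks,
~36 weeks, one month postpartum) a short interview sheet is
administered; every item has a non-risk ("positive") and a risk
("negative") answer set, and a record stores the binary risk indicator
per item (1 = risk, 0 = non-risk, missing = unanswered). Two outcome
labels accompany each record: *administrative cooperation* (the case was
judged to need coordinated support from a public health center — the
derivation outcome) and *hospital support* (socially high-risk but
supported within the institution). Postpartum records may carry an
Edinburgh Postnatal Depression Scale (EPDS) total (0–30); the package
treats the total as an input and never scores the 10 EPDS items.

Answer matching is case-insensitive after whitespace normalization,
because the source item tables capitalize inconsistently. Missingness is
a first-class third state: nothing is imputed at the schema layer, and
each downstream consumer declares its handling (listwise deletion in the
regressions, zero points in the screen).

One transcription judgement: the printed item table places "<25" in the
maternal-age non-risk column, but every fitted model treats age < 25 as
the risk side (teenage/young pregnancy), so the packaged schema codes
"<25" as the risk answer.

## Derivation pipeline

Given a cohort and a period configuration:

1. **Crude and adjusted fits.** Each item gets a univariate
   maximum-likelihood logistic fit (crude OR); all analyzable items
   enter one joint logistic fit. Items with an empty cell in their 2×2
   table against the outcome are flagged as complete separation and
   reported as diverging rather than crashing the fit; such items are
   excluded from the joint model. Items that are constant or entirely
   unobserved are likewise excluded with a recorded reason.
2. **Sign-reversal exclusion.** An item whose crude OR is above 1 while
   its adjusted OR is below 1 (or vice versa) is dropped: its marginal
   association is an artifact of confounding and a points score built
   on it would be misleading. An OR of exactly 1 has no direction and
   never triggers exclusion.
3. **Mandatory-referral exclusion.** Items configured as mandatory
   referrals (illegal drug use by the mother or partner at the first
   visit) are excluded from scoring because any risk answer must lead
   to referral regardless of points; the frozen tool carries them as a
   short-circuit list.
4. **Model-2 and scoring.** The retained items enter one standardized
   linear regression (ordinary least squares of the 0/1 outcome on the
   0/1 indicators after scaling predictors and outcome to unit
   variance). The coefficient of this fit — the standardized partial
   regression coefficient, SPRC — times 100 is the item's points.
   Scores are read from this single joint fit; exclusions never trigger
   per-item refits of other items' scores. If the reduced fit itself
   produces a negative SPRC (a reversal visible only in the reduced
   model), that item is excluded and the model refit; the final table
   is always non-negative.
5. **Rounding.** The published first-visit table keeps one decimal
   (0.212 → 21.2) while the second-trimester table prints whole points
   with ties rounded up (0.165 → 17), so the rounding mode is a
   per-period configuration and both modes round half-up. Half-up is
   also used for report percentages.
6. **Cutoff.** Per-record totals (missing items contribute 0) feed an
   ROC sweep with thresholds at the distinct observed scores; AUC is
   the Mann–Whitney rank statistic with ties counting ½. The STEP-1
   cutoff maximizes Youden's J, with ties broken toward the lower
   threshold to favour sensitivity. Youden's index is adopted as the
   cutoff criterion (it is consistent with the published
   sensitivity/specificity pairs 0.92/0.92 and 0.82/0.62) and is a
   config enum so alternatives can be added.
7. **STEP-2.** Two strategies, matching how the two published tools
   were built. *Prevalence*: items present in at least 30% of
   outcome-positive records, candidates including items excluded from
   scoring; the boundary is inclusive (configurable), since an item at
   exactly 30% was admitted in the published derivation.
   *Weighted Spearman*: on the STEP-1-positive subset, items with
   ρ(indicator, outcome) × 10 ≥ 2; zero-variance items are skipped
   with a warning.
8. **STEP-3.** A minimum count over a configured item set. No selection
   criterion is published for these sets, so they are config inputs;
   the packaged defaults transcribe the published tools (first visit:
   ≥ 2 of {depression symptoms, maternal mental disorder, consultation
   request}; second trimester: ≥ 1 of {no talking with partner, partner
   violence, depression symptoms, consultation request}).
9. **Acceptance gate.** The tool is accepted iff the STEP-1 AUC is at
   least `min_auc` = 0.70 (inclusive). The published derivations accept
   at 0.77 and reject at 0.46 without naming a bound; 0.70 is the
   conventional "acceptable discrimination" floor consistent with both.

STEP semantics default to *sequential narrowing* (each STEP filters the
previous STEP's positives), the only reading compatible with the
published funnels (54 → 20 → 14 and 110 → 21 → 12); a *union* semantics
(positive on any step) is available behind a flag because the narrative
phrasing is ambiguous.

## Statistical conventions

* Logistic fits are maximum-likelihood (Newton, tolerance 1e-10, 100
  iterations, L-BFGS fallback), via statsmodels. Odds-ratio intervals
  are Wald: exp(β ± 1.96·SE) — the default of the commercial software
  used for the original analysis — not profile likelihood.
* Complete-case (listwise) handling in every regression, with the
  complete-case `n` reported; this matches the published per-model n's.
* VIF_j = 1/(1 − R²_j) from regressing indicator j on the others over
  the joint model's complete cases; perfect collinearity reports an
  `inf` sentinel, rank-deficient designs raise an error naming the
  aliased items.
* Spearman's ρ is Pearson on mid-ranks (ties averaged); zero-variance
  input is signalled, not silently NaN.
* The standardized linear fit standardizes both predictors and outcome;
  a switch (`standardize_outcome=False`) exposes the alternative
  reading, which only rescales all SPRCs by the outcome SD.

## EPDS ≥ 9 association analysis

The postpartum depression outcome is the EPDS total binarized at ≥ 9,
the validated community cutoff for suspected postpartum depression in
Japan. Per period, items with fewer than 5 risk-positive records among
EPDS-observed cases are excluded up front (`min_exposed = 5`, the
smallest bound consistent with the published exclusions, which removed
items with 1–4 exposed). Crude ORs come from univariate fits; adjusted
ORs from one joint fit over all kept items of the period, matching the
published table's period blocks.

## Synthetic cohorts

The generator emulates the study conditions: outcome prevalence 2.5%
(first visit), 6% (second/third trimester), 23% (postpartum); binary
indicators conditionally independent given the outcome, with
stratum-wise probabilities linked by a per-item odds ratio on the logit
scale (odds(p1) = OR × odds(p0)), the published crude ORs serving as
default effects. Conditional independence is justified by the published
VIFs, all near 1; an inter-item correlation structure is not published,
so none is imposed. Baseline (outcome-negative stratum) prevalences are
not published; the packaged defaults are a one-time approximate
calibration chosen so the reference tools' STEP-1 positive rates land
near the published ones (≈ 10% at the first visit, ≈ 23% in the second
trimester), and are labelled approximate in the data file. The
mutually exclusive hospital-support label is drawn at the published
high-risk rates among outcome-negative records.

EPDS totals follow a logistic model in the record's indicators (default
effects: the published adjusted ORs) whose intercept is calibrated by
bisection so the marginal P(total ≥ 9) matches the target (default
6.7%); the integer total is then uniform within the implied band.
Prevalence targets of exactly 0 or 1 are honoured degenerately (all
totals below/above the cutoff). Missingness is injected MCAR — only
missing counts, not mechanisms, are published — and never touches
outcome labels.

What the generator does **not** emulate: inter-item correlation,
longitudinal linkage of one woman across periods, informative
missingness, and site heterogeneity. Tests passing on these cohorts
therefore demonstrate the correctness of the pipeline's arithmetic and
its statistical calibration under the stated assumptions, not the
clinical performance of the tools on real populations.

## Reference fixtures

The published score tables, thresholds, STEP rules, regression
coefficient tables and ROC summaries ship as packaged JSON, transcribed
from the publication (provenance `reference_published`). CI cells that
are truncated in print are stored as nulls. Because no per-case data
exist, the published screening funnels are verified against *engineered
synthetic cohorts* (`obscreen.reference`): records built archetype by
archetype so that screening with the reference tools reproduces the
published stage counts and outcome overlaps exactly. These cohorts are
faithful only in their funnel margins and are unfit for model fitting.

## Problem sizes and numerical choices

Parameter-recovery checks run at n = 50,000–100,000 records (relative
tolerance 15%, reflecting Monte-Carlo error at that size); null-model
coverage uses 20 replicates of n = 5,000; screening invariants are
property-checked over ≥ 1,000 random records per period. The EPDS
intercept bisection runs on [−40, 40] to a width of 1e-6. Score sums are
rounded at 1e-10 to keep decimal point totals (e.g. 21.2 + 7.6) exact in
comparisons.

## Known limitations

* The real cohorts are unavailable, so published coefficients, AUCs and
  cutoffs are transcribed, not re-derived; the pipeline re-derives
  tools only from synthetic cohorts.
* The second-trimester STEP-2 Spearman pairing (item vs outcome, rather
  than item vs total score) follows the "risk group" reading of the
  published description; the alternative is not implemented.
* Postpartum simulation effects are round placeholder ORs (no
  derivation was published for that period's items).
* The third-trimester rejection path is reproduced structurally (AUC
  gate), not numerically (0.46 is a property of the unavailable data).
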