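"""Re-run the full tool-derivation pipeline on a synthetic cohort.

Steps: crude + adjusted fits, sign-reversal and mandatory-referral
exclusions, SPRC x 100 scoring, ROC/Youden STEP-1 cutoff, prevalence-
based STEP-2 selection, and the AUC acceptance gate.
"""

from obscreen import DerivationConfig, Period, default_params, derive_tool, generate_cohort

cohort = generate_cohort(default_params("first_visit", n=5000, seed=11))
config = DerivationConfig(
    period=Period.FIRST_VISIT,
    rounding_mode="times100_one_decimal",
    step3_items=("depression_symptoms", "maternal_mental_disorder", "consultation_request"),
    step3_min_count=2,
    mandatory_referral_items=("drug_use_mother", "drug_use_partner"),
)
tool, report = derive_tool(cohort, config)

print(f"accepted: {report.accepted} (AUC {report.roc.auc:.2f}, cutoff {report.roc.threshold} points)")
print(f"sign reversals excluded: {report.excluded_sign_reversal}")
print("item scores (SPRC x 100):")
for item, entry in tool.scoring.entries.items():
    print(f"  {item:26s} {entry.score:6.1f}")
print(f"STEP-2 items (>= 30% of outcome-positives): {list(tool.step2.items)}")
# The cutoff and scores differ from the published tool because the
# cohort is synthetic; the pipeline and acceptance gate are the same.
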