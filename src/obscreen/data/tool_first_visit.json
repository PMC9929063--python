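{
  "schema_version": 1,
  "period": "first_visit",
  "provenance": "reference_published",
  "rounding_mode": "times100_one_decimal",
  "scoring": {
    "maternal_feelings": {"sprc": 0.069, "score": 6.9},
    "depression_symptoms": {"sprc": 0.019, "score": 1.9},
    "family_social_support": {"sprc": 0.117, "score": 11.7},
    "economic_status": {"sprc": 0.076, "score": 7.6},
    "partner_status": {"sprc": 0.129, "score": 12.9},
    "maternal_mental_disorder": {"sprc": 0.16, "score": 16.0},
    "worries_older_child": {"sprc": 0.028, "score": 2.8},
    "multiple_pregnancy": {"sprc": 0.105, "score": 10.5},
    "children_ge3": {"sprc": 0.141, "score": 14.1},
    "maternal_age_lt25": {"sprc": 0.212, "score": 21.2}
  },
  "step1_threshold": 22,
  "step2": {
    "rule": "any_of",
    "items": ["family_social_support", "maternal_mental_disorder",
              "worries_older_child", "multiple_pregnancy"]
  },
  "step3": {
    "min_count": 2,
    "items": ["depression_symptoms", "maternal_mental_disorder", "consultation_request"]
  },
  "step_semantics": "sequential_narrowing",
  "mandatory_referral_items": ["drug_use_mother", "drug_use_partner"]
}
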