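{
  "schema_version": 1,
  "period": "second_trimester",
  "provenance": "reference_published",
  "rounding_mode": "times100_nearest_integer",
  "scoring": {
    "maternity_life": {"sprc": 0.167, "score": 17},
    "talking_with_partner": {"sprc": 0.108, "score": 11},
    "partner_violence": {"sprc": 0.15, "score": 15},
    "childhood_abuse": {"sprc": 0.135, "score": 14},
    "depression_symptoms": {"sprc": 0.058, "score": 6},
    "family_social_support": {"sprc": 0.072, "score": 7},
    "smoking": {"sprc": 0.165, "score": 17},
    "consultation_request": {"sprc": 0.053, "score": 5}
  },
  "step1_threshold": 14,
  "step2": {
    "rule": "any_of",
    "items": ["talking_with_partner", "partner_violence", "smoking"]
  },
  "step3": {
    "min_count": 1,
    "items": ["talking_with_partner", "partner_violence",
              "depression_symptoms", "consultation_request"]
  },
  "step_semantics": "sequential_narrowing",
  "mandatory_referral_items": []
}
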