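{
  "_note": "Calibrated, approximate defaults. Item odds ratios are the published crude (Model-1) associations where printed; baseline prevalences in the outcome-negative stratum are not published and were chosen once so that the reference-tool STEP-1 positive rates land near the published ones (about 10% at the first visit, about 23% in the second trimester). Items whose crude fit was degenerate in print carry OR 1 and a small baseline.",
  "first_visit": {
    "outcome_prevalence": 0.025,
    "hospital_support_prevalence": 0.17,
    "epds": {
      "prevalence_ge9": 0.067,
      "effect_ors": {
        "maternal_feelings": 6.51,
        "partner_feelings": 0.35,
        "depression_symptoms": 2.86,
        "economic_status": 1.46,
        "partner_status": 2.44,
        "maternal_mental_disorder": 4.38,
        "worries_older_child": 1.41,
        "consultation_request": 3.22,
        "multiple_pregnancy": 1.97,
        "children_ge3": 0.85,
        "maternal_age_lt25": 0.8
      }
    },
    "items": {
      "maternal_feelings": {
        "baseline": 0.09,
        "or": 10.985
      },
      "partner_feelings": {
        "baseline": 0.07,
        "or": 5.566
      },
      "depression_symptoms": {
        "baseline": 0.14,
        "or": 3.987
      },
      "family_social_support": {
        "baseline": 0.018,
        "or": 13.489
      },
      "economic_status": {
        "baseline": 0.07,
        "or": 10.235
      },
      "partner_status": {
        "baseline": 0.09,
        "or": 6.433
      },
      "maternal_mental_disorder": {
        "baseline": 0.07,
        "or": 13.593
      },
      "drug_use_mother": {
        "baseline": 0.004,
        "or": 1.0
      },
      "drug_use_partner": {
        "baseline": 0.003,
        "or": 1.0
      },
      "worries_older_child": {
        "baseline": 0.18,
        "or": 2.154
      },
      "consultation_request": {
        "baseline": 0.125,
        "or": 3.689
      },
      "multiple_pregnancy": {
        "baseline": 0.027,
        "or": 4.96
      },
      "children_ge3": {
        "baseline": 0.036,
        "or": 7.239
      },
      "maternal_age_lt25": {
        "baseline": 0.09,
        "or": 15.49
      }
    }
  },
  "second_trimester": {
    "outcome_prevalence": 0.06,
    "hospital_support_prevalence": 0.07,
    "epds": {
      "prevalence_ge9": 0.063,
      "effect_ors": {
        "maternity_life": 3.15,
        "talking_with_partner": 1.76,
        "partner_violence": 1.12,
        "worries_older_child": 1.14,
        "childhood_abuse": 0.77,
        "depression_symptoms": 2.42,
        "smoking": 5.85,
        "consultation_request": 1.96
      }
    },
    "items": {
      "maternity_life": {
        "baseline": 0.155,
        "or": 4.165
      },
      "talking_with_partner": {
        "baseline": 0.027,
        "or": 6.773
      },
      "partner_violence": {
        "baseline": 0.009,
        "or": 12.918
      },
      "worries_older_child": {
        "baseline": 0.11,
        "or": 1.342
      },
      "childhood_abuse": {
        "baseline": 0.022,
        "or": 6.413
      },
      "depression_symptoms": {
        "baseline": 0.135,
        "or": 2.74
      },
      "family_social_support": {
        "baseline": 0.0045,
        "or": 7.691
      },
      "smoking": {
        "baseline": 0.018,
        "or": 24.113
      },
      "alcohol_use": {
        "baseline": 0.005,
        "or": 1.0
      },
      "consultation_request": {
        "baseline": 0.09,
        "or": 2.051
      },
      "health_checkups": {
        "baseline": 0.004,
        "or": 1.0
      }
    }
  },
  "third_trimester": {
    "outcome_prevalence": 0.06,
    "hospital_support_prevalence": 0.13,
    "epds": {
      "prevalence_ge9": 0.073,
      "effect_ors": {
        "depression_symptoms": 4.65,
        "worries_older_child": 1.7,
        "pregnancy_course_concerns": 2.01,
        "family_social_support": 24.14,
        "childbirth_preparation": 0.33,
        "consultation_request": 1.71,
        "fetal_anomaly_fgr": 0.56
      }
    },
    "items": {
      "depression_symptoms": {
        "baseline": 0.05,
        "or": 2.329
      },
      "worries_older_child": {
        "baseline": 0.08,
        "or": 3.039
      },
      "pregnancy_course_concerns": {
        "baseline": 0.1,
        "or": 2.483
      },
      "family_social_support": {
        "baseline": 0.005,
        "or": 53.397
      },
      "childbirth_preparation": {
        "baseline": 0.05,
        "or": 3.416
      },
      "consultation_request": {
        "baseline": 0.08,
        "or": 4.458
      },
      "health_checkups": {
        "baseline": 0.005,
        "or": 12.182
      },
      "fetal_anomaly_fgr": {
        "baseline": 0.05,
        "or": 7.0
      }
    }
  },
  "postpartum": {
    "outcome_prevalence": 0.23,
    "hospital_support_prevalence": 0.21,
    "epds": {
      "prevalence_ge9": 0.067,
      "effect_ors": {}
    },
    "items": {
      "fetal_condition": {
        "baseline": 0.05,
        "or": 2.0
      },
      "childcare_feelings": {
        "baseline": 0.08,
        "or": 3.0
      },
      "partner_support": {
        "baseline": 0.06,
        "or": 3.0
      },
      "family_social_support": {
        "baseline": 0.01,
        "or": 5.0
      },
      "childcare_difficulty": {
        "baseline": 0.1,
        "or": 3.0
      },
      "consultation_request": {
        "baseline": 0.08,
        "or": 3.0
      }
    }
  }
}
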