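{
  "first_visit": {
    "n_epds": 415,
    "n_ge9": 28,
    "prevalence_ge9": 0.067,
    "rows": {
      "maternal_feelings": {"cor": 4.62, "cci": [1.8, 11.86], "cp": 0.002, "aor": 6.51, "aci": [1.62, 26.14], "ap": 0.008},
      "partner_feelings": {"cor": 1.46, "cci": [0.32, 6.6], "cp": 0.62, "aor": 0.35, "aci": [0.03, 3.51], "ap": 0.37},
      "depression_symptoms": {"cor": 2.75, "cci": [1.19, 7.11], "cp": 0.02, "aor": 2.86, "aci": [0.75, 10.92], "ap": 0.13},
      "economic_status": {"cor": 1.9, "cci": [0.74, 4.93], "cp": 0.19, "aor": 1.46, "aci": [0.37, 5.72], "ap": 0.58},
      "partner_status": {"cor": 1.25, "cci": [0.42, 3.77], "cp": 0.69, "aor": 2.44, "aci": [0.61, 9.69], "ap": 0.21},
      "maternal_mental_disorder": {"cor": 5.92, "cci": [1.95, 18.0], "cp": 0.002, "aor": 4.38, "aci": [1.06, 18.1], "ap": 0.04},
      "worries_older_child": {"cor": 1.43, "cci": [0.52, 3.92], "cp": 0.49, "aor": 1.41, "aci": [0.33, 6.14], "ap": 0.64},
      "consultation_request": {"cor": 3.31, "cci": [1.47, 7.43], "cp": 0.004, "aor": 3.22, "aci": [1.09, 9.45], "ap": 0.03},
      "multiple_pregnancy": {"cor": 3.18, "cci": [0.65, 15.48], "cp": 0.15, "aor": 1.97, "aci": [0.19, 20.43], "ap": 0.57},
      "children_ge3": {"cor": 1.0, "cci": [0.13, 7.91], "cp": 1.0, "aor": 0.85, "aci": [0.05, 13.43], "ap": 0.91},
      "maternal_age_lt25": {"cor": 1.06, "cci": [0.06, 5.62], "cp": 0.96, "aor": 0.8, "aci": [0.06, 10.22], "ap": 0.86}
    },
    "excluded": {"family_social_support": 1, "drug_use_mother": 4, "drug_use_partner": 3}
  },
  "second_trimester": {
    "n_epds": 384,
    "n_ge9": 24,
    "prevalence_ge9": 0.063,
    "rows": {
      "maternity_life": {"cor": 4.18, "cci": [1.81, 10.02], "cp": 0.0009, "aor": 3.15, "aci": [1.29, 7.67], "ap": 0.01},
      "talking_with_partner": {"cor": 2.63, "cci": [0.55, 12.48], "cp": 0.22, "aor": 1.76, "aci": [0.27, 11.41], "ap": 0.56},
      "partner_violence": {"cor": 1.91, "cci": [0.23, 15.91], "cp": 0.55, "aor": 1.12, "aci": [0.09, 13.48], "ap": 0.93},
      "worries_older_child": {"cor": 1.78, "cci": [0.64, 5.01], "cp": 0.27, "aor": 1.14, "aci": [0.37, 3.52], "ap": 0.82},
      "childhood_abuse": {"cor": 1.95, "cci": [0.42, 9.04], "cp": 0.39, "aor": 0.77, "aci": [0.13, 4.42], "ap": 0.77},
      "depression_symptoms": {"cor": 3.11, "cci": [1.3, 7.45], "cp": 0.01, "aor": 2.42, "aci": [0.96, 6.1], "ap": 0.06},
      "smoking": {"cor": 5.17, "cci": [0.52, 51.71], "cp": 0.16, "aor": 5.85, "aci": [0.5, 68.9], "ap": 0.16},
      "consultation_request": {"cor": 2.5, "cci": [1.08, 5.76], "cp": 0.03, "aor": 1.96, "aci": [0.8, 4.8], "ap": 0.14}
    },
    "excluded": {"family_social_support": 2, "alcohol_use": 2, "health_checkups": 1}
  },
  "third_trimester": {
    "n_epds": 232,
    "n_ge9": 17,
    "prevalence_ge9": 0.073,
    "rows": {
      "depression_symptoms": {"cor": 3.36, "cci": [0.94, 12.04], "cp": 0.06, "aor": 4.65, "aci": [0.94, 22.94], "ap": 0.06},
      "worries_older_child": {"cor": 1.68, "cci": [0.45, 5.08], "cp": 0.41, "aor": 1.7, "aci": [0.41, 7.1], "ap": 0.46},
      "pregnancy_course_concerns": {"cor": 2.36, "cci": [0.83, 6.73], "cp": 0.11, "aor": 2.01, "aci": [0.54, 7.54], "ap": 0.3},
      "family_social_support": {"cor": 13.25, "cci": [0.79, 221.8], "cp": 0.07, "aor": 24.14, "aci": [0.56, 1035.66], "ap": 0.1},
      "childbirth_preparation": {"cor": 0.96, "cci": [0.26, 2.86], "cp": 0.95, "aor": 0.33, "aci": [0.066, 1.69], "ap": 0.18},
      "consultation_request": {"cor": 2.49, "cci": [0.89, 6.94], "cp": 0.08, "aor": 1.71, "aci": [0.48, 6.09], "ap": 0.41},
      "fetal_anomaly_fgr": {"cor": 1.66, "cci": [0.25, 6.61], "cp": 0.55, "aor": 0.56, "aci": [0.06, 5.24], "ap": 0.62}
    },
    "excluded": {"health_checkups": 3}
  }
}
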