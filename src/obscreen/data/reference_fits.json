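{
  "first_visit": {
    "model1": {
      "n": 558,
      "terms": {
        "maternal_feelings": {"or": 10.985, "ci": [3.966, 30.422], "p": 0.0},
        "partner_feelings": {"or": 5.566, "ci": [1.723, 17.98], "p": 0.004},
        "depression_symptoms": {"or": 3.987, "ci": [1.135, 14.005], "p": 0.031},
        "family_social_support": {"or": 13.489, "ci": [1.325, 137.317], "p": 0.028},
        "economic_status": {"or": 10.235, "ci": [3.787, 27.66], "p": 0.0},
        "partner_status": {"or": 6.433, "ci": [2.324, 17.812], "p": 0.0},
        "maternal_mental_disorder": {"or": 13.593, "ci": [4.653, 39.709], "p": 0.0},
        "drug_use_mother": {"or": 0.0, "ci": [0.0, 0.0], "p": 0.999, "separation": true},
        "drug_use_partner": {"or": 0.0, "ci": [0.0, 0.0], "p": 0.999, "separation": true},
        "worries_older_child": {"or": 2.154, "ci": [0.685, 6.767], "p": 0.189},
        "consultation_request": {"or": 3.689, "ci": [1.322, 10.296], "p": 0.013},
        "multiple_pregnancy": {"or": 4.96, "ci": [1.049, null], "p": 0.043},
        "children_ge3": {"or": 7.239, "ci": [1.903, null], "p": 0.004},
        "maternal_age_lt25": {"or": 15.49, "ci": [4.909, null], "p": 0.0}
      }
    },
    "model2": {
      "n": 554,
      "terms": {
        "maternal_feelings": {"sprc": 0.069, "or": 2.72, "ci": [0.509, 14.527], "p": 0.242, "vif": 1.095},
        "depression_symptoms": {"sprc": 0.019, "or": 1.794, "ci": [0.312, 10.298], "p": 0.512, "vif": 1.058},
        "family_social_support": {"sprc": 0.117, "or": 32.455, "ci": [1.386, 759.856], "p": 0.031, "vif": 1.059},
        "economic_status": {"sprc": 0.076, "or": 2.24, "ci": [0.473, 10.613], "p": 0.31, "vif": 1.167},
        "partner_status": {"sprc": 0.129, "or": 6.068, "ci": [1.33, 27.686], "p": 0.02, "vif": 1.086},
        "maternal_mental_disorder": {"sprc": 0.16, "or": 11.131, "ci": [1.662, 74.542], "p": 0.013, "vif": 1.034},
        "worries_older_child": {"sprc": 0.028, "or": 2.917, "ci": [0.367, null], "p": 0.312, "vif": 1.02},
        "multiple_pregnancy": {"sprc": 0.105, "or": 14.601, "ci": [1.557, null], "p": 0.019, "vif": 1.01},
        "children_ge3": {"sprc": 0.141, "or": 19.624, "ci": [2.45, null], "p": 0.005, "vif": 1.103},
        "maternal_age_lt25": {"sprc": 0.212, "or": 37.134, "ci": [5.458, null], "p": 0.0, "vif": 1.039}
      }
    },
    "roc": {"threshold": 22, "auc": 0.96, "sensitivity": 0.92, "specificity": 0.92}
  },
  "second_trimester": {
    "model1": {
      "n": 483,
      "terms": {
        "maternity_life": {"or": 4.165, "ci": [2.306, 7.525], "p": 0.0},
        "talking_with_partner": {"or": 6.773, "ci": [2.413, 19.008], "p": 0.0},
        "partner_violence": {"or": 12.918, "ci": [3.523, 47.367], "p": 0.0},
        "worries_older_child": {"or": 1.342, "ci": [0.598, 3.009], "p": 0.476},
        "childhood_abuse": {"or": 6.413, "ci": [2.695, 15.259], "p": 0.0},
        "depression_symptoms": {"or": 2.74, "ci": [1.547, 4.852], "p": 0.001},
        "family_social_support": {"or": 7.691, "ci": [0.474, 124.717], "p": 0.151},
        "smoking": {"or": 24.113, "ci": [2.464, 236.008], "p": 0.006},
        "alcohol_use": {"or": 0.0, "ci": [0.0, 0.0], "p": 0.999, "separation": true},
        "consultation_request": {"or": 2.051, "ci": [1.158, 3.632], "p": 0.014},
        "health_checkups": {"or": null, "ci": [0.0, null], "p": 1.0, "separation": true}
      }
    },
    "model2": {
      "n": 472,
      "terms": {
        "maternity_life": {"sprc": 0.167, "or": 3.19, "ci": [1.603, 6.35], "p": 0.001, "vif": 1.119},
        "talking_with_partner": {"sprc": 0.108, "or": 3.102, "ci": [0.819, 11.752], "p": 0.096, "vif": 1.233},
        "partner_violence": {"sprc": 0.15, "or": 7.081, "ci": [1.502, 33.388], "p": 0.013, "vif": 1.236},
        "childhood_abuse": {"sprc": 0.135, "or": 3.566, "ci": [1.281, 9.929], "p": 0.015, "vif": 1.083},
        "depression_symptoms": {"sprc": 0.058, "or": 1.531, "ci": [0.785, 2.984], "p": 0.211, "vif": 1.114},
        "family_social_support": {"sprc": 0.072, "or": 7.517, "ci": [0.407, 138.934], "p": 0.175, "vif": 1.004},
        "smoking": {"sprc": 0.165, "or": 26.667, "ci": [2.316, 306.98], "p": 0.008, "vif": 1.019},
        "consultation_request": {"sprc": 0.053, "or": 1.499, "ci": [0.78, 2.881], "p": 0.225, "vif": 1.064}
      }
    },
    "roc": {"threshold": 14, "auc": 0.77, "sensitivity": 0.82, "specificity": 0.62}
  },
  "third_trimester": {
    "model1": {
      "n": 296,
      "terms": {
        "depression_symptoms": {"or": 2.329, "ci": [0.617, 8.793], "p": 0.2123},
        "worries_older_child": {"or": 3.039, "ci": [0.872, 10.591], "p": 0.0809},
        "pregnancy_course_concerns": {"or": 2.483, "ci": [0.73, 8.446], "p": 0.1453},
        "family_social_support": {"or": 53.397, "ci": [4.462, 638.95], "p": 0.0017},
        "childbirth_preparation": {"or": 3.416, "ci": [0.386, 30.227], "p": 0.2695},
        "consultation_request": {"or": 4.458, "ci": [1.306, 15.218], "p": 0.017},
        "health_checkups": {"or": 12.182, "ci": [1.025, 144.745], "p": 0.0477},
        "fetal_anomaly_fgr": {"or": 7.0, "ci": [1.923, 25.48], "p": 0.0032}
      }
    },
    "model2": {
      "n": 296,
      "terms": {
        "depression_symptoms": {"sprc": 0.288, "or": 2.865, "ci": [0.54, 15.204], "p": 0.2165},
        "worries_older_child": {"sprc": 0.1226, "or": 1.88, "ci": [0.344, 10.28], "p": 0.4664},
        "family_social_support": {"sprc": 0.276, "or": 124.973, "ci": [3.724, null], "p": 0.0071},
        "childbirth_preparation": {"sprc": 0.0653, "or": 2.027, "ci": [0.144, 28.527], "p": 0.6006},
        "consultation_request": {"sprc": 0.5232, "or": 7.603, "ci": [1.54, 37.545], "p": 0.0128},
        "health_checkups": {"sprc": 0.2416, "or": 68.484, "ci": [3.034, null], "p": 0.0079},
        "fetal_anomaly_fgr": {"sprc": 0.4354, "or": 18.455, "ci": [3.628, 93.887], "p": 0.0004}
      }
    },
    "roc": {"threshold": 7, "auc": 0.46, "sensitivity": 0.43, "specificity": 0.57}
  }
}
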