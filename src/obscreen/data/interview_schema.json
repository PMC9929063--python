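{
  "first_visit": [
    {"item_id": "maternal_feelings", "label": "Maternal feelings toward being pregnant",
     "positive": ["Happy"],
     "negative": ["Confused", "Trouble", "Did not feel anything to be pregnant"]},
    {"item_id": "partner_feelings", "label": "Partner's feelings toward being pregnant",
     "positive": ["Happy"],
     "negative": ["Confused", "Trouble", "Did not feel anything to be pregnant"]},
    {"item_id": "depression_symptoms", "label": "Depression symptoms",
     "positive": ["Nothing", "Very few", "Nothing/Very few"],
     "negative": ["Sometimes", "Often", "Sometimes/Often"]},
    {"item_id": "family_social_support", "label": "Family and social support",
     "positive": ["Yes"], "negative": ["No"]},
    {"item_id": "economic_status", "label": "Economic status",
     "positive": ["No problem"],
     "negative": ["Deprived", "Need of public assistance", "Deprived/Need of public assistance"]},
    {"item_id": "partner_status", "label": "Partner's status",
     "positive": ["Married"], "negative": ["Unmarried", "Remarried", "Unmarried/Remarried"]},
    {"item_id": "maternal_mental_disorder", "label": "Maternal mental disorder",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "drug_use_mother", "label": "Illegal drug use by the mother",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "drug_use_partner", "label": "Illegal drug use by the partner",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "worries_older_child", "label": "Worries about older child",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "consultation_request", "label": "Consultation request",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "multiple_pregnancy", "label": "Number of fetuses",
     "positive": ["Singleton pregnancies", "Singleton"],
     "negative": ["Multiple pregnancies", "Multiple"]},
    {"item_id": "children_ge3", "label": "Number of children (exclusive of this pregnancy)",
     "positive": ["<3"], "negative": ["≧3", ">=3"]},
    {"item_id": "maternal_age_lt25", "label": "Maternal age",
     "positive": ["≧25", ">=25"], "negative": ["<25"]}
  ],
  "second_trimester": [
    {"item_id": "maternity_life", "label": "Maternity life",
     "positive": ["Almost happy"],
     "negative": ["Difficulty", "Anxiety", "Difficulty/Anxiety"]},
    {"item_id": "talking_with_partner", "label": "Talking with partner",
     "positive": ["Very often", "Sometimes", "Very often/Sometimes"],
     "negative": ["Very few", "Nothing", "Very few/Nothing"]},
    {"item_id": "partner_violence", "label": "Partner violence",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "worries_older_child", "label": "Worries about older child",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "childhood_abuse", "label": "Parent's own childhood abuse",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "depression_symptoms", "label": "Depression symptoms",
     "positive": ["Nothing", "Very few", "Nothing/Very few"],
     "negative": ["Sometimes", "Often", "Sometimes/Often"]},
    {"item_id": "family_social_support", "label": "Family and social support",
     "positive": ["Yes"], "negative": ["No"]},
    {"item_id": "smoking", "label": "Smoking",
     "positive": ["No", "Discontinued after pregnant", "No/Discontinued after pregnant"],
     "negative": ["Continued after pregnant"]},
    {"item_id": "alcohol_use", "label": "Alcohol use",
     "positive": ["No", "Discontinued after pregnant", "No/Discontinued after pregnant"],
     "negative": ["Continued after pregnant"]},
    {"item_id": "consultation_request", "label": "Consultation request",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "health_checkups", "label": "Status of pregnancy health checkups",
     "positive": ["Usual"], "negative": ["Less", "Unscheduled", "Less/Unscheduled"]}
  ],
  "third_trimester": [
    {"item_id": "depression_symptoms", "label": "Depression symptoms",
     "positive": ["Nothing", "Very few", "Nothing/Very few"],
     "negative": ["Sometimes", "Often", "Sometimes/Often"]},
    {"item_id": "worries_older_child", "label": "Worries about older child",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "pregnancy_course_concerns", "label": "Concerns about the course of pregnancy",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "family_social_support", "label": "Family and social support",
     "positive": ["Yes"], "negative": ["No"]},
    {"item_id": "childbirth_preparation", "label": "Childbirth preparation",
     "positive": ["Almost finished", "Finished"], "negative": ["Unfinished"]},
    {"item_id": "consultation_request", "label": "Consultation request",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "health_checkups", "label": "Pregnancy health checkups",
     "positive": ["Usual"], "negative": ["Less", "Unscheduled", "Less/Unscheduled"]},
    {"item_id": "fetal_anomaly_fgr", "label": "Fetal congenital disease or fetal growth restriction",
     "positive": ["No"], "negative": ["Yes"]}
  ],
  "postpartum": [
    {"item_id": "fetal_condition", "label": "Fetal condition after childbirth",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "childcare_feelings", "label": "Feelings toward childcare",
     "positive": ["Happy"], "negative": ["Neither", "Unhappy", "Neither/Unhappy"]},
    {"item_id": "partner_support", "label": "Partner's support",
     "positive": ["Often", "Sometimes", "Often/Sometimes"], "negative": ["Few"]},
    {"item_id": "family_social_support", "label": "Family and social support",
     "positive": ["Yes"], "negative": ["No"]},
    {"item_id": "childcare_difficulty", "label": "Difficulty of childcare",
     "positive": ["Nothing", "Sometimes", "Nothing/Sometimes"], "negative": ["Often"]},
    {"item_id": "consultation_request", "label": "Consultation request",
     "positive": ["No"], "negative": ["Yes"]},
    {"item_id": "epds", "label": "EPDS",
     "positive": ["<9"], "negative": ["≧9", ">=9"]}
  ]
}
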