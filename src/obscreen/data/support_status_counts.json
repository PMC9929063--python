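{
  "_note": "Published descriptive counts of responses and support status per period and site. Read-only reference; no computation is built on it. hospital_support = socially high-risk women supported within the obstetric institution; admin_cooperation = women judged to need cooperation with a public health center.",
  "sites": ["osaka", "seibo", "showa"],
  "first_visit": {
    "n_cases": {"osaka": 279, "seibo": 120, "showa": 277, "total": 678},
    "missing": {"osaka": 7, "seibo": 0, "showa": 2, "total": 9},
    "hospital_support": {"osaka": 41, "seibo": 5, "showa": 67, "total": 113},
    "admin_cooperation": {"osaka": 8, "seibo": 0, "showa": 6, "total": 14}
  },
  "second_trimester": {
    "n_cases": {"osaka": 225, "seibo": 46, "showa": 224, "total": 495},
    "missing": {"osaka": 10, "seibo": 1, "showa": 0, "total": 11},
    "hospital_support": {"osaka": 23, "seibo": 3, "showa": 8, "total": 34},
    "admin_cooperation": {"osaka": 9, "seibo": 0, "showa": 21, "total": 30}
  },
  "third_trimester": {
    "n_cases": {"osaka": 171, "seibo": 40, "showa": 85, "total": 296},
    "missing": {"osaka": 13, "seibo": 0, "showa": 1, "total": 14},
    "hospital_support": {"osaka": 17, "seibo": 2, "showa": 18, "total": 37},
    "admin_cooperation": {"osaka": 8, "seibo": 0, "showa": 10, "total": 18}
  },
  "postpartum": {
    "n_cases": {"osaka": 199, "seibo": 61, "showa": 562, "total": 822},
    "missing": {"osaka": 8, "seibo": 1, "showa": 294, "total": 303},
    "hospital_support": {"osaka": 5, "seibo": 4, "showa": 99, "total": 108},
    "admin_cooperation": {"osaka": 37, "seibo": 2, "showa": 80, "total": 119}
  }
}
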