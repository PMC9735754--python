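{
  "name": "oral brush-biopsy study cohort (synthetic reconstruction from printed grouped counts)",
  "derivation": [
    "Reconstructed, not deposited data: the published study reports only grouped counts.",
    "Cytology category x ploidy-verdict margins: positive 222/6, suspicious 49/14, doubtful 23/84, negative 0/204 (aneuploid/non-aneuploid), total 602.",
    "Dichotomized cytology vs follow-up: tp=308, tn=204, fp=90, fn=0; ploidy vs follow-up: tp=288, fp=6, fn=20, tn=288.",
    "The within-category follow-up split is not printed; it is allocated here as: all 6 ploidy false positives in (doubtful, aneuploid); the 20 ploidy false negatives as 6 (positive, non-aneuploid) + 14 (suspicious, non-aneuploid), which exactly exhausts those cells; the 84 (doubtful, non-aneuploid) cases all follow-up negative; every other aneuploid case follow-up positive.",
    "Any allocation consistent with the margins yields identical dichotomized metrics (sens/spec/PPV/NPV, AUC, conditional OR), so downstream results do not depend on this choice."
  ],
  "expected_total": 602,
  "counts": [
    {
      "cytology": 4,
      "icm": "aneuploid",
      "followup": "positive",
      "n": 222
    },
    {
      "cytology": 3,
      "icm": "aneuploid",
      "followup": "positive",
      "n": 49
    },
    {
      "cytology": 2,
      "icm": "aneuploid",
      "followup": "positive",
      "n": 17
    },
    {
      "cytology": 2,
      "icm": "aneuploid",
      "followup": "negative",
      "n": 6
    },
    {
      "cytology": 4,
      "icm": "non_aneuploid",
      "followup": "positive",
      "n": 6
    },
    {
      "cytology": 3,
      "icm": "non_aneuploid",
      "followup": "positive",
      "n": 14
    },
    {
      "cytology": 2,
      "icm": "non_aneuploid",
      "followup": "negative",
      "n": 84
    },
    {
      "cytology": 1,
      "icm": "non_aneuploid",
      "followup": "negative",
      "n": 204
    }
  ],
  "benign_criteria_split": {
    "comment": "Among the 6 aneuploid cases with negative follow-up: atypical stemline only, >9c cells only, or both (consistent with the published criteria table's benign column).",
    "atypical_stemline_only": 2,
    "cells_gt9c_only": 1,
    "both": 3
  },
  "sha256": "e214646c6ac308f57a4cf7564358baafc0fbfabac396fe69ca43807b2a57cf8e"
}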