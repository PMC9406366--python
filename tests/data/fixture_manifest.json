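{
  "comment": "Hand-enumerated expected results for the scripted fixture cohort (synthetic, non-clinical). study_end 2013-12-31, washout 180 days, packaged default code lists.",
  "study_end": "2013-12-31",
  "n_patients": 20,
  "events_kept": 18,
  "dropped_orphan_events": 1,
  "dropped_censored_events": 2,
  "exclusions": {
    "non_female": 1,
    "under_18": 1,
    "stage_out_of_range": 0,
    "histology_exclusion": 1,
    "early_death": 1
  },
  "eligible": 16,
  "sbce_patients": 11,
  "non_sbce_patients": 5,
  "contralateral_patients": 3,
  "per_criterion_patients": {
    "death_breast_cancer": 1,
    "procedure_diagnosis": 3,
    "systemic_treatment": 3,
    "radiotherapy": 6
  },
  "per_criterion_events": {
    "death_breast_cancer": 1,
    "procedure_diagnosis": 3,
    "systemic_treatment": 3,
    "radiotherapy": 7
  },
  "per_criterion_contralateral_events": {
    "procedure_diagnosis": 0,
    "radiotherapy": 3
  },
  "combination_partition": {
    "radiotherapy": 4,
    "procedure_diagnosis": 3,
    "systemic_treatment": 1,
    "death_breast_cancer": 1,
    "systemic_treatment+radiotherapy": 2
  },
  "sbce_patient_ids": ["F01", "F03", "F05", "F06", "F12", "F13", "F14", "F15", "F17", "F19", "F20"],
  "contralateral_patient_ids": ["F01", "F05", "F19"]
}
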