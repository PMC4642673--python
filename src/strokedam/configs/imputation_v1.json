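{
  "name": "imputation_v1",
  "comment": "Population defaults for optional covariates, from the treated-registry margins: infarct sign uses the registry mean, antiplatelet/weight/hypertension follow the worked-example conventions; unknown comorbidities default to absent.",
  "defaults": {
    "infarct_sign": 0.294,
    "weight_kg": 80,
    "aspirin": 1,
    "clopidogrel": 0,
    "hypertension": 0,
    "chf": 0,
    "diabetes": 0,
    "prior_stroke": 0
  }
}
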