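{
  "name": "population_vista_v1",
  "comment": "Marginal distributions of the untreated trial-archive validation cohort. Onset-to-treatment time is not recorded for untreated patients; the treated registry's margin is reused so that generated profiles pass validation. Infarct-sign prevalence likewise reuses the treated registry value.",
  "margins": {
    "age": {"dist": "truncnorm", "mean": 70.5, "sd": 12.2, "lo": 18, "hi": null},
    "male": {"dist": "bernoulli", "p": 0.516},
    "diabetes": {"dist": "bernoulli", "p": 0.214},
    "prior_stroke": {"dist": "bernoulli", "p": 0.343},
    "sbp": {"dist": "truncnorm", "mean": 156.8, "sd": 26.7, "lo": 60, "hi": 200},
    "glucose": {"dist": "lognorm_iqr", "median": 6.7, "q1": 5.8, "q3": 8.5, "lo": 2.0, "hi": 25},
    "nihss": {"dist": "lognorm_iqr", "median": 13, "q1": 8, "q3": 18, "lo": 0, "hi": 42, "integer": true},
    "ott": {"dist": "lognorm_iqr", "median": 146, "q1": 109, "q3": 175, "lo": 0, "hi": 270},
    "infarct_sign": {"dist": "bernoulli", "p": 0.239},
    "hypertension": {"dist": "bernoulli", "p": 0.721},
    "chf": {"dist": "bernoulli", "p": 0.045}
  }
}
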