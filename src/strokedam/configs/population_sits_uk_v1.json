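{
  "name": "population_sits_uk_v1",
  "comment": "Marginal distributions of the treated UK registry cohort (three-month survivors column). Median/IQR variables use a log-normal matched to the printed median and quartiles; truncation bounds respect the model's validated ranges.",
  "margins": {
    "age": {"dist": "truncnorm", "mean": 67.8, "sd": 13.26, "lo": 18, "hi": null},
    "male": {"dist": "bernoulli", "p": 0.586},
    "diabetes": {"dist": "bernoulli", "p": 0.149},
    "prior_stroke": {"dist": "bernoulli", "p": 0.1441},
    "sbp": {"dist": "truncnorm", "mean": 145.5, "sd": 21.8, "lo": 60, "hi": 200},
    "glucose": {"dist": "lognorm_iqr", "median": 6.2, "q1": 5.6, "q3": 7.8, "lo": 2.0, "hi": 25},
    "nihss": {"dist": "lognorm_iqr", "median": 12, "q1": 7, "q3": 18, "lo": 0, "hi": 42, "integer": true},
    "ott": {"dist": "lognorm_iqr", "median": 146, "q1": 109, "q3": 175, "lo": 0, "hi": 270},
    "infarct_sign": {"dist": "bernoulli", "p": 0.239},
    "hypertension": {"dist": "bernoulli", "p": 0.6036},
    "chf": {"dist": "bernoulli", "p": 0.045}
  }
}
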