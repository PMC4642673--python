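{
  "name": "stpi_severe_v1",
  "comment": "Original thrombolytic predictive instrument: P(mRS 5-6), no treatment association. Glucose enters truncated at 25 mmol/L.",
  "intercept": -7.58,
  "main_effects": {
    "age": 0.05,
    "nihss": 0.142,
    "glucose": 0.072
  },
  "interactions": [],
  "treatment_block": null,
  "base_prediction_coefficient": null
}
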