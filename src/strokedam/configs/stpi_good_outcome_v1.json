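{
  "name": "stpi_good_outcome_v1",
  "comment": "Original thrombolytic predictive instrument: P(mRS <= 1) with treatment interactions. Treatment x OTT is a worked-example solve pending the original publication's value.",
  "intercept": 1.0702,
  "main_effects": {
    "age": 0.0173,
    "sbp": -0.00488,
    "diabetes": -0.7431,
    "male": 0.3757,
    "nihss": -0.00764,
    "prior_stroke": 0.3728,
    "ott": 0.000333
  },
  "interactions": [
    [["age", "nihss"], -0.00285]
  ],
  "treatment_block": {
    "treatment": 3.3774,
    "interactions": {
      "sbp": -0.0117,
      "male": -0.4286,
      "prior_stroke": -0.7738,
      "ott": -0.00387
    }
  },
  "base_prediction_coefficient": null
}
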