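{
  "name": "dam_independence_v1",
  "comment": "Recalibration layer for P(mRS <= 2 | survival): registry-fitted corrections plus the base instrument's predicted probability as covariate (probability scale). Applied identically to both arms; the arm enters only through the base prediction.",
  "intercept": -0.1144,
  "main_effects": {
    "age": -0.0259,
    "sbp": 0.00831,
    "male": 0.1763,
    "nihss": -0.1372,
    "infarct_sign": -0.402
  },
  "interactions": [
    [["age", "nihss"], 0.00159]
  ],
  "treatment_block": null,
  "base_prediction_coefficient": 3.3896
}
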