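{
  "name": "dam_death_v1",
  "comment": "Registry refit for P(death, mRS 6) at three months; full refit (no base-prediction term), identical in both arms.",
  "intercept": -7.417,
  "main_effects": {
    "age": 0.0418,
    "nihss": 0.132,
    "glucose": 0.1024
  },
  "interactions": [],
  "treatment_block": null,
  "base_prediction_coefficient": null
}
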