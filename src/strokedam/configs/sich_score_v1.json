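{
  "name": "sich_score_v1",
  "comment": "Registry point score for symptomatic intracerebral haemorrhage (PH2 haematoma with NIHSS worsening >= 4 within 24 h) in thrombolysed patients, over antiplatelet use, NIHSS band, glucose, age, SBP, weight, onset-to-treatment time and hypertension history. Risk table classes 5, 6 and 7 are anchored to the decision model's published worked-example risks (3.14 %, 3.72 %, 5.05 %); the remaining classes are filled by logit-linear interpolation between those anchors.",
  "items": [
    {"name": "dual_antiplatelet", "points": 3, "conditions": [
      {"field": "aspirin", "op": "eq", "value": 1},
      {"field": "clopidogrel", "op": "eq", "value": 1}
    ]},
    {"name": "aspirin_monotherapy", "points": 2, "conditions": [
      {"field": "aspirin", "op": "eq", "value": 1},
      {"field": "clopidogrel", "op": "eq", "value": 0}
    ]},
    {"name": "nihss_7_to_12", "points": 1, "conditions": [
      {"field": "nihss", "op": "band", "lo": 7, "hi": 12}
    ]},
    {"name": "nihss_13_plus", "points": 2, "conditions": [
      {"field": "nihss", "op": "band", "lo": 13, "hi": null}
    ]},
    {"name": "glucose_10_plus", "points": 2, "conditions": [
      {"field": "glucose", "op": "ge", "value": 10}
    ]},
    {"name": "age_72_plus", "points": 1, "conditions": [
      {"field": "age", "op": "ge", "value": 72}
    ]},
    {"name": "sbp_146_plus", "points": 1, "conditions": [
      {"field": "sbp", "op": "ge", "value": 146}
    ]},
    {"name": "weight_95_plus", "points": 1, "conditions": [
      {"field": "weight_kg", "op": "ge", "value": 95}
    ]},
    {"name": "ott_180_plus", "points": 1, "conditions": [
      {"field": "ott", "op": "ge", "value": 180}
    ]},
    {"name": "hypertension_history", "points": 1, "conditions": [
      {"field": "hypertension", "op": "eq", "value": 1}
    ]}
  ],
  "risk_table": {
    "0": 0.0093,
    "1": 0.0119,
    "2": 0.0152,
    "3": 0.0194,
    "4": 0.0247,
    "5": 0.0314,
    "6": 0.0372,
    "7": 0.0505,
    "8": 0.0638,
    "9": 0.0803,
    "10": 0.1005,
    "11": 0.1252,
    "12": 0.155
  },
  "outcome_split": {
    "p_independent_given_sich": 0.06,
    "p_dependent_given_sich": 0.33,
    "p_dead_given_sich": 0.61
  }
}
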