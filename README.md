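# strokedam

Individualised risk–benefit forecasts for intravenous thrombolysis in
acute ischaemic stroke.

Whether to thrombolyse a stroke patient is a trade-off: treatment raises
the chance of functional independence but carries a risk of symptomatic
intracerebral haemorrhage (SICH), and both vary strongly with patient
characteristics. `strokedam` implements a decision-analytic model that
predicts, for a single patient, the three-month probability of
independence (modified Rankin Scale mRS ≤ 2), dependence (mRS 3–5) and
death (mRS 6) **with and without** thrombolysis, together with the
treated-arm SICH risk — plus the calibration machinery used to build
such models and a synthetic-cohort generator to test it with.

## The model

The core is a recalibration of the Stroke-Thrombolytic Predictive
Instrument (S-TPI), a pooled-trial logistic model of good outcome
(mRS ≤ 1) with treatment interactions, against outcomes of routinely
treated registry patients. Death is handled as a competing risk:

- **Death**: `P(dead) = expit(−7.417 + 0.0418·age + 0.132·NIHSS +
  0.1024·glucose)`, a registry refit, identical in both arms (the net
  effect of thrombolysis on three-month death is taken as zero).
- **Independence among survivors**: a logistic recalibration in which
  the S-TPI's own predicted probability `P_STPI(arm)` enters as a
  covariate,
  `P(mRS ≤ 2 | survival) = expit(−0.1144 − 0.0259·age + 0.00831·SBP +
  0.1763·male − 0.1372·NIHSS + 0.00159·age·NIHSS − 0.402·infarct +
  3.3896·P_STPI(arm))`.
  The same correction coefficients apply to both arms, so the
  instrument's net treatment effect is preserved; the arm enters only
  through `P_STPI`.
- **Combination**: `P(independent) = P(mRS ≤ 2 | survival)·(1 −
  P(dead))`, with dependence as the residual, so the three states always
  sum to one.
- **SICH**: a registry point score (antiplatelet use, NIHSS band,
  glucose, age, SBP, weight, onset-to-treatment time, hypertension
  history) mapped through a monotone risk table; post-SICH outcomes
  split 6 % / 33 % / 61 % (independent / dependent / dead). SICH
  consequences are already inside the treated-arm death probability, so
  the risk is reported alongside, never subtracted.

All coefficient sets live in versioned JSON configs
(`strokedam/configs/`), not in code. Supported input ranges follow the
calibration cohort: age ≥ 18, SBP ≤ 200 mmHg, OTT ≤ 270 min; glucose is
truncated at 25 mmol/L.

## Worked example

A 57-year-old man with diabetes, SBP 179 mmHg, glucose 20.7 mmol/L,
NIHSS 5, presenting 164 min after onset:

```sh
$ echo '{"age": 57, "male": 1, "diabetes": 1, "prior_stroke": 0,
         "sbp": 179, "glucose": 20.7, "nihss": 5, "ott": 164}' > patient.json
$ strokedam predict --patient patient.json
Three-month outcome forecast (per 100 such patients):
  untreated  independent  73 %   dependent  17 %   dead   9 %
  treated    independent  76 %   dependent  15 %   dead   9 %
  SICH risk if treated: 3.14 %
  net benefit (independence gained by treating): +2.5 percentage points
```

Of 100 such patients, 73 would be independent at three months without
treatment and 76 with it — a modest expected gain of about 3 per 100
treated, against a 3.14 % haemorrhage risk. Missing optional fields
(infarct sign on the pre-treatment scan, weight, antiplatelet use,
hypertension history) are imputed from configurable registry defaults.

The same API is available in Python:

```python
from strokedam import PatientProfile, prepare_profile, predict_pair

profile = prepare_profile(PatientProfile(age=57, male=1, diabetes=1,
    prior_stroke=0, sbp=179, glucose=20.7, nihss=5, ott=164))
pair = predict_pair(profile)
pair.net_benefit        # 0.0246
pair.treated.p_dead     # 0.095
```

Other commands: `strokedam sweep` (one-way sensitivity analysis),
`strokedam simulate` (synthetic registry-like cohorts),
`strokedam calibrate` (stepwise logistic recalibration of a base model
against observed outcomes) and `strokedam validate` (concordance
statistic and calibration curves).

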