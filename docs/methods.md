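# Methods

## Model structure

`strokedam` predicts the three-month outcome distribution of an acute
ischaemic-stroke patient under each treatment decision (intravenous
thrombolysis yes/no) as a competing-risk composition of two logistic
models layered on the Stroke-Thrombolytic Predictive Instrument
(S-TPI).

**Base instrument (`stpi`).** Two pooled-trial logistic regressions:
P(mRS ≤ 1), with a thrombolysis main effect and treatment interactions
with SBP, sex, prior stroke and onset-to-treatment time (OTT); and
P(mRS 5–6) from age, NIHSS and glucose, with no treatment term
(thrombolysis shows no association with the catastrophic-outcome
composite). The OTT main effect is evaluated in both arms exactly as
published; for an untreated prediction OTT is read as
onset-to-assessment time. The treatment × OTT coefficient is not
legible in the published coefficient table; the shipped config carries
−0.00387 per minute, the value that solves the published treated
worked examples, and is stored in config precisely so it can be
replaced without touching code if the original trial publication's
value is recovered.

**Death model (`dam`).** A registry refit (no base-prediction term):
logit P(death) = −7.417 + 0.0418·age + 0.132·NIHSS + 0.1024·glucose.
It is applied identically in both arms, encoding the assumption that
acute-phase deaths caused by treatment are offset by post-acute lives
saved, so the *net* effect of thrombolysis on three-month death is
zero. Haemorrhage deaths in treated patients are therefore inside this
probability, which is why the SICH overlay (below) is display-only.

**Independence among survivors (`dam`).** Because death competes with
functional outcome, the independence model is conditional on survival.
It is a *recalibration*, not a refit: the S-TPI's predicted probability
of the matching arm enters as a covariate on the probability scale
with weight 3.3896, alongside the correction terms that survived
stepwise deletion in the registry fit (age, SBP, male, NIHSS,
age × NIHSS, infarct sign on the pre-treatment scan). The corrections
are applied to both arms so the instrument's net treatment effect is
preserved; the treatment arm influences the result only through the
base prediction. The unconditional probabilities are

    P(independent) = P(independent | survive) · (1 − P(death))
    P(dependent)   = 1 − P(independent) − P(death)

The residual is non-negative by construction (the conditional
probability cannot exceed 1), and an assertion — not a silent clamp —
guards it.

Two structural choices here were genuinely open and were fixed by
forward evaluation against the published worked examples: the base
prediction enters on the *probability* scale (a logit-scale entry does
not reproduce the printed percentages), and the base prediction for the
mRS ≤ 2 calibration is the mRS ≤ 1 prediction of the *corresponding*
arm. The published table's sign typography is ambiguous for several
coefficients (signs printed flush against values); the shipped signs
are the unique assignment we found that reproduces the worked examples,
including the initially surprising negative diabetes effect
(−0.7431) and the positive prior-stroke main effect (+0.3728). One
published worked example (the only prior-stroke patient) does not
reproduce under any sign assignment we tried (computed 28 %/31 %
vs printed 21 %/24 % for treated/untreated independence); it is
documented here rather than "fixed", and excluded from the reproduction
tests.

**SICH (`sich`).** Symptomatic intracerebral haemorrhage (NIHSS
worsening ≥ 4 within 24 h with a PH2 haematoma) is too rare for a
bespoke regression, so risk is assigned by a registry-derived point
score held entirely in config: dual antiplatelet 3 points, aspirin
monotherapy 2, NIHSS ≥ 13 2 (7–12: 1), glucose ≥ 10 mmol/L 2, age ≥ 72
1, SBP ≥ 146 1, weight ≥ 95 kg 1, OTT ≥ 180 min 1, hypertension history
1. The risk table is anchored at points classes 5, 6 and 7 to the three
published risks (3.14 %, 3.72 %, 5.05 %); the remaining classes are
filled by logit-linear interpolation/extrapolation through those
anchors — they are monotone and plausible but are a modelling choice,
not published values. Two published worked examples print the class-5
risk where their point totals imply class 6; the shipped config follows
the score arithmetic, and those two values are excluded from the
anchor tests. Post-SICH outcomes use the fixed split 6 % independent /
33 % dependent / 61 % dead; the overlay decomposes `p_sich` for
pictograph display and is never added to the three-state totals, which
would double-count. Untreated haemorrhage risk is deliberately not
modelled (insufficient data); reports show it as not applicable, never
zero.

## Validation and imputation

Covariates outside the calibration ranges (age < 18, SBP > 200 mmHg,
OTT outside 0–270 min, NIHSS outside 0–42) are rejected with an error
naming the field, mirroring the calibration cohort's exclusions —
except glucose, which is truncated at 25 mmol/L with a logged warning,
because the severity models were fitted on glucose truncated there.

Mandatory fields are age, sex, SBP, glucose, NIHSS and OTT. Optional
fields are imputed from a config of registry defaults: infarct sign
0.294 (the registry mean, expressible because `infarct_sign` accepts a
fraction), weight 80 kg, aspirin yes, clopidogrel no, hypertension no.
Diabetes and prior stroke, which the base instrument needs but which
are not part of the published imputation set, default to absent (0);
all defaults are overridable. `validate → impute → validate` is
idempotent.

## Calibration engine

`fit_logistic` wraps a Newton maximum-likelihood logistic fit
(statsmodels) with hard failure modes: one-class outcome vectors,
perfect separation and non-convergence raise rather than return
boundary estimates, and rank-deficient designs are rejected with the
collinear columns named. Convergence is accepted only with a small
score norm at the optimum.

`recalibrate` builds outcome ~ intercept + base prediction +
candidates and deletes candidates backward. The published account says
variables were deleted "stepwise" until removal no longer improved the
model, without naming a criterion; we default to the Wald p-value rule
(drop the largest p above α = 0.05, refit, repeat), because the
surrounding text describes retention in terms of statistical
significance, and a pure-noise candidate survives an AIC rule about
16 % of the time — inconsistent with the reported deletion of all
non-significant covariates. The AIC rule is available as
`criterion="aic"`. Ties break toward the larger p-value and then
lexicographically, so the procedure is deterministic. The
base-prediction term is never a deletion candidate: deleting it would
turn the procedure into a refit, which the published death model shows
as a separate, deliberate choice (its base-prediction weight is 0). A
`base_scale="logit"` option supports classical intercept/slope
recalibration, under which slope 1 with zero corrections is exactly the
identity; the shipped decision model uses the probability scale, which
is what the worked examples require.

The concordance statistic uses the rank-based Mann–Whitney form with
ties counted half; tests verify exact agreement with an exhaustive
O(n²) pairwise oracle. Calibration curves use equal-frequency bins by
predicted probability; duplicate quantile edges (e.g. constant
predictions) collapse into fewer effective bins so the curve remains
defined.

## Synthetic cohorts

The registry and trial-archive patient data behind the shipped
coefficients cannot be redistributed, so the calibration machinery is
validated on synthetic cohorts matched to the *published marginal
statistics* of the treated registry (the three-month-survivor column,
the only one with complete margins): age ~ N(67.8, 13.26²) truncated at
18; SBP ~ N(145.5, 21.8²) truncated at 200; male 58.6 %, diabetes
14.9 %, prior stroke 14.41 %, infarct sign 23.9 %, hypertension
60.36 %, CHF 4.5 %; glucose, NIHSS and OTT as log-normals matched to
the published median and IQR (σ = ln(q3/q1)/(2·z₀.₇₅)), truncated to
the model's valid ranges, NIHSS rounded to integers and clipped to
0–42. A preset for the untreated validation archive's margins is also
shipped (reusing the treated OTT margin, which the archive does not
report). Covariates are drawn independently — the tables publish no
joint structure — through a Gaussian-copula hook whose correlation
defaults to identity, so joint structure can be injected without
changing the margins.

Because the cohorts reproduce margins only, passing tests show that the
*machinery* (fitting, stepwise deletion, diagnostics) behaves correctly
at realistic sample sizes and covariate scales; they cannot show that
the shipped coefficients are correct for any real population, nor do
they emulate real-data features such as covariate correlation
(age–NIHSS, glucose–diabetes), measurement error, or informative
missingness.

Outcome simulation follows the model's own generative structure: death
~ Bernoulli(P(death)); among survivors, independence ~
Bernoulli(P(independent | survival)) of the assigned arm. The
round-trip experiment (`experiments.recovery_replicate`) simulates
50,000 treated patients from the shipped model, restricts to
survivors (~43,000), and recalibrates offering the true correction
covariates plus two pure-noise candidates (diabetes, prior stroke).
Recovered coefficients land within sampling error of the truth and the
noise candidates are deleted in ≥ 90 % of seeded replicates at this
cohort size, which was chosen to match the scale at which the shipped
corrections were originally estimated while keeping the full
20-replicate experiment under a minute.

## Numerical and interface choices

- Probabilities are stored at full precision; human-readable reports
  round to whole percent, matching how the published worked examples
  are printed (reproduction tests therefore compare rounded values
  within ±1 percentage point).
- Natural-frequency counts use largest-remainder (Hamilton) rounding so
  each arm's three states sum exactly to the chosen denominator;
  remainder ties break by state order, deterministically. The expected
  SICH count is rounded to the nearest unit separately.
- One-way sensitivity sweeps accept the numeric fields (age, SBP,
  glucose, NIHSS, OTT) over their validated ranges and hold everything
  else fixed, reproducing the published sensitivity pattern: death
  rises with NIHSS but is flat in OTT, while the treated-minus-
  untreated independence gap shrinks with OTT.
- All randomness flows through explicit seeds or numpy Generators;
  identical seeds give byte-identical cohorts, simulations and CLI
  output.

## Known limitations

- The three published discrepancies noted above (the prior-stroke
  worked example; two SICH class assignments) are reproduced as
  discrepancies, not patched.
- The positive prior-stroke main effect in the base instrument makes a
  prior stroke beneficial in the untreated arm; it is what the
  published untreated values require, and is documented rather than
  altered.
- Discrimination statistics reported for the original registry and
  archive populations (C ≈ 0.77–0.79) concern data this package cannot
  access; nothing here validates the shipped coefficients against real
  patients.
- The SICH risk table outside classes 5–7 is interpolated, not
  published; decisions sensitive to extreme point totals should treat
  those risks as indicative.
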