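"""The calibrated decision-analytic model (DAM).

The DAM turns the original instrument's trial-derived predictions into
three-state forecasts — independent (mRS <= 2), dependent (mRS 3-5),
dead (mRS 6) at three months — calibrated to routinely treated registry
patients.  Its structure treats death as a competing risk:

* ``dam_death`` — a registry refit, P(death) from age, NIHSS and glucose,
  shared by both arms (net treatment effect on death is taken as zero);
* ``dam_independence_given_survival`` — P(mRS <= 2 | survival): a
  recalibration of the instrument in which the instrument's own predicted
  probability (of the matching arm) enters as a covariate with weight
  3.3896 alongside registry-significant corrections (age, SBP, sex,
  NIHSS, age x NIHSS, infarct sign);
* ``dam_three_state`` — the unconditional combination
  P(independent) = P(independent | survival) * (1 - P(death)),
  with dependence as the residual, so the three states always sum to 1;
* ``predict_pair`` — both arms plus the treated-arm SICH risk and the net
  benefit (treated minus untreated probability of independence).

The correction coefficients are applied identically to the treated and
untreated predictions, preserving the instrument's net treatment effect;
the arm enters only through the base prediction.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model_core import (
    CoefficientSet,
    PatientProfile,
    PredictionPair,
    ProfileLike,
    ThreeStateDistribution,
    linear_predictor,
    logistic,
)
from .sich import SichScoreConfig, sich_probability
from .stpi import default_coefficients, stpi_good_outcome

__all__ = [
    "dam_death",
    "dam_independence_given_survival",
    "dam_three_state",
    "predict_pair",
]


def dam_death(profile: ProfileLike, coeffs: Optional[CoefficientSet] = None):
    """P(mRS 6 at three months); arm-invariant by construction."""
    if coeffs is None:
        coeffs = default_coefficients("dam_death_v1")
    return logistic(linear_predictor(profile, coeffs))


def dam_independence_given_survival(
    profile: ProfileLike,
    treated,
    coeffs: Optional[CoefficientSet] = None,
    stpi_coeffs: Optional[CoefficientSet] = None,
):
    """P(mRS <= 2 | survival to three months) for one treatment arm.

    The base prediction is the original instrument's P(mRS <= 1) for the
    *same* arm, entered on the probability scale.
    """
    if coeffs is None:
        coeffs = default_coefficients("dam_independence_v1")
    base = stpi_good_outcome(profile, treated, coeffs=stpi_coeffs)
    return logistic(linear_predictor(profile, coeffs, base_prediction=base))


def dam_three_state(
    profile: ProfileLike,
    treated,
    death_coeffs: Optional[CoefficientSet] = None,
    independence_coeffs: Optional[CoefficientSet] = None,
    stpi_coeffs: Optional[CoefficientSet] = None,
):
    """Unconditional three-state forecast for one arm.

    Returns a :class:`ThreeStateDistribution` for a single profile, or a
    dict of ndarrays for a cohort frame.
    """
    p_dead = dam_death(profile, coeffs=death_coeffs)
    p_ind_surv = dam_independence_given_survival(
        profile, treated, coeffs=independence_coeffs, stpi_coeffs=stpi_coeffs
    )
    p_independent = p_ind_surv * (1.0 - np.asarray(p_dead))
    p_dependent = 1.0 - p_independent - p_dead
    # residual construction: p_ind <= 1 - p_dead, so dependence cannot go
    # negative beyond rounding error
    assert np.all(np.asarray(p_dependent) >= -1e-12)
    if isinstance(profile, PatientProfile):
        return ThreeStateDistribution(
            p_independent=float(p_independent),
            p_dependent=float(p_dependent),
            p_dead=float(p_dead),
        )
    return {
        "p_independent": np.asarray(p_independent),
        "p_dependent": np.asarray(p_dependent),
        "p_dead": np.asarray(p_dead),
    }


def predict_pair(
    profile: PatientProfile,
    death_coeffs: Optional[CoefficientSet] = None,
    independence_coeffs: Optional[CoefficientSet] = None,
    stpi_coeffs: Optional[CoefficientSet] = None,
    sich_config: Optional[SichScoreConfig] = None,
) -> PredictionPair:
    """Full decision forecast: both arms, SICH risk, net benefit.

    The SICH risk is reported alongside the treated arm, never subtracted
    from it: haemorrhage deaths are already part of the treated death
    probability, so an explicit subtraction would double-count.
    """
    untreated = dam_three_state(
        profile,
        treated=0,
        death_coeffs=death_coeffs,
        independence_coeffs=independence_coeffs,
        stpi_coeffs=stpi_coeffs,
    )
    treated = dam_three_state(
        profile,
        treated=1,
        death_coeffs=death_coeffs,
        independence_coeffs=independence_coeffs,
        stpi_coeffs=stpi_coeffs,
    )
    return PredictionPair(
        untreated=untreated,
        treated=treated,
        p_sich=sich_probability(profile, config=sich_config),
        net_benefit=treated.p_independent - untreated.p_independent,
    )
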