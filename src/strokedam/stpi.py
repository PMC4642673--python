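"""The original Stroke-Thrombolytic Predictive Instrument (S-TPI).

Two pooled-trial logistic models:

* ``stpi_good_outcome`` — P(mRS <= 1 at three months), with a treatment
  main effect and treatment interactions with SBP, sex, prior stroke and
  onset-to-treatment time (OTT);
* ``stpi_severe_outcome`` — P(mRS 5-6 at three months) from age, NIHSS and
  serum glucose; thrombolysis showed no association with this outcome, so
  there is no treatment term.

The OTT main effect applies in both arms exactly as published; for an
untreated prediction OTT is read as onset-to-assessment time.
"""

from __future__ import annotations

from functools import lru_cache

from .model_core import (
    CoefficientSet,
    ProfileLike,
    linear_predictor,
    load_coefficient_set,
    logistic,
)

__all__ = ["stpi_good_outcome", "stpi_severe_outcome", "default_coefficients"]


@lru_cache(maxsize=None)
def default_coefficients(name: str) -> CoefficientSet:
    return load_coefficient_set(name)


def stpi_good_outcome(profile: ProfileLike, treated, coeffs: CoefficientSet = None):
    """P(mRS <= 1) under the original instrument, by treatment arm.

    ``treated`` is 0/1 (or an array when ``profile`` is a cohort frame);
    the treatment block contributes only when treated = 1.
    """
    if coeffs is None:
        coeffs = default_coefficients("stpi_good_outcome_v1")
    return logistic(linear_predictor(profile, coeffs, treated=treated))


def stpi_severe_outcome(profile: ProfileLike, coeffs: CoefficientSet = None):
    """P(mRS 5-6), identical in both arms; glucose enters truncated at 25."""
    if coeffs is None:
        coeffs = default_coefficients("stpi_severe_v1")
    return logistic(linear_predictor(profile, coeffs))
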