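"""Self-validation experiments: parameter recovery on synthetic cohorts.

Real registry data cannot be redistributed, so the recalibration engine
is validated by a round trip: draw a registry-like cohort, simulate
outcomes with the *shipped* decision model as the truth, recalibrate
from scratch, and compare the recovered correction coefficients with the
coefficients that generated the data.  Two pure-noise candidates
(diabetes and prior stroke, which carry no correction term in the truth)
are offered to the stepwise deletion and should be discarded.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, recalibrate
from .model_core import load_coefficient_set
from .synthetic_cohort import generate_cohort, simulate_outcomes

__all__ = [
    "NOISE_CANDIDATES",
    "true_correction_coefficients",
    "recovery_replicate",
    "check_recovery",
]

NOISE_CANDIDATES = ("diabetes", "prior_stroke")


def true_correction_coefficients() -> dict:
    """The shipped independence corrections, keyed by design-column name."""
    coeffs = load_coefficient_set("dam_independence_v1")
    truth = {"intercept": coeffs.intercept,
             "base_prediction": coeffs.base_prediction_coefficient}
    truth.update(coeffs.main_effects)
    for (a, b), value in coeffs.interactions:
        truth[f"{a}:{b}"] = value
    return truth


def recovery_replicate(
    seed: int,
    n: int = 50_000,
    alpha: float = 0.05,
    criterion: str = "pvalue",
) -> CalibrationResult:
    """One full round trip at cohort size ``n``.

    Simulates treated-arm outcomes from the shipped model, restricts to
    three-month survivors (the conditional independence model is defined
    on survivors) and recalibrates the base instrument's predictions
    against the simulated outcomes, offering the true correction
    covariates plus the two noise candidates.
    """
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(n, rng=rng)
    sim = simulate_outcomes(cohort, treated_fraction=1.0, rng=rng)
    surv = sim[sim["dead"] == 0.0]
    covariates = pd.DataFrame(
        {
            "age": surv["age"].to_numpy(),
            "sbp": surv["sbp"].to_numpy(),
            "male": surv["male"].to_numpy(),
            "nihss": surv["nihss"].to_numpy(),
            "age:nihss": surv["age"].to_numpy() * surv["nihss"].to_numpy(),
            "infarct_sign": surv["infarct_sign"].to_numpy(),
            "diabetes": surv["diabetes"].to_numpy(),
            "prior_stroke": surv["prior_stroke"].to_numpy(),
        }
    )
    return recalibrate(
        surv["base_prediction"].to_numpy(),
        covariates,
        surv["independent"].to_numpy(),
        alpha=alpha,
        criterion=criterion,
        base_scale="probability",
    )


def check_recovery(result: CalibrationResult, n_se: float = 3.0) -> dict:
    """Compare recovered coefficients with the generating truth.

    Returns per-coefficient dicts with the estimate, its standard error
    and the absolute z-deviation from truth; a true coefficient that was
    deleted appears with ``retained=False``.
    """
    truth = true_correction_coefficients()
    params = result.diagnostics["params"]
    bse = result.diagnostics["bse"]
    report = {}
    for name, true_value in truth.items():
        if name in params:
            z = abs(params[name] - true_value) / bse[name]
            report[name] = {"retained": True, "estimate": params[name],
                            "se": bse[name], "z_from_truth": z,
                            "within": bool(z <= n_se)}
        else:
            report[name] = {"retained": False, "within": False}
    return report
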