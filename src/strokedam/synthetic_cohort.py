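"""Synthetic registry-like cohorts for exercising the calibration engine.

No patient-level registry data can be redistributed, so the calibration
and validation machinery is tested on cohorts drawn to match the treated
registry's published marginal statistics: age and SBP as truncated
normals, skewed positives (glucose, NIHSS, OTT) as log-normals matched to
the published median and inter-quartile range, indicators as Bernoulli at
the published prevalence.

Margins only: covariates are drawn independently by default.  A Gaussian
copula hook accepts a correlation matrix for joint structure, but the
shipped presets use the identity (the published tables give no joint
information).  Outcomes are then simulated from a caller-specified "true"
model with the same competing-risk structure as the decision model:
death first, then independence among survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .dam import dam_death, dam_independence_given_survival
from .stpi import stpi_good_outcome
from .errors import ConfigurationError
from .model_core import (
    CoefficientSet,
    PatientProfile,
    load_bundled_json,
    validate_profile,
)

__all__ = [
    "PopulationConfig",
    "load_population_preset",
    "lognormal_from_median_iqr",
    "generate_cohort",
    "cohort_to_profiles",
    "simulate_outcomes",
]

_Z75 = stats.norm.ppf(0.75)  # 0.6745; half the IQR in SD units


def lognormal_from_median_iqr(median: float, q1: float, q3: float):
    """Two-parameter log-normal solve: mu = ln(median), sigma from the IQR ratio."""
    if not (0 < q1 < median < q3):
        raise ConfigurationError("need 0 < q1 < median < q3 for a log-normal match")
    mu = np.log(median)
    sigma = np.log(q3 / q1) / (2.0 * _Z75)
    return mu, sigma


@dataclass(frozen=True)
class PopulationConfig:
    """Per-covariate marginal specs plus an optional copula correlation."""

    margins: Mapping[str, Mapping]
    correlation: Optional[np.ndarray] = None
    name: str = "population"

    def __post_init__(self):
        for fname, spec in self.margins.items():
            if spec["dist"] not in ("truncnorm", "bernoulli", "lognorm_iqr"):
                raise ConfigurationError(
                    f"{fname}: unknown marginal family {spec['dist']!r}"
                )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationConfig":
        corr = d.get("correlation")
        return cls(
            margins={k: dict(v) for k, v in d["margins"].items()},
            correlation=None if corr is None else np.asarray(corr, dtype=float),
            name=d.get("name", "population"),
        )


@lru_cache(maxsize=None)
def load_population_preset(name: str = "sits-uk") -> PopulationConfig:
    filename = {
        "sits-uk": "population_sits_uk_v1.json",
        "vista": "population_vista_v1.json",
    }.get(name)
    if filename is None:
        raise ConfigurationError(f"unknown population preset {name!r}")
    return PopulationConfig.from_dict(load_bundled_json(filename))


def _marginal_ppf(spec: Mapping, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF of one truncated marginal, evaluated at uniforms u."""
    kind = spec["dist"]
    if kind == "bernoulli":
        return (u < spec["p"]).astype(float)
    if kind == "truncnorm":
        mean, sd = spec["mean"], spec["sd"]
        lo = spec.get("lo")
        hi = spec.get("hi")
        dist = stats.norm(loc=mean, scale=sd)
    else:  # lognorm_iqr
        mu, sigma = lognormal_from_median_iqr(spec["median"], spec["q1"], spec["q3"])
        lo = spec.get("lo")
        hi = spec.get("hi")
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    flo = 0.0 if lo is None else float(dist.cdf(lo))
    fhi = 1.0 if hi is None else float(dist.cdf(hi))
    if fhi - flo < 1e-6:
        raise ConfigurationError(
            f"truncation [{lo}, {hi}] excludes the mass of a {kind} marginal"
        )
    x = dist.ppf(flo + u * (fhi - flo))
    if spec.get("integer"):
        x = np.rint(x)
    if spec.get("clip"):
        x = np.clip(x, *spec["clip"])
    elif lo is not None or hi is not None:
        x = np.clip(x, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)
    return x


def generate_cohort(
    n: int,
    config: Optional[PopulationConfig] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw ``n`` synthetic patients; every row passes profile validation.

    Returns a covariate DataFrame (the same schema the calibration CLI
    reads); use :func:`cohort_to_profiles` for PatientProfile objects.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if config is None:
        config = load_population_preset("sits-uk")
    if rng is None:
        rng = np.random.default_rng(seed)
    fields = list(config.margins)
    k = len(fields)
    if config.correlation is not None:
        corr = np.asarray(config.correlation, dtype=float)
        if corr.shape != (k, k):
            raise ConfigurationError("correlation matrix shape mismatch")
        z = rng.multivariate_normal(np.zeros(k), corr, size=n)
        u = stats.norm.cdf(z)
    else:
        u = rng.random((n, k))
    data = {
        fname: _marginal_ppf(config.margins[fname], u[:, j])
        for j, fname in enumerate(fields)
    }
    return pd.DataFrame(data)


def cohort_to_profiles(frame: pd.DataFrame, validate: bool = True) -> List[PatientProfile]:
    profiles = [PatientProfile.from_dict(row) for row in frame.to_dict("records")]
    if validate:
        profiles = [validate_profile(p) for p in profiles]
    return profiles


def simulate_outcomes(
    cohort: pd.DataFrame,
    death_coeffs: Optional[CoefficientSet] = None,
    independence_coeffs: Optional[CoefficientSet] = None,
    stpi_coeffs: Optional[CoefficientSet] = None,
    treated_fraction: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate three-state outcomes from a specified true model.

    Per patient: assign arm Bernoulli(treated_fraction); draw death from
    the (arm-invariant) death model; among survivors draw independence
    from the conditional independence model of the assigned arm.  The
    returned frame carries the covariates plus ``treated``, the true
    event probabilities, the base-model prediction of the assigned arm,
    the drawn indicators and an ``mrs_class`` label.
    """
    if not (0.0 <= treated_fraction <= 1.0):
        raise ValueError("treated_fraction must lie in [0,1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(cohort)
    treated = (rng.random(n) < treated_fraction).astype(float)
    p_dead = np.asarray(dam_death(cohort, coeffs=death_coeffs), dtype=float)
    p_ind_surv = np.asarray(
        dam_independence_given_survival(
            cohort, treated, coeffs=independence_coeffs, stpi_coeffs=stpi_coeffs
        ),
        dtype=float,
    )
    base_prediction = np.asarray(stpi_good_outcome(cohort, treated, coeffs=stpi_coeffs))
    dead = (rng.random(n) < p_dead).astype(float)
    independent = np.where(dead == 1.0, 0.0, (rng.random(n) < p_ind_surv).astype(float))
    mrs_class = np.where(
        dead == 1.0, "dead", np.where(independent == 1.0, "independent", "dependent")
    )
    out = cohort.copy()
    out["treated"] = treated
    out["p_dead"] = p_dead
    out["p_independent_given_survival"] = p_ind_surv
    out["base_prediction"] = base_prediction
    out["dead"] = dead
    out["independent"] = independent
    out["mrs_class"] = mrs_class
    return out
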