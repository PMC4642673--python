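"""Domain types and the shared logistic machinery.

Every model in the package (the original thrombolytic predictive
instrument, its recalibrated successor and the mortality model) is a
logistic regression over a patient's covariate vector.  This module holds
the patient record type, the serialisable coefficient-set type, the
inverse-logit link and the linear-predictor evaluator they all share, plus
the validation and imputation rules applied before any prediction.

Covariate coding conventions
----------------------------
* indicators are 1 = yes / male, 0 = no / female;
* ``infarct_sign`` may be a fraction in [0, 1] so that a population-mean
  imputation (0.294, the registry prevalence among treated survivors) is
  expressible; an observed scan is coded 0 or 1;
* serum glucose above 25 mmol/L is truncated to 25, matching the range the
  severity models were fitted on;
* the derived product age x NIHSS appears as the interaction
  ``("age", "nihss")`` in coefficient sets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import special

from .errors import ConfigurationError, MissingDataError, RangeViolationError

logger = logging.getLogger(__name__)

#: Fields that every prediction needs; absence is an error, never imputed.
MANDATORY_FIELDS = ("age", "male", "sbp", "glucose", "nihss", "ott")

#: Fields the shipped imputation config can fill from registry statistics.
OPTIONAL_FIELDS = (
    "diabetes",
    "prior_stroke",
    "infarct_sign",
    "chf",
    "weight_kg",
    "aspirin",
    "clopidogrel",
    "hypertension",
)

_INDICATOR_FIELDS = (
    "male",
    "diabetes",
    "prior_stroke",
    "chf",
    "aspirin",
    "clopidogrel",
    "hypertension",
)

KNOWN_COVARIATES = frozenset(MANDATORY_FIELDS) | frozenset(OPTIONAL_FIELDS)

GLUCOSE_TRUNCATION = 25.0


@dataclass(frozen=True)
class PatientProfile:
    """One patient's covariates.

    Numeric units: age in years, sbp in mmHg, glucose in mmol/L, nihss on
    the 0-42 stroke-severity scale, ott (onset-to-treatment time) in
    minutes, weight_kg in kilograms.  ``None`` marks a missing value.
    """

    age: Optional[float] = None
    male: Optional[float] = None
    diabetes: Optional[float] = None
    prior_stroke: Optional[float] = None
    sbp: Optional[float] = None
    glucose: Optional[float] = None
    nihss: Optional[float] = None
    ott: Optional[float] = None
    infarct_sign: Optional[float] = None
    chf: Optional[float] = None
    weight_kg: Optional[float] = None
    aspirin: Optional[float] = None
    clopidogrel: Optional[float] = None
    hypertension: Optional[float] = None

    def replace(self, **changes) -> "PatientProfile":
        return dataclasses.replace(self, **changes)

    def require(self, field: str) -> float:
        value = getattr(self, field)
        if value is None:
            raise MissingDataError(field)
        return float(value)

    def to_dict(self, drop_missing: bool = True) -> dict:
        d = dataclasses.asdict(self)
        if drop_missing:
            d = {k: v for k, v in d.items() if v is not None}
        return d

    @classmethod
    def from_dict(cls, record: Mapping) -> "PatientProfile":
        known = {f.name for f in dataclasses.fields(cls)}
        clean = {}
        for key, value in record.items():
            if key not in known:
                continue
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            if value == "" or value == "NA":
                continue
            clean[key] = float(value)
        return cls(**clean)


@dataclass(frozen=True)
class TreatmentBlock:
    """Treatment main effect plus treatment x covariate interactions."""

    treatment: float
    interactions: Mapping[str, float] = dataclasses.field(default_factory=dict)


@dataclass(frozen=True)
class CoefficientSet:
    """A named logistic model on patient covariates.

    ``base_prediction_coefficient`` is the weight a recalibration model
    places on an upstream model's predicted probability.  The shipped
    recalibration enters that prediction on the probability scale
    (``base_prediction_scale="probability"``); ``"logit"`` selects the
    intercept/slope-style recalibration of the logit instead, under which
    slope 1 with zero corrections is the exact identity.
    """

    name: str
    intercept: float
    main_effects: Mapping[str, float] = dataclasses.field(default_factory=dict)
    interactions: Sequence[tuple] = dataclasses.field(default_factory=tuple)
    treatment_block: Optional[TreatmentBlock] = None
    base_prediction_coefficient: Optional[float] = None
    base_prediction_scale: str = "probability"

    def __post_init__(self):
        if self.base_prediction_scale not in ("probability", "logit"):
            raise ConfigurationError(
                f"unknown base prediction scale {self.base_prediction_scale!r}"
            )
        for name in self.covariate_names():
            if name not in KNOWN_COVARIATES:
                raise ConfigurationError(
                    f"coefficient set {self.name!r} references unknown "
                    f"covariate {name!r}"
                )

    def covariate_names(self) -> set:
        names = set(self.main_effects)
        for pair, _ in self.interactions:
            names.update(pair)
        if self.treatment_block is not None:
            names.update(self.treatment_block.interactions)
        return names

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "intercept": self.intercept,
            "main_effects": dict(self.main_effects),
            "interactions": [[list(pair), coef] for pair, coef in self.interactions],
        }
        if self.treatment_block is not None:
            d["treatment_block"] = {
                "treatment": self.treatment_block.treatment,
                "interactions": dict(self.treatment_block.interactions),
            }
        else:
            d["treatment_block"] = None
        d["base_prediction_coefficient"] = self.base_prediction_coefficient
        d["base_prediction_scale"] = self.base_prediction_scale
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientSet":
        block = d.get("treatment_block")
        if block is not None:
            block = TreatmentBlock(
                treatment=float(block["treatment"]),
                interactions={k: float(v) for k, v in block.get("interactions", {}).items()},
            )
        return cls(
            name=d["name"],
            intercept=float(d["intercept"]),
            main_effects={k: float(v) for k, v in d.get("main_effects", {}).items()},
            interactions=tuple(
                (tuple(pair), float(coef)) for pair, coef in d.get("interactions", [])
            ),
            treatment_block=block,
            base_prediction_coefficient=(
                None
                if d.get("base_prediction_coefficient") is None
                else float(d["base_prediction_coefficient"])
            ),
            base_prediction_scale=d.get("base_prediction_scale", "probability"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ThreeStateDistribution:
    """Probabilities over {independent (mRS<=2), dependent (mRS 3-5), dead}."""

    p_independent: float
    p_dependent: float
    p_dead: float

    def __post_init__(self):
        for name, p in self.as_dict().items():
            if not (-1e-12 <= p <= 1 + 1e-12):
                raise ValueError(f"{name}={p} outside [0,1]")
        total = self.p_independent + self.p_dependent + self.p_dead
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"three-state probabilities sum to {total}, not 1")

    def as_dict(self) -> dict:
        return {
            "p_independent": self.p_independent,
            "p_dependent": self.p_dependent,
            "p_dead": self.p_dead,
        }

    def as_tuple(self) -> tuple:
        return (self.p_independent, self.p_dependent, self.p_dead)


@dataclass(frozen=True)
class PredictionPair:
    """Treated and untreated three-state forecasts for one patient.

    ``p_sich`` is the symptomatic intracerebral haemorrhage risk of the
    treated arm only (haemorrhage in untreated patients is deliberately not
    modelled).  ``net_benefit`` is the absolute gain in probability of
    independence from treatment.
    """

    untreated: ThreeStateDistribution
    treated: ThreeStateDistribution
    p_sich: float
    net_benefit: float

    def __post_init__(self):
        if not (0.0 <= self.p_sich <= 1.0):
            raise ValueError(f"p_sich={self.p_sich} outside [0,1]")
        if not (-1.0 <= self.net_benefit <= 1.0):
            raise ValueError(f"net_benefit={self.net_benefit} outside [-1,1]")

    def as_dict(self) -> dict:
        return {
            "untreated": self.untreated.as_dict(),
            "treated": self.treated.as_dict(),
            "p_sich": self.p_sich,
            "net_benefit": self.net_benefit,
        }


# ---------------------------------------------------------------------------
# Link and linear predictor


def logistic(eta):
    """Inverse-logit link, 1 / (1 + exp(-eta)).

    Accepts a scalar or array; rejects non-finite linear predictors.
    """
    arr = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite linear predictor")
    out = special.expit(arr)
    if np.isscalar(eta) or arr.ndim == 0:
        return float(out)
    return out


ProfileLike = Union[PatientProfile, pd.DataFrame]


def _resolve(profile: ProfileLike, name: str):
    """Covariate value(s) for one named field, scalar or column."""
    if isinstance(profile, pd.DataFrame):
        if name not in profile.columns:
            raise ConfigurationError(f"cohort frame lacks covariate column {name!r}")
        values = profile[name].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise MissingDataError(name)
        return values
    if not hasattr(profile, name):
        raise ConfigurationError(f"profile has no covariate field {name!r}")
    return profile.require(name)


def linear_predictor(
    profile: ProfileLike,
    coeffs: CoefficientSet,
    treated=0,
    base_prediction=None,
):
    """Evaluate a coefficient set's linear predictor.

    eta = intercept + sum(main effects) + sum(interaction products)
        + treated * (treatment main effect + treatment interactions)
        + base_prediction_coefficient * base_prediction.

    ``profile`` may be a single PatientProfile (returns a float) or a
    cohort DataFrame with covariate columns (returns an ndarray);
    ``treated`` and ``base_prediction`` broadcast accordingly.
    """
    eta = coeffs.intercept + 0.0
    for name, coef in coeffs.main_effects.items():
        eta = eta + coef * _resolve(profile, name)
    for (a, b), coef in coeffs.interactions:
        eta = eta + coef * _resolve(profile, a) * _resolve(profile, b)
    if coeffs.treatment_block is not None:
        block = coeffs.treatment_block
        block_eta = block.treatment + 0.0
        for name, coef in block.interactions.items():
            block_eta = block_eta + coef * _resolve(profile, name)
        eta = eta + np.asarray(treated, dtype=float) * block_eta
    if coeffs.base_prediction_coefficient is not None:
        if base_prediction is None:
            raise ConfigurationError(
                f"coefficient set {coeffs.name!r} requires a base prediction"
            )
        base = np.asarray(base_prediction, dtype=float)
        if coeffs.base_prediction_scale == "logit":
            base = np.log(base / (1.0 - base))
        eta = eta + coeffs.base_prediction_coefficient * base
    if isinstance(profile, PatientProfile) and np.ndim(eta) == 0:
        return float(eta)
    return np.asarray(eta, dtype=float)


# ---------------------------------------------------------------------------
# Validation and imputation


def validate_profile(profile: PatientProfile) -> PatientProfile:
    """Enforce the model's supported covariate ranges.

    Glucose above 25 mmol/L is truncated to 25 (the severity models were
    fitted with glucose truncated there); every other violation is raised
    as a :class:`RangeViolationError`, mirroring the eligibility
    restrictions of the calibration cohort rather than silently clamping.
    """
    p = profile
    if p.age is not None and p.age < 18:
        raise RangeViolationError("age", p.age, "model requires age >= 18 years")
    if p.sbp is not None and p.sbp > 200:
        raise RangeViolationError("sbp", p.sbp, "model requires SBP <= 200 mmHg")
    if p.sbp is not None and p.sbp <= 0:
        raise RangeViolationError("sbp", p.sbp, "SBP must be positive")
    if p.ott is not None and not (0 <= p.ott <= 270):
        raise RangeViolationError("ott", p.ott, "model requires 0 <= OTT <= 270 min")
    if p.nihss is not None and not (0 <= p.nihss <= 42):
        raise RangeViolationError("nihss", p.nihss, "NIHSS scale runs 0-42")
    if p.glucose is not None:
        if p.glucose <= 0:
            raise RangeViolationError("glucose", p.glucose, "glucose must be positive")
        if p.glucose > GLUCOSE_TRUNCATION:
            logger.warning(
                "glucose %.2f mmol/L truncated to %.0f", p.glucose, GLUCOSE_TRUNCATION
            )
            p = p.replace(glucose=GLUCOSE_TRUNCATION)
    if p.infarct_sign is not None and not (0 <= p.infarct_sign <= 1):
        raise RangeViolationError(
            "infarct_sign", p.infarct_sign, "must lie in [0,1] (fraction or indicator)"
        )
    if p.weight_kg is not None and p.weight_kg <= 0:
        raise RangeViolationError("weight_kg", p.weight_kg, "weight must be positive")
    for field in _INDICATOR_FIELDS:
        value = getattr(p, field)
        if value is not None and value not in (0, 1, 0.0, 1.0):
            raise RangeViolationError(field, value, "indicator must be 0 or 1")
    return p


def default_imputation_config() -> dict:
    """Registry-derived defaults for optional covariates."""
    return dict(load_bundled_json("imputation_v1.json")["defaults"])


def impute_missing(
    profile: PatientProfile, imputation_config: Optional[Mapping] = None
) -> PatientProfile:
    """Fill absent optional covariates with configured population defaults.

    Mandatory covariates (age, sex, SBP, glucose, NIHSS, OTT) are never
    imputed; their absence raises :class:`MissingDataError`.
    """
    defaults = (
        default_imputation_config() if imputation_config is None else imputation_config
    )
    for field in MANDATORY_FIELDS:
        if getattr(profile, field) is None:
            raise MissingDataError(field)
    changes = {}
    for field in OPTIONAL_FIELDS:
        if getattr(profile, field) is None:
            if field not in defaults:
                raise ConfigurationError(f"no imputation default for field {field!r}")
            changes[field] = float(defaults[field])
    return profile.replace(**changes) if changes else profile


def prepare_profile(
    profile: PatientProfile, imputation_config: Optional[Mapping] = None
) -> PatientProfile:
    """validate -> impute -> validate; idempotent convenience wrapper."""
    return validate_profile(impute_missing(validate_profile(profile), imputation_config))


# ---------------------------------------------------------------------------
# Bundled coefficient configs


def load_bundled_json(filename: str) -> dict:
    ref = resources.files("strokedam.configs").joinpath(filename)
    with ref.open() as fh:
        return json.load(fh)


def available_coefficient_sets() -> list:
    names = []
    for entry in resources.files("strokedam.configs").iterdir():
        if entry.name.endswith(".json"):
            data = json.loads(entry.read_text())
            if "intercept" in data:
                names.append(data["name"])
    return sorted(names)


def load_coefficient_set(name: str) -> CoefficientSet:
    """Load a shipped coefficient set by name (e.g. ``stpi_good_outcome_v1``)."""
    try:
        data = load_bundled_json(f"{name}.json")
    except FileNotFoundError:
        raise ConfigurationError(
            f"unknown coefficient set {name!r}; available: "
            f"{', '.join(available_coefficient_sets())}"
        ) from None
    return CoefficientSet.from_dict(data)
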