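"""Model-building machinery: logistic fits, recalibration, diagnostics.

Recalibration here means refitting the *relationship* between an existing
model's predictions and outcomes observed in a new population: a logistic
regression of the observed outcome on the original model's predicted
probability plus candidate correction covariates, followed by backward
stepwise deletion.  Any correction term that survives deletion marks a
covariate along which the original model under- or over-predicts in the
new population.

The base-prediction term is protected from deletion — it is the anchor
that makes the procedure a recalibration rather than a refit.  Two
stopping rules are provided: Wald p-value thresholding (default, matching
the significance language used when the shipped corrections were built)
and AIC improvement.

Diagnostics: a concordance statistic (ties counted half) and
equal-frequency calibration curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

from .errors import ConfigurationError, SeparationError, UndefinedStatisticError
from .model_core import (
    CoefficientSet,
    PatientProfile,
    linear_predictor,
    logistic,
)
from .stpi import stpi_good_outcome

__all__ = [
    "LogisticFit",
    "CalibrationResult",
    "CalibrationCurve",
    "fit_logistic",
    "recalibrate",
    "apply_corrections_both_arms",
    "c_statistic",
    "calibration_curve",
]

_GRADIENT_TOL = 1e-8


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with its observed-information covariance."""

    params: pd.Series
    cov: pd.DataFrame
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    nobs: int

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        return logistic(design[self.params.index].to_numpy(float) @ self.params.to_numpy())


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a recalibration: retained corrections plus diagnostics."""

    corrections: CoefficientSet
    dropped_covariates: Sequence[str]
    diagnostics: Mapping
    c_statistic_before: float
    c_statistic_after: float


@dataclass(frozen=True)
class CalibrationCurve:
    """Equal-frequency bins of (mean predicted, observed fraction, count)."""

    bins: Sequence[tuple]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.bins, columns=["mean_predicted", "observed_fraction", "count"]
        )


def _as_design(design) -> pd.DataFrame:
    if isinstance(design, pd.DataFrame):
        return design.astype(float)
    arr = np.asarray(design, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def fit_logistic(design, outcomes) -> LogisticFit:
    """Fit a logistic regression by Newton-Raphson IRLS.

    ``design`` must already contain the intercept column (constant 1).
    Degenerate inputs fail loudly: a one-class outcome vector or perfect
    separation raises :class:`SeparationError`; a rank-deficient design
    raises :class:`ConfigurationError` naming the collinear columns.
    """
    X = _as_design(design)
    y = np.asarray(outcomes, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome lengths differ")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError(
            "all outcomes identical: logistic MLE lies on the boundary"
        )
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    constant = X.nunique(axis=0) == 1
    nonconst_constant = [c for c in X.columns[constant] if X[c].iloc[0] != 1.0]
    if nonconst_constant:
        raise ConfigurationError(
            f"zero-variance non-intercept columns: {nonconst_constant}"
        )
    if constant.sum() > 1:
        raise ConfigurationError("multiple constant columns in design")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns involved via QR pivoting
        _, r = np.linalg.qr(X.to_numpy())
        small = np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        guilty = list(X.columns[small]) or list(X.columns)
        raise ConfigurationError(f"rank-deficient design; collinear columns: {guilty}")

    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            # statsmodels downgrades separation to a warning; treat it as fatal
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(disp=0, method="newton", maxiter=200, tol=1e-12)
    except Exception as exc:  # separation / singular hessian / non-convergence
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    grad = model.score(res.params.to_numpy())
    if not np.all(np.isfinite(grad)) or np.linalg.norm(grad) > _GRADIENT_TOL * max(
        1.0, len(y)
    ):
        raise SeparationError(
            "logistic fit did not converge (possible quasi-separation)"
        )
    return LogisticFit(
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        bse=res.bse,
        pvalues=res.pvalues,
        llf=float(res.llf),
        aic=float(res.aic),
        nobs=int(res.nobs),
    )


_BASE_COLUMN = "base_prediction"
_INTERCEPT_COLUMN = "intercept"


def _build_design(base_predictions, covariates: pd.DataFrame, base_scale: str):
    base = np.asarray(base_predictions, dtype=float)
    if np.any((base <= 0.0) | (base >= 1.0)):
        raise ValueError("base predictions must lie strictly in (0,1)")
    if base_scale == "logit":
        base_col = np.log(base / (1.0 - base))
    elif base_scale == "probability":
        base_col = base
    else:
        raise ConfigurationError(f"unknown base scale {base_scale!r}")
    design = pd.DataFrame({_INTERCEPT_COLUMN: np.ones_like(base_col)})
    design[_BASE_COLUMN] = base_col
    for col in covariates.columns:
        design[col] = covariates[col].to_numpy(dtype=float)
    return design


def _corrections_from_params(params: pd.Series, base_scale: str) -> CoefficientSet:
    main, inter = {}, []
    for name, coef in params.items():
        if name in (_INTERCEPT_COLUMN, _BASE_COLUMN):
            continue
        if ":" in name:
            a, b = name.split(":", 1)
            inter.append(((a, b), float(coef)))
        else:
            main[name] = float(coef)
    return CoefficientSet(
        name="recalibration",
        intercept=float(params[_INTERCEPT_COLUMN]),
        main_effects=main,
        interactions=tuple(inter),
        base_prediction_coefficient=float(params[_BASE_COLUMN]),
        base_prediction_scale=base_scale,
    )


def recalibrate(
    base_predictions,
    covariates: pd.DataFrame,
    outcomes,
    alpha: float = 0.05,
    criterion: str = "pvalue",
    base_scale: str = "probability",
) -> CalibrationResult:
    """Recalibrate an existing model against observed outcomes.

    Fits outcome ~ intercept + base prediction + candidate corrections,
    then deletes candidates backward.  Under ``criterion="pvalue"`` the
    candidate with the largest Wald p-value above ``alpha`` is removed
    each round; under ``criterion="aic"`` the deletion that most lowers
    the AIC is taken while any deletion lowers it.  Ties break toward the
    larger p-value, then lexicographically, so the procedure is
    deterministic.  The base-prediction term is never a deletion
    candidate.

    Interaction candidates are passed as product columns named
    ``"a:b"`` (e.g. ``"age:nihss"``); they re-emerge as interaction terms
    in the returned :class:`~strokedam.model_core.CoefficientSet`.
    """
    if criterion not in ("pvalue", "aic"):
        raise ConfigurationError(f"unknown stepwise criterion {criterion!r}")
    design = _build_design(base_predictions, covariates, base_scale)
    y = np.asarray(outcomes, dtype=float)
    candidates = [c for c in design.columns if c not in (_INTERCEPT_COLUMN, _BASE_COLUMN)]
    dropped: list = []
    fit = fit_logistic(design, y)
    while candidates:
        if criterion == "pvalue":
            pv = fit.pvalues[candidates]
            worst = pv.max()
            if worst <= alpha:
                break
            ties = sorted(pv.index[pv >= worst - 1e-12])
            victim = ties[0]
        else:
            improvements = {}
            for cand in candidates:
                trial = fit_logistic(design.drop(columns=[cand]), y)
                improvements[cand] = fit.aic - trial.aic
            best = max(improvements.values())
            if best <= 0.0:
                break
            tied = [c for c, v in improvements.items() if v >= best - 1e-9]
            tied.sort(key=lambda c: (-fit.pvalues[c], c))
            victim = tied[0]
        design = design.drop(columns=[victim])
        candidates.remove(victim)
        dropped.append(victim)
        fit = fit_logistic(design, y)

    corrections = _corrections_from_params(fit.params, base_scale)
    return CalibrationResult(
        corrections=corrections,
        dropped_covariates=tuple(dropped),
        diagnostics={
            "llf": fit.llf,
            "aic": fit.aic,
            "nobs": fit.nobs,
            "params": fit.params.to_dict(),
            "bse": fit.bse.to_dict(),
            "pvalues": fit.pvalues.to_dict(),
            "criterion": criterion,
            "alpha": alpha,
        },
        c_statistic_before=c_statistic(np.asarray(base_predictions, float), y),
        c_statistic_after=c_statistic(fit.predict(design), y),
    )


def apply_corrections_both_arms(
    corrections: Union[CalibrationResult, CoefficientSet],
    profile: PatientProfile,
    stpi_coeffs: Optional[CoefficientSet] = None,
):
    """Evaluate one set of corrections with arm-specific base predictions.

    The corrections were fitted on treated-arm data but are applied to
    both arms, so the treatment effect carried by the base model is
    preserved; the arm enters only through the base prediction.
    """
    coeffs = (
        corrections.corrections
        if isinstance(corrections, CalibrationResult)
        else corrections
    )
    out = []
    for arm in (0, 1):
        base = stpi_good_outcome(profile, arm, coeffs=stpi_coeffs)
        out.append(logistic(linear_predictor(profile, coeffs, base_prediction=base)))
    return tuple(out)


def c_statistic(predictions, outcomes) -> float:
    """Concordance probability (area under the ROC curve), ties at half.

    Rank-based Mann-Whitney form; identical to exhaustive pairwise
    comparison of every event/non-event pair.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError(
            "concordance undefined without both an event and a non-event"
        )
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def calibration_curve(predictions, outcomes, n_bins: int = 10) -> CalibrationCurve:
    """Equal-frequency calibration curve.

    Bins predictions by quantile; duplicate quantile edges (e.g. constant
    predictions) collapse into fewer effective bins.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least two bins")
    if n_bins > p.size:
        raise ValueError("more bins than observations")
    edges = np.unique(np.quantile(p, np.linspace(0.0, 1.0, n_bins + 1)))
    idx = np.searchsorted(edges[1:-1], p, side="right") if edges.size > 2 else np.zeros(
        p.size, dtype=int
    )
    bins = []
    for b in range(idx.max() + 1):
        mask = idx == b
        if mask.any():
            bins.append((float(p[mask].mean()), float(y[mask].mean()), int(mask.sum())))
    return CalibrationCurve(bins=tuple(bins))
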