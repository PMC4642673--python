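"""Logistic fitting, stepwise recalibration and diagnostics.

The concordance statistic is checked against an exhaustive O(n^2)
pairwise oracle; parameter recovery is checked on data simulated from a
known truth.
"""

import numpy as np
import pandas as pd
import pytest

from strokedam import (
    CoefficientSet,
    ConfigurationError,
    SeparationError,
    UndefinedStatisticError,
    apply_corrections_both_arms,
    c_statistic,
    calibration_curve,
    fit_logistic,
    load_coefficient_set,
    recalibrate,
)
from strokedam.calibration import CalibrationResult
from strokedam.model_core import logistic
from strokedam.synthetic_cohort import generate_cohort, simulate_outcomes

from conftest import TABLE3, table3_profile


def brute_force_concordance(predictions, outcomes):
    """Oracle: average over all event/non-event pairs, ties worth half."""
    p = np.asarray(predictions, float)
    y = np.asarray(outcomes)
    ev, non = p[y == 1], p[y == 0]
    diff = ev[:, None] - non[None, :]
    return float(((diff > 0) + 0.5 * (diff == 0)).mean())


class TestFitLogistic:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        n = 50_000
        x = rng.normal(size=n)
        y = (rng.random(n) < logistic(0.5 + 1.2 * x)).astype(float)
        fit = fit_logistic(pd.DataFrame({"intercept": np.ones(n), "x": x}), y)
        for name, truth in (("intercept", 0.5), ("x", 1.2)):
            assert abs(fit.params[name] - truth) < 3 * fit.bse[name]

    def test_intercept_only_half_events(self):
        rng = np.random.default_rng(3)
        y = (rng.random(20_000) < 0.5).astype(float)
        fit = fit_logistic(np.ones((20_000, 1)), y)
        assert abs(fit.params.iloc[0]) < 3 * fit.bse.iloc[0]

    def test_one_class_outcomes_rejected(self):
        with pytest.raises(SeparationError):
            fit_logistic(np.ones((50, 1)), np.zeros(50))

    def test_perfect_separation_rejected(self):
        x = np.arange(40, dtype=float)
        y = (x >= 20).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(pd.DataFrame({"intercept": np.ones(40), "x": x}), y)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        design = pd.DataFrame({"intercept": 1.0, "x": x, "x2": 2 * x})
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(ConfigurationError, match="collinear"):
            fit_logistic(design, y)

    def test_zero_variance_column_rejected(self):
        rng = np.random.default_rng(0)
        design = pd.DataFrame({"intercept": np.ones(100), "flat": np.full(100, 2.0)})
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(ConfigurationError, match="flat"):
            fit_logistic(design, y)


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert c_statistic([0.5, 0.5], [1, 0]) == 0.5

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = np.round(rng.random(200), 2)  # rounding forces ties
            y = (rng.random(200) < 0.4).astype(int)
            assert c_statistic(p, y) == pytest.approx(
                brute_force_concordance(p, y), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        p = rng.random(300)
        y = (rng.random(300) < 0.5).astype(int)
        assert c_statistic(np.exp(3 * p), y) == pytest.approx(
            c_statistic(p, y), abs=1e-12
        )

    def test_undefined_for_one_class(self):
        with pytest.raises(UndefinedStatisticError):
            c_statistic([0.1, 0.9], [1, 1])


class TestCalibrationCurve:
    def test_well_calibrated_data(self):
        rng = np.random.default_rng(2)
        p = rng.beta(2, 2, size=100_000)
        y = (rng.random(100_000) < p).astype(float)
        curve = calibration_curve(p, y, n_bins=10)
        assert max(abs(m - o) for m, o, _ in curve.bins) < 0.02

    def test_constant_predictions_single_bin(self):
        y = np.array([0, 1, 1, 0, 1])
        curve = calibration_curve(np.full(5, 0.3), y, n_bins=2)
        assert len(curve.bins) == 1
        assert curve.bins[0][1] == pytest.approx(0.6)

    def test_counts_partition_the_cohort(self):
        rng = np.random.default_rng(4)
        p = rng.random(997)
        y = (rng.random(997) < 0.5).astype(float)
        curve = calibration_curve(p, y, n_bins=7)
        assert sum(c for _, _, c in curve.bins) == 997

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([0.1, 0.9], [0, 1], n_bins=5)


def _simulated_cohort(n, seed, nihss_correction=-0.14):
    """Outcomes drawn from base predictions distorted only along NIHSS."""
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(n, seed=rng.integers(2**31))
    from strokedam.stpi import stpi_good_outcome

    base = np.asarray(stpi_good_outcome(cohort, np.ones(n)))
    eta = np.log(base / (1 - base)) + nihss_correction * (
        cohort["nihss"].to_numpy() - cohort["nihss"].mean()
    )
    y = (rng.random(n) < logistic(eta)).astype(float)
    covs = cohort[["nihss", "diabetes", "prior_stroke"]].copy()
    return base, covs, y


class TestRecalibrate:
    def test_true_miscalibration_retained_noise_dropped(self):
        base, covs, y = _simulated_cohort(20_000, seed=0)
        result = recalibrate(base, covs, y, base_scale="logit")
        assert "nihss" in result.corrections.main_effects
        assert "diabetes" in result.dropped_covariates
        assert "prior_stroke" in result.dropped_covariates
        assert result.corrections.main_effects["nihss"] == pytest.approx(-0.14, abs=0.04)

    def test_null_calibration_drops_everything(self):
        """Outcomes generated exactly from the base predictions: all
        candidates are noise; the base slope approximates identity."""
        rng = np.random.default_rng(1)
        n = 20_000
        base = rng.beta(2, 3, size=n).clip(0.01, 0.99)
        y = (rng.random(n) < base).astype(float)
        covs = pd.DataFrame({"diabetes": (rng.random(n) < 0.2).astype(float),
                             "prior_stroke": (rng.random(n) < 0.15).astype(float)})
        result = recalibrate(base, covs, y, base_scale="logit")
        assert set(result.dropped_covariates) == {"diabetes", "prior_stroke"}
        assert result.corrections.base_prediction_coefficient == pytest.approx(1.0, abs=0.1)
        assert abs(result.corrections.intercept) < 0.1

    def test_retain_everything_configuration(self):
        base, covs, y = _simulated_cohort(5_000, seed=2)
        result = recalibrate(base, covs, y, alpha=1.0, base_scale="logit")
        assert result.dropped_covariates == ()
        assert set(result.corrections.main_effects) == set(covs.columns)

    def test_every_retained_coefficient_is_significant(self):
        base, covs, y = _simulated_cohort(20_000, seed=3)
        result = recalibrate(base, covs, y, alpha=0.05, base_scale="logit")
        for name in result.corrections.main_effects:
            assert result.diagnostics["pvalues"][name] < 0.05

    def test_deterministic_given_data(self):
        base, covs, y = _simulated_cohort(5_000, seed=4)
        r1 = recalibrate(base, covs, y, base_scale="logit")
        r2 = recalibrate(base, covs, y, base_scale="logit")
        assert r1.dropped_covariates == r2.dropped_covariates
        assert r1.corrections == r2.corrections

    def test_aic_criterion_also_converges(self):
        base, covs, y = _simulated_cohort(10_000, seed=5)
        result = recalibrate(base, covs, y, criterion="aic", base_scale="logit")
        assert "nihss" in result.corrections.main_effects

    def test_interaction_column_round_trips(self):
        rng = np.random.default_rng(6)
        n = 10_000
        cohort = generate_cohort(n, seed=60)
        from strokedam.stpi import stpi_good_outcome

        base = np.asarray(stpi_good_outcome(cohort, np.ones(n)))
        y = (rng.random(n) < base).astype(float)
        covs = pd.DataFrame(
            {"age:nihss": cohort["age"].to_numpy() * cohort["nihss"].to_numpy()}
        )
        result = recalibrate(base, covs, y, alpha=1.0, base_scale="logit")
        assert result.corrections.interactions[0][0] == ("age", "nihss")


class TestApplyCorrections:
    def test_identity_configuration_reproduces_base(self, table3_profiles):
        identity = CoefficientSet(
            name="identity", intercept=0.0, base_prediction_coefficient=1.0,
            base_prediction_scale="logit",
        )
        from strokedam.stpi import stpi_good_outcome

        for profile in table3_profiles:
            untreated, treated = apply_corrections_both_arms(identity, profile)
            assert untreated == pytest.approx(stpi_good_outcome(profile, 0), abs=1e-9)
            assert treated == pytest.approx(stpi_good_outcome(profile, 1), abs=1e-9)

    def test_shipped_corrections_row1_conditionals(self):
        coeffs = load_coefficient_set("dam_independence_v1")
        untreated, treated = apply_corrections_both_arms(coeffs, table3_profile(TABLE3[0]))
        assert untreated == pytest.approx(0.616, abs=0.005)
        assert treated == pytest.approx(0.786, abs=0.005)

    def test_ordering_preserved(self, table3_profiles):
        coeffs = load_coefficient_set("dam_independence_v1")
        for profile in table3_profiles:
            untreated, treated = apply_corrections_both_arms(coeffs, profile)
            assert treated > untreated
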