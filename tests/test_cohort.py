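"""Unit tests for the synthetic cohort generator and outcome model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from qgmix import reference
from qgmix.cohort import (
    COHORT_COLUMNS,
    CoefficientSet,
    DemographicParams,
    ParameterError,
    SchemaError,
    assign_outcome,
    calibrate_intercept,
    generate_covariates,
    null_preset,
    reference_preset,
)
from qgmix.qgcomp import signed_weights


class TestGenerateCovariates:
    def test_default_marginals_at_reference_n(self):
        params = DemographicParams()
        cohort = generate_covariates(params, seed=7)
        n = len(cohort)
        assert n == 9060
        se_age = params.age_sd / math.sqrt(n)
        assert abs(cohort["age"].mean() - params.age_mean) < 3 * se_age
        p = params.p_female
        se_f = math.sqrt(p * (1 - p) / n)
        frac_female = 1.0 - cohort["sex_male"].mean()
        assert abs(frac_female - p) < 3 * se_f

    def test_empty_cohort_has_schema(self):
        cohort = generate_covariates(DemographicParams(n=0), seed=1)
        assert list(cohort.columns) == COHORT_COLUMNS
        assert len(cohort) == 0

    def test_degenerate_probability(self):
        cohort = generate_covariates(
            DemographicParams(n=50, p_smoke=1.0), seed=1
        )
        assert (cohort["smoked_100"] == 1).all()

    def test_negative_n_rejected(self):
        with pytest.raises(ParameterError):
            generate_covariates(DemographicParams(n=-1), seed=1)

    def test_age_floor_respected(self):
        cohort = generate_covariates(DemographicParams(n=5000), seed=3)
        assert (cohort["age"] >= 18.0).all()

    def test_seed_determinism(self):
        a = generate_covariates(DemographicParams(n=500), seed=11)
        b = generate_covariates(DemographicParams(n=500), seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_marginal_fidelity_over_replicates(self):
        """Across repeated cohorts, each indicator proportion stays within
        4 binomial SEs of its target in at least 95% of checks."""
        params = DemographicParams()
        targets = {
            "sex_male": 1 - params.p_female,
            "smoked_100": params.p_smoke,
            "family_ra": params.p_family_ra,
            "other_ai": params.p_other_ai,
            "income_gt_30k": params.p_income,
        }
        checks = []
        for s in range(20):
            cohort = generate_covariates(params, seed=1000 + s)
            for col, p in targets.items():
                se = math.sqrt(p * (1 - p) / len(cohort))
                checks.append(abs(cohort[col].mean() - p) < 4 * se)
        assert np.mean(checks) >= 0.95


class TestAssignOutcome:
    def _xq(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.integers(0, 8, (n, len(reference.EXPOSURE_COLUMNS))),
            columns=reference.EXPOSURE_COLUMNS,
        )

    def test_null_model_hits_reference_prevalence(self):
        n = 9060
        cohort = generate_covariates(DemographicParams(n=n), seed=5)
        coeffs = null_preset(intercept=float(logit(0.125)))
        out = assign_outcome(cohort, self._xq(n), coeffs, seed=6)
        se = math.sqrt(0.125 * 0.875 / n)
        assert abs(out["outcome"].mean() - 0.125) < 3 * se

    def test_probabilities_numerically_bounded(self):
        n = 200
        cohort = generate_covariates(DemographicParams(n=n), seed=5)
        coeffs = null_preset(intercept=-1e9)  # extreme intercept is clamped
        out = assign_outcome(cohort, self._xq(n), coeffs, seed=6)
        assert set(out["outcome"].unique()) <= {0, 1}

    def test_binary_covariate_log_or_recovered(self):
        """With a single planted alpha = ln 2, the empirical 2x2 log odds
        ratio matches within 0.05 at n = 50,000."""
        n = 50_000
        rng = np.random.default_rng(9)
        cohort = pd.DataFrame(
            {
                "id": np.arange(n),
                "z": rng.integers(0, 2, n),
            }
        )
        xq = pd.DataFrame(index=cohort.index)
        coeffs = CoefficientSet(
            intercept=-1.5,
            mixture_betas=pd.Series(dtype=float),
            covariate_alphas=pd.Series({"z": math.log(2.0)}),
        )
        out = assign_outcome(cohort, xq, coeffs, seed=10)
        tab = pd.crosstab(out["z"], out["outcome"])
        log_or = math.log(
            (tab.loc[1, 1] * tab.loc[0, 0]) / (tab.loc[0, 1] * tab.loc[1, 0])
        )
        assert abs(log_or - math.log(2.0)) < 0.05

    def test_name_mismatch_raises(self):
        cohort = generate_covariates(DemographicParams(n=100), seed=5)
        coeffs = CoefficientSet(
            intercept=0.0,
            mixture_betas=pd.Series({"not_a_column": 0.1}),
            covariate_alphas=pd.Series(dtype=float),
        )
        with pytest.raises(SchemaError):
            assign_outcome(cohort, self._xq(100), coeffs, seed=1)


class TestCalibrateIntercept:
    def test_all_slopes_zero_closed_form(self):
        cohort = generate_covariates(DemographicParams(n=400), seed=2)
        xq = pd.DataFrame(index=cohort.index)
        coeffs = CoefficientSet(
            intercept=0.0,
            mixture_betas=pd.Series(dtype=float),
            covariate_alphas=pd.Series(dtype=float),
        )
        b0 = calibrate_intercept(coeffs, xq, cohort, 0.2)
        assert b0 == pytest.approx(float(logit(0.2)), abs=1e-8)

    def test_symmetric_design_target_half(self):
        """For target 0.5 with one symmetric +/-1 covariate the solution is
        b0 = 0 = -mean(slope terms); cross-checked against a grid search."""
        n = 1000
        z = np.tile([-1.0, 1.0], n // 2)
        cohort = pd.DataFrame({"id": np.arange(n), "z": z})
        xq = pd.DataFrame(index=cohort.index)
        coeffs = CoefficientSet(
            intercept=0.0,
            mixture_betas=pd.Series(dtype=float),
            covariate_alphas=pd.Series({"z": 0.7}),
        )
        b0 = calibrate_intercept(coeffs, xq, cohort, 0.5)
        grid = np.linspace(-2, 2, 40001)
        means = expit(grid[:, None] + 0.7 * z[None, :]).mean(axis=1)
        b0_grid = grid[np.argmin(np.abs(means - 0.5))]
        assert b0 == pytest.approx(-np.mean(0.7 * z), abs=1e-8)
        assert b0 == pytest.approx(b0_grid, abs=1e-4)

    def test_preset_self_consistency(self, small_cohort, small_exposures):
        from qgmix.quantize import quantize_columns

        xq = quantize_columns(small_exposures, 8).codes
        coeffs = reference_preset("per_component")
        b0 = calibrate_intercept(coeffs, xq, small_cohort, 0.125)
        from qgmix.cohort import _linear_predictor

        eta = _linear_predictor(small_cohort, xq, coeffs.with_intercept(b0))
        assert float(np.mean(expit(eta))) == pytest.approx(0.125, abs=1e-6)

    def test_unattainable_target_rejected(self, small_cohort):
        xq = pd.DataFrame(index=small_cohort.index)
        coeffs = null_preset()
        with pytest.raises(ParameterError):
            calibrate_intercept(coeffs, xq, small_cohort, 1.0)


class TestReferencePreset:
    def test_uniform_psi_sums_exactly(self):
        coeffs = reference_preset("uniform_psi")
        assert coeffs.psi == pytest.approx(math.log(reference.PSI_OR), abs=1e-15)
        assert len(coeffs.mixture_betas) == 17

    def test_per_component_sulfate_beta(self):
        coeffs = reference_preset("per_component")
        assert coeffs.mixture_betas["so4"] == pytest.approx(
            math.log(1.059), abs=1e-12
        )

    def test_weights_recomputed_from_published_ors(self):
        """Signed weights recomputed from the published per-component odds
        ratios match the published weight column within 0.01 per term, once
        the misprinted pm10 OR is replaced by the value its own printed
        weight implies (~0.989).  The positive-sign weights -- including the
        headline sulfate weight -- match even from the raw printed ORs,
        because pm10 only distorts the negative-side denominator."""
        betas = reference_preset("per_component").mixture_betas  # consistent set
        weights = signed_weights(betas)
        for col in reference.EXPOSURE_COLUMNS:
            assert weights[col] == pytest.approx(
                reference.MIXTURE_WEIGHTS[col], abs=0.01
            ), col
        raw = signed_weights(reference.mixture_log_odds(consistent=False))
        assert raw["so4"] == pytest.approx(
            reference.MIXTURE_WEIGHTS["so4"], abs=0.01
        )
        # the consistent set's coefficient sum sits within OR-rounding
        # distance of the printed mixture OR (printed to 2 decimals)
        assert math.exp(betas.sum()) == pytest.approx(reference.PSI_OR, abs=0.02)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            reference_preset("nope")


def test_outcome_model_fidelity_large_n():
    """Fitting the generating logistic model to a large planted cohort
    recovers every coefficient within 3 estimated SEs."""
    from qgmix.logistic import build_design, fit_logistic_mle
    from qgmix.pipeline import RunConfig, covariates_for_fit, simulate_cohort
    from qgmix.quantize import quantize_columns

    cfg = RunConfig(
        seed=2024,
        demographics=DemographicParams(n=200_000),
        preset="per_component",
        bootstrap=0,
        exposure_mode="direct",
    )
    cohort, exposures, coeffs = simulate_cohort(cfg)
    xq = quantize_columns(exposures, 8).codes
    design = build_design(xq, covariates_for_fit(cohort))
    fit = fit_logistic_mle(design, cohort["outcome"].to_numpy())
    truth = pd.concat(
        [
            pd.Series({"intercept": coeffs.intercept}),
            coeffs.mixture_betas,
            coeffs.covariate_alphas,
        ]
    )
    for name, true_val in truth.items():
        z = abs(fit.params[name] - true_val) / fit.bse[name]
        assert z < 3.0, f"{name}: z={z:.2f}"
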