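"""Restricted cubic splines, nonlinearity testing, contrasts, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from cfmdnet.dose_response import (
    PowerSpec,
    default_knots,
    fit_rcs_model,
    heuristic_network_n,
    nonlinearity_test,
    predict_curve,
    rcs_basis,
    regression_power,
    required_sample_size_f2,
    standardized_fit,
    total_effect,
    wald_ci,
)
from cfmdnet.synthetic import CohortSpec, simulate_dose_response_cohort


class TestKnots:
    def test_default_quantiles_on_1_to_100(self):
        knots = default_knots(np.arange(1, 101))
        assert np.allclose(knots, [5.95, 35.65, 65.35, 95.05])

    def test_translation_equivariance(self):
        x = np.linspace(0, 10, 200)
        assert np.allclose(default_knots(x + 3.5), default_knots(x) + 3.5)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            default_knots(np.array([1, 1, 2, 2, 3] * 10))

    def test_collapsing_ties_advise_manual_knots(self):
        x = np.r_[np.full(60, 5.0), np.linspace(5, 6, 40)]
        with pytest.raises(ValueError, match="manual"):
            default_knots(x)


def _hand_truncated_power(x, t):
    """Independent symbolic evaluation of the restricted truncated-power term."""
    plus = lambda u: max(u, 0.0) ** 3
    norm = (t[3] - t[0]) ** 2
    terms = []
    for j in range(2):
        v = (
            plus(x - t[j])
            - plus(x - t[2]) * (t[3] - t[j]) / (t[3] - t[2])
            + plus(x - t[3]) * (t[2] - t[j]) / (t[3] - t[2])
        )
        terms.append(v / norm)
    return terms


class TestRcsBasis:
    def test_four_knots_give_two_nonlinear_columns(self):
        basis = rcs_basis(np.linspace(0, 3, 10), [0, 1, 2, 3])
        assert basis.shape == (10, 3)

    def test_nonlinear_terms_vanish_at_and_below_first_knot(self):
        knots = [2.0, 3.0, 5.0, 8.0]
        basis = rcs_basis(np.array([0.5, 2.0]), knots)
        assert np.allclose(basis[:, 1:], 0.0)

    def test_matches_hand_evaluated_formula_between_knots(self):
        knots = [0.0, 1.0, 2.0, 3.0]
        x = 1.5  # midpoint of (t2, t3)
        basis = rcs_basis(np.array([x]), knots)
        assert np.allclose(basis[0, 1:], _hand_truncated_power(x, knots))
        assert basis[0, 0] == x

    @pytest.mark.parametrize("seed", range(4))
    def test_tail_linearity_beyond_boundary_knots(self, seed):
        """Second differences of the spline are ~0 outside [t1, t4]."""
        rng = np.random.default_rng(seed)
        knots = np.sort(rng.uniform(0, 10, 4))
        if np.min(np.diff(knots)) < 0.1:
            knots = np.array([1.0, 3.0, 6.0, 9.0])
        coefs = rng.normal(size=3)
        for grid in (np.linspace(knots[0] - 5, knots[0], 50),
                     np.linspace(knots[3], knots[3] + 5, 50)):
            y = rcs_basis(grid, knots) @ coefs
            second = np.diff(y, 2)
            assert np.abs(second).max() < 1e-8

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([1.0, np.nan]), [0, 1, 2, 3])


class TestFit:
    def test_linear_truth_noiseless_interpolated_exactly(self):
        rng = np.random.default_rng(0)
        cf = rng.uniform(30, 140, 300)
        md = 2.0 + 0.5 * cf
        fit = fit_rcs_model(md, cf)
        assert fit.rsquared == pytest.approx(1.0, abs=1e-10)
        nl = [fit.params[name] for name in fit.spline_names[1:]]
        assert np.allclose(nl, 0.0, atol=1e-6)

    def test_saturating_cohort_fit_is_monotone_and_steepest_mid_range(self):
        cohort = simulate_dose_response_cohort(CohortSpec(seed=7))
        fit = fit_rcs_model(cohort.md_total, cohort.cf_total)
        # between the boundary knots the fit is data-driven; beyond them it
        # extrapolates linearly and noise can tilt the flat plateaus slightly
        grid = np.arange(np.ceil(fit.knots[0]), 101.0)
        pred = predict_curve(fit, grid)["fit"].to_numpy()
        slopes = np.diff(pred)
        assert (slopes > -0.05).all()  # monotone up to tiny numerical dips
        mid = slopes[(grid[:-1] >= 60) & (grid[:-1] <= 90)]
        outer = slopes[(grid[:-1] < 55) | (grid[:-1] > 95)]
        assert mid.mean() > outer.mean()

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fit_rcs_model(np.arange(4.0), np.array([1.0, 2.0, 3.0, 4.0]),
                          knots=[1.0, 2.0, 3.0, 4.0])

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(1)
        cf = rng.uniform(0, 100, 80)
        covs = pd.DataFrame({"dup": cf})  # numeric covariate duplicating the linear term
        with pytest.raises(ValueError, match="collinear"):
            fit_rcs_model(rng.normal(size=80), cf, covs)

    def test_model2_r2_at_least_model1(self):
        cohort = simulate_dose_response_cohort(CohortSpec(n=400, seed=9))
        fit1 = fit_rcs_model(cohort.md_total, cohort.cf_total)
        fit2 = fit_rcs_model(cohort.md_total, cohort.cf_total, cohort[["gender", "age_band"]])
        assert fit2.rsquared >= fit1.rsquared - 1e-12

    def test_scaled_nonlinear_basis_reparameterization_equivalence(self):
        """Fitted values agree between the scaled and unscaled nonlinear bases."""
        rng = np.random.default_rng(3)
        cf = rng.uniform(30, 140, 250)
        md = rng.normal(size=250)
        knots = default_knots(cf)
        fit = fit_rcs_model(md, cf, knots=knots)
        # independent unscaled truncated-power fit
        plus = lambda u: np.where(u > 0, u, 0.0) ** 3
        cols = [np.ones_like(cf), cf]
        for j in range(2):
            cols.append(
                plus(cf - knots[j])
                - plus(cf - knots[2]) * (knots[3] - knots[j]) / (knots[3] - knots[2])
                + plus(cf - knots[3]) * (knots[2] - knots[j]) / (knots[3] - knots[2])
            )
        X = np.column_stack(cols)
        beta = np.linalg.lstsq(X, md, rcond=None)[0]
        assert np.allclose(fit.results.fittedvalues, X @ beta, atol=1e-8)


class TestNonlinearity:
    def test_zero_nonlinear_coefficients_give_zero_f(self):
        rng = np.random.default_rng(2)
        cf = rng.uniform(30, 140, 500)
        knots = default_knots(cf)
        md = 1.0 + 0.3 * cf + rng.normal(size=500)
        # construct a response whose projection on the nonlinear columns is exactly 0
        basis = rcs_basis(cf, knots)
        X = np.column_stack([np.ones(500), basis])
        beta = np.linalg.lstsq(X, md, rcond=None)[0]
        md_clean = X[:, :2] @ beta[:2] + (md - X @ beta)
        # refit: nonlinear coefs are ~0 by construction, so F ~ 0
        fit = fit_rcs_model(md_clean, cf, knots=knots)
        f, p = nonlinearity_test(fit)
        assert f == pytest.approx(0.0, abs=1e-10)

    def test_saturating_truth_rejected_with_high_power(self):
        reject = 0
        for rep in range(60):
            cohort = simulate_dose_response_cohort(
                CohortSpec(n=645, covariate_effects={}, seed=40_000 + rep)
            )
            fit = fit_rcs_model(cohort.md_total, cohort.cf_total)
            reject += nonlinearity_test(fit)[1] < 0.05
        assert reject / 60 > 0.9


class TestTotalEffect:
    def test_wald_ci_convention(self):
        lo, hi = wald_ci(56.43, 6.56)
        assert round(lo, 2) == 43.57 and round(hi, 2) == 69.29

    def test_linear_fit_gives_slope_contrast(self):
        rng = np.random.default_rng(4)
        cf = rng.uniform(30, 140, 400)
        md = 5.0 + 0.7 * cf
        fit = fit_rcs_model(md, cf)
        est, se, _ = total_effect(fit)
        lo, hi = np.quantile(cf, [0.25, 0.75])
        assert est == pytest.approx(0.7 * (hi - lo), rel=1e-6)
        assert se == pytest.approx(0.0, abs=1e-6)

    def test_null_contrast(self):
        cohort = simulate_dose_response_cohort(CohortSpec(n=200, seed=1))
        fit = fit_rcs_model(cohort.md_total, cohort.cf_total)
        est, se, _ = total_effect(fit, 0.5, 0.5)
        assert est == 0.0 and se == 0.0

    def test_reversed_quantiles_rejected(self):
        cohort = simulate_dose_response_cohort(CohortSpec(n=200, seed=1))
        fit = fit_rcs_model(cohort.md_total, cohort.cf_total)
        with pytest.raises(ValueError):
            total_effect(fit, 0.75, 0.25)


class TestStandardized:
    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        cf = rng.uniform(30, 140, 300)
        md = 10 + 0.5 * cf + rng.normal(0, 5, 300)
        f1 = standardized_fit(md, cf)
        f2 = standardized_fit(md, cf * 10)
        assert np.allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-8)

    def test_pure_linear_noiseless_gives_unit_coefficient(self):
        cf = np.linspace(30, 140, 200)
        fit = standardized_fit(3 * cf + 1, cf)
        assert fit.params[fit.spline_names[0]] == pytest.approx(1.0, abs=1e-8)
        assert abs(fit.params["const"]) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardized_fit(np.ones(50), np.linspace(0, 1, 50))


class TestPredictCurve:
    def test_band_narrowest_near_data_bulk(self):
        cohort = simulate_dose_response_cohort(CohortSpec(seed=6))
        fit = fit_rcs_model(cohort.md_total, cohort.cf_total)
        curve = predict_curve(fit, np.array([40.0, 82.0, 135.0]))
        widths = (curve.ci_high - curve.ci_low).to_numpy()
        assert widths[1] < widths[0] and widths[1] < widths[2]

    def test_noiseless_fit_has_zero_width_band(self):
        cf = np.linspace(30, 140, 150)
        fit = fit_rcs_model(2 * cf, cf)
        curve = predict_curve(fit, np.array([60.0, 90.0]))
        assert np.allclose(curve.se, 0.0, atol=1e-8)

    def test_deterministic(self):
        cohort = simulate_dose_response_cohort(CohortSpec(n=200, seed=2))
        f1 = fit_rcs_model(cohort.md_total, cohort.cf_total)
        f2 = fit_rcs_model(cohort.md_total, cohort.cf_total)
        g = np.linspace(40, 130, 50)
        assert predict_curve(f1, g).equals(predict_curve(f2, g))

    def test_empty_grid_rejected(self):
        cohort = simulate_dose_response_cohort(CohortSpec(n=200, seed=2))
        fit = fit_rcs_model(cohort.md_total, cohort.cf_total)
        with pytest.raises(ValueError):
            predict_curve(fit, np.array([]))


def _oracle_ncf_power(n, f2, alpha, p):
    """Noncentral-F power via the Poisson-mixture-of-betas CDF (independent)."""
    d1, d2 = p, n - p - 1
    lam = f2 * n
    fcrit = stats.f.ppf(1 - alpha, d1, d2)
    xx = d1 * fcrit / (d1 * fcrit + d2)
    cdf = sum(
        np.exp(-lam / 2 + j * np.log(lam / 2) - special.gammaln(j + 1))
        * special.betainc(d1 / 2 + j, d2 / 2, xx)
        for j in range(400)
    )
    return 1 - cdf


class TestPowerAnalysis:
    def test_reference_spec_gives_254(self):
        assert required_sample_size_f2(PowerSpec()) == 254

    def test_matches_independent_noncentral_f_oracle(self):
        spec = PowerSpec(f2=0.15, alpha=0.05, power=0.95, n_predictors=10)
        n = spec.n_predictors + 2
        while _oracle_ncf_power(n, spec.f2, spec.alpha, spec.n_predictors) < spec.power:
            n += 1
        assert required_sample_size_f2(spec) == n

    def test_power_saturates_for_huge_effects(self):
        # denominator df, not the effect, limits n in this regime
        spec = PowerSpec(f2=10.0, n_predictors=3)
        assert required_sample_size_f2(spec) <= spec.n_predictors + 5

    def test_returned_n_is_minimal(self):
        spec = PowerSpec()
        n = required_sample_size_f2(spec)
        assert regression_power(n, spec) >= spec.power
        assert regression_power(n - 1, spec) < spec.power

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(f2=-0.1)
        with pytest.raises(ValueError):
            PowerSpec(alpha=1.5)


class TestHeuristicSampleSize:
    def test_52_nodes(self):
        assert heuristic_network_n(52) == (520, 578)

    def test_zero_attrition_identity(self):
        minimum, target = heuristic_network_n(30, attrition=0.0)
        assert minimum == target == 300

    def test_full_attrition_rejected(self):
        with pytest.raises(ValueError):
            heuristic_network_n(52, attrition=1.0)
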