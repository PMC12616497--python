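"""FIML likelihood, reference models, fit indices, and factor scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cddsev as cs
from cddsev.cohort import OBSERVED_VARS
from cddsev.fiml import (
    PatternData,
    baseline_loglik,
    fiml_loglik,
    fiml_loglik_grad,
    fit_indices,
    saturated_loglik,
    start_values,
)

from conftest import random_missing_mask


def _frame(y: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(y, columns=list(OBSERVED_VARS))


def _per_row_loglik(mu, sigma, y):
    """Naive ungrouped oracle: one MVN density per row on its observed set."""
    total = 0.0
    for row in y:
        o = np.flatnonzero(~np.isnan(row))
        if o.size == 0:
            continue
        total += stats.multivariate_normal.logpdf(
            row[o], mean=mu[o], cov=sigma[np.ix_(o, o)])
    return total


class TestInclusionRule:
    def test_counts_rule(self):
        y = np.full((5, 9), np.nan)
        y[1, 0] = 1.0                 # 1 score
        y[2, :2] = 1.0                # 2 scores
        y[3, :5] = 1.0
        y[4, :] = 1.0
        df = _frame(y)
        df["subject_id"] = [f"s{i}" for i in range(5)]
        df["visit"] = "baseline"
        kept = cs.filter_inclusion(df)
        assert list(kept.subject_id) == ["s2", "s3", "s4"]
        assert kept.attrs["n_excluded"] == 2

    def test_complete_cohort_identity(self, complete_latent_cohort):
        cohort, _ = complete_latent_cohort
        kept = cs.filter_inclusion(cohort)
        assert len(kept) == len(cohort)

    def test_matches_brute_force_row_scan(self, study_cohort):
        cohort, _ = study_cohort
        base = cohort[cohort.visit == "baseline"]
        expected = sum(
            1 for _, row in base.iterrows()
            if row[list(OBSERVED_VARS)].notna().sum() >= 2)
        assert len(cs.filter_inclusion(cohort)) == expected

    def test_instrument_level_option(self, study_cohort):
        cohort, _ = study_cohort
        var_level = cs.filter_inclusion(cohort, level="variable")
        inst_level = cs.filter_inclusion(cohort, level="instrument")
        # instrument counting is at least as strict as variable counting
        assert len(inst_level) <= len(var_level)


class TestFimlLoglik:
    def test_single_observation_closed_form(self, model):
        y = np.full((1, 9), np.nan)
        y[0, 0] = 0.0
        theta = model.pack(
            resid_var={v: 1.0 for v in model.observed},
            psi={("communication", "communication"): 1e-300,
                 ("comorbidities", "comorbidities"): 1e-300,
                 ("global", "global"): 1e-300})
        ll = fiml_loglik(model, theta, _frame(y))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_complete_data_equals_closed_form(self, model, complete_latent_cohort):
        cohort, _ = complete_latent_cohort
        data = PatternData.from_frame(cohort)
        theta = start_values(model, data)
        mu = cs.implied_moments(model, theta).mean
        sigma = cs.implied_moments(model, theta).cov
        y = cohort[list(OBSERVED_VARS)].to_numpy()
        oracle = stats.multivariate_normal.logpdf(y, mean=mu, cov=sigma).sum()
        assert fiml_loglik(model, theta, data) == pytest.approx(oracle, abs=1e-8)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 0.5))
    def test_grouped_equals_per_row_on_random_masks(self, model, seed, rate):
        rng = np.random.default_rng(seed)
        cfg = cs.GeneratorConfig(n_subjects=60, seed=seed % 997, bounded=False,
                                 missing_rates={})
        y = cs.generate_cohort(cfg)[list(OBSERVED_VARS)].to_numpy()
        y[random_missing_mask(rng, *y.shape, rate=rate)] = np.nan
        data = PatternData(y)
        theta = start_values(model, data)
        im = cs.implied_moments(model, theta)
        grouped = fiml_loglik(model, theta, data)
        assert grouped == pytest.approx(_per_row_loglik(im.mean, im.cov, y),
                                        abs=1e-8)

    def test_inadmissible_theta_signals_not_crashes(self, model,
                                                    complete_latent_cohort):
        cohort, _ = complete_latent_cohort
        theta = cs.default_cdd_model().pack(
            resid_var={v: -1.0 for v in OBSERVED_VARS})
        assert fiml_loglik(model, theta, cohort) == -np.inf

    def test_analytic_gradient_matches_finite_differences(self, model):
        cfg = cs.GeneratorConfig(n_subjects=80, seed=3)
        harm = cs.harmonize(cs.filter_inclusion(cs.generate_cohort(cfg)))
        data = PatternData.from_frame(harm)
        x = start_values(model, data) * 1.03
        _, g = fiml_loglik_grad(model, x, data)
        for j in range(0, x.size, 4):
            h = 1e-5 * max(1.0, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            num = (fiml_loglik(model, xp, data)
                   - fiml_loglik(model, xm, data)) / (2 * h)
            assert g[j] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestReferenceModels:
    def test_saturated_complete_data_closed_form(self, complete_latent_cohort):
        cohort, _ = complete_latent_cohort
        data = PatternData.from_frame(cohort)
        ll, mu, sigma = saturated_loglik(data)
        y = cohort[list(OBSERVED_VARS)].to_numpy()
        np.testing.assert_allclose(mu, y.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(sigma, np.cov(y.T, ddof=0), atol=1e-10)
        oracle = stats.multivariate_normal.logpdf(y, mean=mu, cov=sigma).sum()
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_saturated_em_matches_anderson_factorization(self):
        """Bivariate monotone missingness has a closed-form observed-data
        MLE (factor the likelihood into y1 and y2|y1); the EM solution must
        reproduce it."""
        rng = np.random.default_rng(5)
        n, n_c = 300, 180
        y1 = rng.normal(2.0, 1.5, size=n)
        y2 = 1.0 + 0.8 * y1 + rng.normal(0, 0.7, size=n)
        y2[n_c:] = np.nan
        y = np.full((n, 9), np.nan)
        y[:, 0], y[:, 1] = y1, y2
        y[:, 2:] = rng.normal(size=(n, 7))   # complete filler columns
        data = PatternData(y[:, :2])
        ll, mu, sigma = saturated_loglik(data, tol=1e-12)

        mu1, s11 = y1.mean(), y1.var()
        slope, intercept, *_ = stats.linregress(y1[:n_c], y2[:n_c])
        resid = y2[:n_c] - (intercept + slope * y1[:n_c])
        s22_1 = resid.var()
        mu2 = intercept + slope * mu1
        s12 = slope * s11
        s22 = s22_1 + slope ** 2 * s11
        np.testing.assert_allclose(mu, [mu1, mu2], atol=1e-6)
        np.testing.assert_allclose(
            sigma, [[s11, s12], [s12, s22]], atol=1e-5)
        oracle_ll = _per_row_loglik(np.array([mu1, mu2]),
                                    np.array([[s11, s12], [s12, s22]]),
                                    y[:, :2])
        assert ll == pytest.approx(oracle_ll, abs=1e-6)

    def test_baseline_is_per_variable_univariate(self, study_cohort):
        cohort, _ = study_cohort
        harm = cs.harmonize(cs.filter_inclusion(cohort))
        data = PatternData.from_frame(harm)
        ll = baseline_loglik(data)
        oracle = 0.0
        for var in OBSERVED_VARS:
            vals = harm[var].dropna().to_numpy()
            oracle += stats.norm.logpdf(vals, vals.mean(),
                                        vals.std(ddof=0)).sum()
        assert ll == pytest.approx(oracle, abs=1e-8)


class TestFitIndices:
    def test_exact_fit_boundary(self):
        out = fit_indices(24.0, 24, 900.0, 36, 206)
        assert out["rmsea"] == 0.0
        assert out["cfi"] == 1.0

    def test_rmsea_closed_form(self):
        out = fit_indices(121.0, 100, 900.0, 36, 206)
        assert out["rmsea"] == pytest.approx(np.sqrt(21 / 20_500), abs=1e-12)
        assert out["rmsea"] == pytest.approx(0.032, abs=5e-4)

    def test_cfi_one_when_zero_misfit(self):
        out = fit_indices(0.0, 24, 1000.0, 36, 206)
        assert out["cfi"] == 1.0
        assert out["tli"] > 1.0            # uncapped

    def test_rmsea_denominator_option(self):
        a = fit_indices(121.0, 100, 900.0, 36, 206)["rmsea"]
        b = fit_indices(121.0, 100, 900.0, 36, 206,
                        rmsea_denominator="n")["rmsea"]
        assert b < a and b == pytest.approx(np.sqrt(21 / (100 * 206)))

    def test_tli_undefined_when_baseline_ratio_small(self):
        with pytest.warns(UserWarning, match="TLI undefined"):
            out = fit_indices(30.0, 24, 30.0, 36, 206)
        assert np.isnan(out["tli"])


class TestFitSem:
    def test_converged_with_sensible_indices(self, fitted_complete):
        _, fit = fitted_complete
        assert fit.converged
        assert fit.df == 24
        assert fit.chi_square >= 0
        assert 0 <= fit.rmsea < 0.1
        assert fit.cfi > 0.95

    def test_nesting_of_logliks(self, fitted_complete, model, study_cohort):
        _, fit = fitted_complete
        assert fit.loglik_baseline <= fit.loglik_model <= fit.loglik_saturated
        cohort, _ = study_cohort
        fit2 = cs.fit_sem(model, cs.harmonize(cs.filter_inclusion(cohort)))
        assert fit2.loglik_baseline <= fit2.loglik_model <= fit2.loglik_saturated

    def test_monotonicity_contract(self, model, complete_latent_cohort):
        cohort, _ = complete_latent_cohort
        data = PatternData.from_frame(cohort)
        fit = cs.fit_sem(model, cohort)
        ll_start = fiml_loglik(model, start_values(model, data), data)
        assert fit.loglik_model >= ll_start

    def test_too_few_subjects_rejected(self, model):
        cfg = cs.GeneratorConfig(n_subjects=20, seed=0, bounded=False,
                                 missing_rates={})
        with pytest.raises(ValueError, match="n_used"):
            cs.fit_sem(model, cs.generate_cohort(cfg))

    def test_second_order_structure_also_fits(self, complete_latent_cohort):
        cohort, _ = complete_latent_cohort
        fit = cs.fit_sem(cs.second_order_model(), cohort)
        assert fit.converged
        assert fit.loglik_model <= fit.loglik_saturated


class TestFactorScores:
    def test_zero_deviation_gives_zero_scores(self, model):
        theta = model.pack(
            loadings={v: 0.8 for v in ("sleepiness", "seizures", "alertness",
                                       "csbs", "vision", "feeding")},
            beta={("communication", "global"): 0.5,
                  ("comorbidities", "global"): 0.5},
            psi={("communication", "communication"): 1.0,
                 ("comorbidities", "comorbidities"): 1.0,
                 ("global", "global"): 0.5},
            resid_var={v: 0.5 for v in OBSERVED_VARS},
            intercept={v: 3.0 for v in OBSERVED_VARS})
        df = _frame(np.full((2, 9), 3.0))
        sc = cs.factor_scores(model, theta, df)
        np.testing.assert_allclose(
            sc[["communication", "comorbidities", "global"]], 0.0, atol=1e-12)

    def test_complete_data_matches_regression_formula(self, fitted_complete):
        """Scores equal the textbook regression method computed from the
        brute-force joint covariance of (latents, observed)."""
        harm, fit = fitted_complete
        sc = cs.factor_scores(fit.model, fit, harm)
        im = cs.implied_moments(fit.model, fit.theta)
        cov_ly = im.latent_cov @ im.lam.T
        w = cov_ly @ np.linalg.inv(im.cov)
        y = harm[list(OBSERVED_VARS)].to_numpy()
        oracle = (y - im.mean) @ w.T
        np.testing.assert_allclose(
            sc[["communication", "comorbidities", "global"]].to_numpy(),
            oracle, atol=1e-8)

    def test_identical_subvectors_identical_scores(self, model, fitted_complete):
        harm, fit = fitted_complete
        row = harm.iloc[[0]].copy()
        two = pd.concat([row, row], ignore_index=True)
        two.loc[:, "subject_id"] = ["a", "b"]
        sc = cs.factor_scores(model, fit, two)
        assert sc.loc[0, "global"] == sc.loc[1, "global"]

    def test_no_observed_indicators_gives_nan(self, model, fitted_complete):
        harm, fit = fitted_complete
        row = harm.iloc[[0]].copy()
        row.loc[:, list(OBSERVED_VARS)] = np.nan
        sc = cs.factor_scores(model, fit, row)
        assert np.isnan(sc.loc[0, "global"])
        assert sc.loc[0, "n_observed_vars"] == 0

    def test_missingness_pattern_scores_are_conditional_expectations(
            self, model, fitted_complete):
        """For a partially observed subject the score equals the explicit
        conditional-expectation formula on the observed subset."""
        harm, fit = fitted_complete
        row = harm.iloc[[3]].copy()
        keep = list(OBSERVED_VARS[:4])
        row.loc[:, [v for v in OBSERVED_VARS if v not in keep]] = np.nan
        sc = cs.factor_scores(model, fit, row)
        im = cs.implied_moments(model, fit.theta)
        o = [OBSERVED_VARS.index(v) for v in keep]
        cov_ly = (im.latent_cov @ im.lam.T)[:, o]
        yv = row[keep].to_numpy()[0]
        oracle = cov_ly @ np.linalg.solve(im.cov[np.ix_(o, o)], yv - im.mean[o])
        np.testing.assert_allclose(
            sc[["communication", "comorbidities", "global"]].to_numpy()[0],
            oracle, atol=1e-10)
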