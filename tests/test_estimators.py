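"""Unit and oracle tests for the four regression estimators."""

import itertools

import numpy as np
import pytest

from chu9dmap import Design, fit_clad, fit_fractional_logit, fit_lad, fit_mm, fit_ols
from chu9dmap.estimators import (RankDeficiencyError, S_TUNING_C,
                                 _rho_bisquare, bisquare_tuning_constant)


def _design(x_cols, y, names=None):
    X = np.column_stack([np.ones(len(y))] + list(x_cols))
    terms = ["const"] + (names or [f"x{i}" for i in range(len(x_cols))])
    return Design(X, y, terms)


# ---------------------------------------------------------------------------
# OLS


class TestOLS:
    def test_exact_linear_interpolation(self, rng):
        x = rng.uniform(0, 10, 30)
        res = fit_ols(_design([x], 2 + 3 * x))
        assert res.coefficients["const"] == pytest.approx(2, abs=1e-9)
        assert res.coefficients["x0"] == pytest.approx(3, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_fitted_mean_equals_response_mean(self, rng):
        x = rng.standard_normal(50)
        y = 0.5 + x + rng.standard_normal(50)
        res = fit_ols(_design([x], y))
        assert res.fitted.mean() == pytest.approx(y.mean(), abs=1e-10)

    def test_hc1_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        x = rng.standard_normal((80, 2))
        y = 1 + x @ [0.5, -0.2] + rng.standard_normal(80) * (1 + x[:, 0] ** 2)
        res = fit_ols(_design([x[:, 0], x[:, 1]], y))
        ref = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC1")
        np.testing.assert_allclose(
            [res.robust_se[t] for t in res.terms], ref.bse, rtol=1e-8)

    def test_rank_deficiency_names_terms(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(RankDeficiencyError, match="dup"):
            fit_ols(_design([x, x], np.ones(20), names=["x", "dup"]))


# ---------------------------------------------------------------------------
# LAD


class TestLAD:
    def test_two_points_interpolated(self):
        res = fit_lad(_design([np.array([0.0, 2.0])], np.array([1.0, 5.0])),
                      n_boot=0)
        assert res.coefficients["const"] == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients["x0"] == pytest.approx(2.0, abs=1e-9)
        assert res.objective == pytest.approx(0.0, abs=1e-9)

    def test_intercept_only_is_lower_median(self):
        y = np.array([1.0, 2.0, 4.0, 9.0])
        res = fit_lad(Design(np.ones((4, 1)), y, ["const"]), n_boot=0)
        assert res.coefficients["const"] == 2.0

    def test_objective_matches_brute_force_oracle(self, rng):
        """The LP optimum equals the best of all interpolating p-subsets."""
        for trial in range(5):
            n = 15
            x = rng.uniform(-2, 2, n)
            y = 0.3 + 0.8 * x + rng.standard_normal(n)
            X = np.column_stack([np.ones(n), x])
            best = np.inf
            for i, j in itertools.combinations(range(n), 2):
                try:
                    beta = np.linalg.solve(X[[i, j]], y[[i, j]])
                except np.linalg.LinAlgError:
                    continue
                best = min(best, np.abs(y - X @ beta).sum())
            res = fit_lad(Design(X, y, ["const", "x"]), n_boot=0)
            assert res.objective == pytest.approx(best, abs=1e-8)

    def test_lad_objective_beats_ols_coefficients(self, rng):
        x = rng.standard_normal(60)
        y = 1 + x + rng.standard_normal(60) ** 3
        d = _design([x], y)
        ols = fit_ols(d)
        lad = fit_lad(d, n_boot=0)
        ols_abs = np.abs(y - ols.fitted).sum()
        assert lad.objective <= ols_abs + 1e-10

    def test_record_order_invariance(self, rng):
        x = rng.standard_normal(40)
        y = 0.2 + 0.7 * x + rng.standard_normal(40)
        d1 = _design([x], y)
        perm = rng.permutation(40)
        d2 = _design([x[perm]], y[perm])
        r1, r2 = fit_lad(d1, n_boot=0), fit_lad(d2, n_boot=0)
        for t in r1.terms:
            assert r1.coefficients[t] == pytest.approx(r2.coefficients[t],
                                                       abs=1e-8)


# ---------------------------------------------------------------------------
# CLAD


class TestCLAD:
    def test_equals_lad_when_censoring_inactive(self, rng):
        x = rng.uniform(0, 1, 50)
        y = 0.1 + 0.3 * x + 0.05 * rng.standard_normal(50)  # far below 1
        d = _design([x], y)
        lad = fit_lad(d, n_boot=0)
        clad = fit_clad(d, n_boot=0)
        for t in lad.terms:
            assert clad.coefficients[t] == pytest.approx(
                lad.coefficients[t], abs=1e-10)
        assert clad.n_iter == 1

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censor"):
            fit_clad(Design(np.ones((5, 1)), np.ones(5), ["const"]), n_boot=0)

    def test_deterministic_given_data(self, rng):
        x = rng.uniform(0, 5, 80)
        y = np.minimum(0.3 + 0.2 * x + 0.2 * rng.standard_normal(80), 1.0)
        d = _design([x], y)
        r1, r2 = fit_clad(d, n_boot=0), fit_clad(d, n_boot=0)
        assert r1.coefficients == r2.coefficients
        assert r1.n_iter == r2.n_iter

    def test_less_biased_than_ols_under_heavy_ceiling(self, rng):
        """Slope recovery: y* = 0.3 + 0.5x + e observed as min(y*, 1)."""
        slope_bias = {"CLAD": [], "OLS": []}
        for rep in range(50):
            r = np.random.default_rng(rep)
            x = r.uniform(0, 2, 300)
            y = np.minimum(0.3 + 0.5 * x + 0.15 * r.standard_normal(300), 1.0)
            d = _design([x], y)
            slope_bias["CLAD"].append(
                fit_clad(d, n_boot=0).coefficients["x0"] - 0.5)
            slope_bias["OLS"].append(fit_ols(d).coefficients["x0"] - 0.5)
        assert abs(np.mean(slope_bias["CLAD"])) < abs(np.mean(slope_bias["OLS"]))


# ---------------------------------------------------------------------------
# MM


class TestMM:
    def test_bisquare_loss_identities(self):
        assert _rho_bisquare(np.array([0.0]), S_TUNING_C)[0] == 0.0
        big = _rho_bisquare(np.array([S_TUNING_C, 10.0, 100.0]), S_TUNING_C)
        assert np.all(big == 1.0)

    def test_tuning_constant_for_95_efficiency(self):
        assert bisquare_tuning_constant(0.95) == pytest.approx(4.685, abs=2e-3)

    def test_close_to_ols_on_clean_gaussian(self):
        diffs = []
        for rep in range(10):
            r = np.random.default_rng(rep)
            x = r.standard_normal((1000, 2))
            y = 0.5 + x @ [1.0, -0.5] + 0.3 * r.standard_normal(1000)
            d = _design([x[:, 0], x[:, 1]], y)
            mm = fit_mm(d, n_subsets=50, seed=rep)
            ols = fit_ols(d)
            diffs.append(max(abs(mm.coefficients[t] - ols.coefficients[t])
                             for t in mm.terms))
        assert np.mean(diffs) < 0.01

    def test_higher_efficiency_closer_to_ols(self):
        r = np.random.default_rng(7)
        x = r.standard_normal(800)
        y = 1 + 2 * x + r.standard_normal(800)
        d = _design([x], y)
        ols = fit_ols(d).coef_array
        d99 = np.abs(fit_mm(d, efficiency=0.99, n_subsets=50).coef_array - ols)
        d95 = np.abs(fit_mm(d, efficiency=0.95, n_subsets=50).coef_array - ols)
        assert d99.max() <= d95.max() + 1e-6

    def test_resists_gross_outliers(self):
        r = np.random.default_rng(11)
        x = r.standard_normal(400)
        y = 0.5 + 1.0 * x + 0.2 * r.standard_normal(400)
        y_bad = y.copy()
        idx = r.choice(400, 80, replace=False)
        y_bad[idx] = -5.0
        d = _design([x], y_bad)
        mm = fit_mm(d, n_subsets=50)
        ols = fit_ols(d)
        assert abs(mm.coefficients["const"] - 0.5) < 0.05
        assert abs(mm.coefficients["x0"] - 1.0) < 0.05
        assert abs(ols.coefficients["const"] - 0.5) > 0.5

    def test_needs_enough_observations(self, rng):
        x = rng.standard_normal(5)
        with pytest.raises(ValueError, match="2p"):
            fit_mm(_design([x, x ** 2], rng.standard_normal(5)))


# ---------------------------------------------------------------------------
# Fractional logit


class TestFractionalLogit:
    def test_constant_response_closed_form(self, rng):
        x = rng.standard_normal(100)
        y = np.full(100, 0.7)
        res = fit_fractional_logit(_design([x], y))
        assert res.coefficients["const"] == pytest.approx(
            np.log(0.7 / 0.3), abs=1e-6)
        assert res.coefficients["x0"] == pytest.approx(0.0, abs=1e-6)

    def test_fitted_mean_equals_observed_mean(self, rng):
        for _ in range(5):
            x = rng.standard_normal((120, 2))
            y = rng.uniform(0.33, 1.0, 120)
            res = fit_fractional_logit(_design([x[:, 0], x[:, 1]], y))
            assert abs(res.fitted.mean() - y.mean()) < 1e-8

    def test_response_domain_enforced(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            fit_fractional_logit(_design([x], np.linspace(0.5, 1.2, 20)))
        with pytest.raises(ValueError):
            fit_fractional_logit(_design([x], np.linspace(0.0, 1.0, 20)))

    def test_matches_statsmodels_quasibinomial(self, rng):
        import statsmodels.api as sm
        x = rng.standard_normal(200)
        mu = 1 / (1 + np.exp(-(1.2 + 0.8 * x)))
        y = np.clip(mu + 0.05 * rng.standard_normal(200), 0.01, 1.0)
        res = fit_fractional_logit(_design([x], y))
        ref = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Binomial()).fit(cov_type="HC0")
        np.testing.assert_allclose(res.coef_array, ref.params, rtol=1e-6)
        np.testing.assert_allclose(
            [res.robust_se[t] for t in res.terms], ref.bse, rtol=1e-4)
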