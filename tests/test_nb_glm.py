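"""NB2 likelihood, fitting (against independent oracles) and prediction."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import nbinom

from trapcatch.core_io import ForestType, ValidationError
from trapcatch.covariates import DESIGN_COLUMNS
from trapcatch.nb_glm import (
    FitConfig,
    fit_batch,
    fit_matrix,
    fit_species,
    lr_statistic,
    nb_loglik,
    predict_catch,
)

# Table-style coefficient vectors used in worked examples
OVERLAETI = {
    "intercept": -5.56, "date": 0.00360, "rain": -0.0366, "deadwood": 4.42,
    "swamp": 0.0273, "disturbed": -1.300, "clearcut": -2.210, "farm": -12.3,
}
UELENSIS = {
    "intercept": -4.17, "date": 0.00543, "rain": -0.3740, "deadwood": 2.31,
    "swamp": -1.040, "disturbed": -0.945, "clearcut": -0.999, "farm": -12.4,
}


class TestNbLoglik:
    def test_closed_form_zero_count(self):
        # P(Y=0 | mu=1, theta=1) = theta/(theta+mu) = 1/2
        assert nb_loglik(np.array([0]), np.array([1.0]), 1.0) == pytest.approx(
            np.log(0.5), abs=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_pmf_summation(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 30, size=40)
        mu = rng.uniform(0.1, 8.0, size=40)
        theta = float(rng.uniform(0.3, 5.0))
        expected = nbinom.logpmf(y, theta, theta / (theta + mu)).sum()
        assert nb_loglik(y, mu, theta) == pytest.approx(expected, abs=1e-8)

    def test_poisson_limit(self):
        from scipy.stats import poisson

        rng = np.random.default_rng(5)
        y = rng.integers(0, 10, size=25)
        mu = rng.uniform(0.2, 5.0, size=25)
        assert nb_loglik(y, mu, 1e8) == pytest.approx(
            poisson.logpmf(y, mu).sum(), abs=1e-4
        )

    def test_additivity(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 6, size=20)
        mu = rng.uniform(0.5, 3.0, size=20)
        assert nb_loglik(y, mu, 2.0) == pytest.approx(
            nb_loglik(y[:8], mu[:8], 2.0) + nb_loglik(y[8:], mu[8:], 2.0)
        )

    def test_rejects_non_integer_counts(self):
        with pytest.raises(ValidationError):
            nb_loglik(np.array([1.5]), np.array([1.0]), 1.0)


def _grid_polish_oracle(X, y, offset):
    """Independent maximiser: coarse grid over (slope, log-theta) + Nelder-Mead."""
    def nll(params):
        beta, ltheta = params[:-1], params[-1]
        eta = np.clip(offset + X @ beta, -30, 30)
        return -nb_loglik(y, np.exp(eta), float(np.exp(ltheta)))

    best, best_val = None, np.inf
    for b0 in np.linspace(-6, 2, 9):
        for b1 in np.linspace(-2, 2, 9):
            for lt in np.linspace(-1.5, 3, 7):
                v = nll(np.array([b0, b1, lt]))
                if v < best_val:
                    best, best_val = np.array([b0, b1, lt]), v
    res = minimize(nll, best, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    return -res.fun


class TestFitSpecies:
    def test_intercept_only_closed_form(self):
        # all efforts 1, all counts k: the NB mean MLE is the sample mean
        n, k = 20, 3
        X = np.ones((n, 1))
        y = np.full(n, k)
        fit = fit_matrix(X, y, np.zeros(n), ("intercept",))
        assert fit.coefficients["intercept"] == pytest.approx(np.log(k), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_matches_grid_polish_oracle_on_small_fixture(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        X = np.column_stack([np.ones(n), rng.uniform(-1, 1, n)])
        offset = np.log(rng.uniform(7, 14, n))
        eta = offset + X @ np.array([-1.0, 0.8])
        y = rng.negative_binomial(1.5, 1.5 / (1.5 + np.exp(eta)))
        fit = fit_matrix(X, y, offset, ("intercept", "x"))
        oracle = _grid_polish_oracle(X, y, offset)
        assert fit.loglik == pytest.approx(oracle, abs=1e-3)

    def test_matches_statsmodels_negative_binomial(self, default_design):
        sm = pytest.importorskip("statsmodels.api")
        X = default_design.model_matrix()
        off = default_design.offsets()
        Y = default_design.counts_matrix()
        # drop the farm dummy (all-zero catches there break statsmodels);
        # compare on the remaining, regular design
        keep = [c for c in DESIGN_COLUMNS if c != "farm"]
        idx = [DESIGN_COLUMNS.index(c) for c in keep]
        sp = "Epirhyssa_uelensis"
        k = default_design.species.index(sp)
        ours = fit_matrix(X[:, idx], Y[:, k], off, keep)
        model = sm.NegativeBinomial(Y[:, k], X[:, idx], offset=off, loglike_method="nb2")
        ref = model.fit(disp=0, maxiter=500, method="bfgs")
        assert ours.loglik == pytest.approx(ref.llf, abs=5e-3)
        np.testing.assert_allclose(
            ours.coef_vector, ref.params[:-1], rtol=0, atol=0.02
        )

    def test_simulation_recovery_n2000(self):
        rng = np.random.default_rng(11)
        n = 2000
        X = np.column_stack([np.ones(n), rng.uniform(-1, 1, n), rng.uniform(0, 0.5, n)])
        beta = np.array([-2.0, 0.7, 2.5])
        theta = 2.0
        offset = np.log(np.full(n, 14.0))
        mu = np.exp(offset + X @ beta)
        y = rng.negative_binomial(theta, theta / (theta + mu))
        fit = fit_matrix(X, y, offset, ("intercept", "x1", "x2"))
        np.testing.assert_allclose(fit.coef_vector, beta, atol=0.25)
        assert fit.theta == pytest.approx(theta, rel=0.3)
        # MLE dominance: fitted loglik beats the truth on the same data
        assert fit.loglik >= nb_loglik(y, mu, theta) - 1e-6

    def test_all_zero_counts_flags_intercept(self):
        X = np.ones((10, 1))
        fit = fit_matrix(X, np.zeros(10, dtype=int), np.zeros(10), ("intercept",))
        assert fit.separation_flags == {"intercept"}
        assert fit.coefficients["intercept"] == -15.0

    def test_empty_forest_level_flagged_separated(self, default_design):
        # the default campaign's farmland catches nothing: complete separation
        fit = fit_species(default_design, "Epirhyssa_ghesquierei")
        assert "farm" in fit.separation_flags
        assert fit.coefficients["farm"] == -15.0
        assert fit.converged

    def test_low_n_marking(self, default_design):
        fits = {sp: fit_species(default_design, sp) for sp in default_design.species}
        low = {sp for sp, f in fits.items() if f.low_n}
        assert low == {"Epirhyssa_minor", "Epirhyssa_johanna"}


class TestLrStatistic:
    def test_self_comparison_is_zero(self, default_design):
        f = fit_species(default_design, "Epirhyssa_uelensis")
        assert lr_statistic(f, f) == 0.0

    @pytest.mark.parametrize("seed", [1, 4, 9])
    def test_adding_a_column_never_decreases_loglik(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        X = np.column_stack([np.ones(n), rng.uniform(-1, 1, n), rng.normal(size=n)])
        offset = np.log(np.full(n, 10.0))
        mu = np.exp(offset - 2.0 + 0.5 * X[:, 1])
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        full = fit_matrix(X, y, offset, ("intercept", "x1", "x2"))
        null = fit_matrix(X[:, :2], y, offset, ("intercept", "x1"))
        assert lr_statistic(full, null) >= 0.0

    def test_statistic_grows_with_information(self):
        rng = np.random.default_rng(21)
        stats = []
        for n in (100, 400, 1600):
            x = rng.uniform(-1, 1, n)
            X = np.column_stack([np.ones(n), x])
            offset = np.zeros(n)
            mu = np.exp(1.0 + 0.6 * x)
            y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
            full = fit_matrix(X, y, offset, ("intercept", "x"))
            null = fit_matrix(X[:, :1], y, offset, ("intercept",))
            stats.append(lr_statistic(full, null))
        assert stats[0] < stats[1] < stats[2]

    def test_mismatched_rows_rejected(self, default_design):
        f1 = fit_species(default_design, "Epirhyssa_uelensis")
        short = default_design.subset(range(100))
        f2 = fit_species(short, "Epirhyssa_uelensis")
        with pytest.raises(ValidationError):
            lr_statistic(f1, f2)


class TestPredictCatch:
    def test_deadwood_fold_change(self):
        hi = predict_catch(OVERLAETI, 100.0, 3.0, 0.27, "primary", 14.0)
        lo = predict_catch(OVERLAETI, 100.0, 3.0, 0.0, "primary", 14.0)
        assert hi / lo == pytest.approx(np.exp(4.42 * 0.27), rel=1e-12)
        assert round(hi / lo, 1) == 3.3

    def test_intercept_only_prediction(self):
        v = predict_catch(UELENSIS, 0.0, 0.0, 0.0, ForestType.PRIMARY, 1.0)
        assert v == pytest.approx(np.exp(-4.17), rel=1e-12)
        assert v == pytest.approx(0.01545, abs=5e-6)

    def test_zero_effort_zero_catch(self):
        assert predict_catch(OVERLAETI, 50.0, 2.0, 0.1, "swamp", 0.0) == 0.0

    def test_linear_in_days_loglinear_in_covariates(self):
        one = predict_catch(OVERLAETI, 50.0, 2.0, 0.1, "disturbed", 1.0)
        assert predict_catch(OVERLAETI, 50.0, 2.0, 0.1, "disturbed", 2.0) == pytest.approx(2 * one)
        bumped = predict_catch(OVERLAETI, 51.0, 2.0, 0.1, "disturbed", 1.0)
        assert bumped / one == pytest.approx(np.exp(OVERLAETI["date"]))

    def test_unknown_forest_level_rejected(self):
        with pytest.raises(ValueError):
            predict_catch(OVERLAETI, 0.0, 0.0, 0.0, "savanna", 1.0)


class TestFitBatch:
    def test_batch_agrees_with_scalar_fits(self, toy_design):
        X = toy_design.model_matrix()
        off = toy_design.offsets()
        Y = toy_design.counts_matrix()
        rng = np.random.default_rng(3)
        Yb = np.stack([rng.permutation(Y[:, 0]) for _ in range(6)])
        scalar = fit_matrix(X, Y[:, 0], off, DESIGN_COLUMNS)
        _, _, ll = fit_batch(
            X, Yb, off, DESIGN_COLUMNS, scalar.coef_vector, scalar.theta
        )
        for b in range(6):
            ref = fit_matrix(X, Yb[b], off, DESIGN_COLUMNS)
            assert ll[b] == pytest.approx(ref.loglik, abs=0.05)
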