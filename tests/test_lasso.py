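import numpy as np
import pytest
from scipy.optimize import minimize

from spatioassoc import LassoConfig, fit_poisson_lasso, poisson_deviance


@pytest.fixture()
def toy_problem():
    rng = np.random.default_rng(0)
    n, p = 40, 3
    X = rng.normal(size=(n, p))
    total = rng.integers(50, 500, n).astype(float)
    eta = -3.0 + 0.6 * X[:, 0]
    cases = rng.poisson(total * np.exp(eta)).astype(float)
    return X, cases, total


def brute_force_solution(X, cases, total, lam, pf=None):
    """Direct numerical minimization of the penalized Poisson likelihood
    via positive/negative splitting (independent of the package solver)."""
    n, p = X.shape
    pf = np.ones(p) if pf is None else pf
    offset = np.log(total)
    mean, sd = X.mean(0), X.std(0)
    Xs = (X - mean) / sd

    def obj(z):
        b = z[1 : 1 + p] - z[1 + p :]
        eta = offset + z[0] + Xs @ b
        return (
            np.sum(np.exp(eta)) / n
            - cases @ eta / n
            + lam * np.sum(pf * (z[1 : 1 + p] + z[1 + p :]))
        )

    r = minimize(
        obj,
        np.zeros(1 + 2 * p),
        method="L-BFGS-B",
        bounds=[(None, None)] + [(0, None)] * (2 * p),
        options=dict(maxiter=50000, ftol=1e-16, gtol=1e-13),
    )
    return r.x[0], r.x[1 : 1 + p] - r.x[1 + p :]


def standardized_coefs(res, X, k):
    sd = X.std(0)
    b = res.coef[:, k] * sd
    b0 = res.intercept[k] + X.mean(0) @ res.coef[:, k]
    return b0, b


def test_path_matches_direct_minimization(toy_problem):
    X, cases, total = toy_problem
    cfg = LassoConfig(n_lambda=15, lambda_min_ratio=1e-3, tol=1e-10)
    res = fit_poisson_lasso(X, cases, total, cfg, n_folds=4, seed=0)
    for k in [0, 4, 9, 14]:
        b0o, bo = brute_force_solution(X, cases, total, res.lambdas[k])
        b0, b = standardized_coefs(res, X, k)
        assert b0 == pytest.approx(b0o, abs=1e-5)
        assert np.allclose(b, bo, atol=1e-5)


def test_saturated_penalty_gives_pooled_rate_intercept(toy_problem):
    """At lambda_max all penalized coefficients are zero and the intercept is
    the log pooled rate log(sum cases / sum total)."""
    X, cases, total = toy_problem
    res = fit_poisson_lasso(X, cases, total, LassoConfig(n_lambda=10), n_folds=4)
    assert np.allclose(res.coef[:, 0], 0.0, atol=1e-10)
    assert res.intercept[0] == pytest.approx(np.log(cases.sum() / total.sum()), abs=1e-8)


def test_offset_shift_moves_only_intercept(toy_problem):
    X, cases, total = toy_problem
    cfg = LassoConfig(n_lambda=10, tol=1e-10)
    r1 = fit_poisson_lasso(X, cases, total, cfg, n_folds=4, seed=1)
    r2 = fit_poisson_lasso(X, cases, total * 7.0, cfg, n_folds=4, seed=1)
    assert np.allclose(r1.coef, r2.coef, atol=1e-6)
    assert np.allclose(r2.intercept - r1.intercept, -np.log(7.0), atol=1e-6)


def test_feature_rescaling_inverts_coefficient_and_keeps_selection(toy_problem):
    X, cases, total = toy_problem
    cfg = LassoConfig(n_lambda=12, tol=1e-10)
    r1 = fit_poisson_lasso(X, cases, total, cfg, n_folds=4, seed=2)
    X2 = X.copy()
    X2[:, 0] *= 100.0
    r2 = fit_poisson_lasso(X2, cases, total, cfg, n_folds=4, seed=2)
    assert np.allclose(r2.coef[0, :] * 100.0, r1.coef[0, :], atol=1e-8)
    assert np.allclose(r2.coef[1:, :], r1.coef[1:, :], atol=1e-8)
    assert r1.selected() == r2.selected()


def test_support_size_weakly_decreasing_in_lambda(toy_problem):
    X, cases, total = toy_problem
    res = fit_poisson_lasso(X, cases, total, LassoConfig(n_lambda=30), n_folds=4)
    sizes = res.support_sizes()  # path is decreasing in lambda
    assert (np.diff(sizes) >= 0).all()


def test_cv_deviance_at_lambda_min_is_minimum(toy_problem):
    X, cases, total = toy_problem
    res = fit_poisson_lasso(X, cases, total, LassoConfig(n_lambda=20), n_folds=4, seed=3)
    k_min = res._lambda_index(res.lambda_min)
    assert res.cv_mean_deviance[k_min] == res.cv_mean_deviance.min()
    assert (res.cv_mean_deviance >= 0).all()
    # 1se rule picks a lambda at least as large (sparser or equal model)
    assert res.lambda_1se >= res.lambda_min


def test_unpenalized_features_stay_in_model(toy_problem):
    X, cases, total = toy_problem
    cfg = LassoConfig(n_lambda=10, penalty_factor=[1.0, 0.0, 1.0])
    res = fit_poisson_lasso(X, cases, total, cfg, n_folds=4)
    # feature 1 is unpenalized: nonzero along the whole path (incl. lambda_max)
    assert np.all(np.abs(res.coef[1, :]) > 0)
    # and never reported as "selected" (selection is among penalized features)
    assert "x1" not in res.selected()


def test_constant_feature_dropped_with_zero_coefficient(toy_problem):
    X, cases, total = toy_problem
    X2 = np.column_stack([X, np.full(len(X), 3.3)])
    res = fit_poisson_lasso(X2, cases, total, LassoConfig(n_lambda=8), n_folds=4)
    assert np.allclose(res.coef[3, :], 0.0)


def test_poisson_deviance_saturated_is_zero_and_zero_counts_ok():
    y = np.array([0.0, 2.0, 5.0])
    assert poisson_deviance(y, np.maximum(y, 1e-300)) == pytest.approx(0.0, abs=1e-8)
    assert poisson_deviance(y, np.array([1.0, 2.0, 5.0])) == pytest.approx(2.0)


def test_invalid_inputs_rejected(toy_problem):
    X, cases, total = toy_problem
    with pytest.raises(ValueError, match="non-finite"):
        bad = X.copy()
        bad[0, 0] = np.nan
        fit_poisson_lasso(bad, cases, total)
    with pytest.raises(ValueError, match="positive"):
        fit_poisson_lasso(X, cases, 0 * total)
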