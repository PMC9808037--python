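"""L1-penalized Poisson rate regression with an exposure offset.

Fits the objective

    (1/n) * sum_i [ total_i * exp(eta_i) - cases_i * (log total_i + eta_i) ]
        + lambda * sum_j pf_j * |beta_j|,        eta_i = beta0 + x_i' beta

over a geometric lambda path, with per-feature penalty factors (pf_j = 0
leaves a feature unpenalized — used for ecological covariates and the
spatial autocovariate so that selection operates on the pollutants only).
The lambda path runs from the smallest lambda that zeroes every penalized
coefficient down to ``lambda_min_ratio`` times that value.

The solver is iteratively reweighted least squares with an inner
coordinate-descent loop on the quadratic subproblem (Gram-matrix updates),
warm-started along the path; features are standardized internally and
coefficients returned on the original scale. Cross-validation
scores each lambda by the mean held-out Poisson deviance

    2 * sum_i [ y_i log(y_i / mu_i) - (y_i - mu_i) ]     (0 log 0 = 0)

over either supplied spatial folds or seeded random folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, LassoConfig
from .spatial import FoldAssignment

__all__ = ["LassoResult", "fit_poisson_lasso", "poisson_deviance"]

logger = logging.getLogger(__name__)


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Total Poisson deviance 2*sum[y log(y/mu) - (y - mu)], 0 log 0 = 0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


@dataclass
class LassoResult:
    """Fitted lambda path, CV curve and selection for a Poisson lasso."""

    feature_names: list[str]
    lambdas: np.ndarray  # decreasing path
    coef: np.ndarray  # (p, n_lambda), original scale
    intercept: np.ndarray  # (n_lambda,)
    penalty_factor: np.ndarray
    cv_mean_deviance: np.ndarray
    cv_se_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float
    selection_rule: str

    def _lambda_index(self, lam: float) -> int:
        return int(np.argmin(np.abs(self.lambdas - lam)))

    def coef_at(self, lam: float | None = None) -> pd.Series:
        """Coefficients (original scale) at a path point; default = chosen rule."""
        if lam is None:
            lam = self.chosen_lambda
        k = self._lambda_index(lam)
        return pd.Series(self.coef[:, k], index=self.feature_names)

    def intercept_at(self, lam: float | None = None) -> float:
        if lam is None:
            lam = self.chosen_lambda
        return float(self.intercept[self._lambda_index(lam)])

    @property
    def chosen_lambda(self) -> float:
        return self.lambda_1se if self.selection_rule == "lambda_1se" else self.lambda_min

    def selected(self, lam: float | None = None, tol: float = 1e-8) -> list[str]:
        """Penalized features with nonzero coefficient at the chosen lambda."""
        c = self.coef_at(lam)
        return [
            f
            for f, pf in zip(self.feature_names, self.penalty_factor)
            if pf > 0 and abs(c[f]) > tol
        ]

    def support_sizes(self, tol: float = 1e-8) -> np.ndarray:
        """Number of nonzero penalized coefficients at each path point."""
        pen = self.penalty_factor > 0
        return (np.abs(self.coef[pen, :]) > tol).sum(axis=0)


def _newton_unpenalized(
    x: np.ndarray, y: np.ndarray, offset: np.ndarray, max_iter: int = 100, tol: float = 1e-12
) -> np.ndarray:
    """Newton-Raphson fit of an unpenalized Poisson GLM with offset."""
    n, p = x.shape
    beta = np.zeros(p)
    if p == 0:
        return beta
    for _ in range(max_iter):
        eta = offset + x @ beta
        mu = np.exp(np.clip(eta, -700, 700))
        grad = x.T @ (mu - y) / n
        hess = (x * mu[:, None]).T @ x / n
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step halving for stability
        f0 = np.sum(mu) / n - y @ eta / n
        t = 1.0
        for _ in range(50):
            cand = beta - t * step
            eta_c = offset + x @ cand
            with np.errstate(over="ignore"):
                f_c = np.sum(np.exp(np.clip(eta_c, -700, 700))) / n - y @ eta_c / n
            if np.isfinite(f_c) and f_c <= f0 + 1e-14:
                break
            t *= 0.5
        beta = cand
        if np.max(np.abs(t * step)) < tol:
            break
    return beta


def _penalized_objective(xa, y, offset, beta, lam, pf, n):
    eta = offset + xa @ beta
    with np.errstate(over="ignore"):
        val = np.sum(np.exp(np.clip(eta, -700, 700))) / n - (y @ eta) / n
    return val + lam * np.sum(pf * np.abs(beta))


def _cd_quadratic(g, q, pf, lam, beta, n_pass=1000, tol=1e-12):
    """Coordinate descent for (1/2) b'Gb - q'b + lam*sum(pf|b|), in place.

    ``g`` is the weighted Gram matrix X'WX/n, ``q = X'Wz/n``; each coordinate
    update costs O(p) via a maintained gradient vector.
    """
    p = len(beta)
    v = g @ beta  # smooth-part gradient is v - q
    diag = np.diag(g)
    for _ in range(n_pass):
        delta_max = 0.0
        for j in range(p):
            if diag[j] <= 0:
                continue
            u = q[j] - v[j] + diag[j] * beta[j]
            t = lam * pf[j]
            b_new = (np.sign(u) * max(abs(u) - t, 0.0)) / diag[j]
            d = b_new - beta[j]
            if d != 0.0:
                beta[j] = b_new
                v += g[:, j] * d
                delta_max = max(delta_max, abs(d))
        if delta_max < tol:
            break
    return beta


def _irls_lasso(xa, y, offset, pf, lam, beta, max_iter, tol):
    """One penalized Poisson fit: IRLS with coordinate-descent subproblems.

    ``xa`` includes the intercept column; ``pf`` entries of 0 mark
    unpenalized coordinates (intercept, covariates, autocovariate). A
    step-halving safeguard keeps the penalized objective non-increasing.
    """
    n = xa.shape[0]
    beta = beta.copy()
    obj = _penalized_objective(xa, y, offset, beta, lam, pf, n)
    for _ in range(max_iter):
        eta_c = xa @ beta
        mu = np.exp(np.clip(offset + eta_c, -700, 700))
        wz = mu * eta_c + (y - mu)  # weighted working response, avoids 0/0
        g = (xa * mu[:, None]).T @ xa / n
        q = xa.T @ wz / n
        prev = beta.copy()
        beta = _cd_quadratic(g, q, pf, lam, beta, tol=max(0.1 * tol, 1e-14))
        new_obj = _penalized_objective(xa, y, offset, beta, lam, pf, n)
        shrink = 0
        while new_obj > obj + 1e-13 and shrink < 30:
            beta = 0.5 * (beta + prev)
            new_obj = _penalized_objective(xa, y, offset, beta, lam, pf, n)
            shrink += 1
        obj = new_obj
        if np.max(np.abs(beta - prev)) < tol:
            break
    return beta


def _fit_path(xs, y, offset, pf, lambdas, unpen_idx, max_iter, tol):
    """Fit the full lambda path on standardized features, warm-started."""
    n, p = xs.shape
    xa = np.column_stack([np.ones(n), xs])
    pf_a = np.concatenate([[0.0], pf])
    # warm start: unpenalized-features-only fit (valid solution at lambda_max)
    cols = np.concatenate([[0], np.asarray(unpen_idx, dtype=int) + 1])
    beta = np.zeros(p + 1)
    beta[cols] = _newton_unpenalized(xa[:, cols], y, offset)
    coefs = np.empty((p + 1, len(lambdas)))
    for k, lam in enumerate(lambdas):
        beta = _irls_lasso(xa, y, offset, pf_a, lam, beta, max_iter, tol)
        coefs[:, k] = beta
    return coefs


def _random_folds(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, k + 1), int(np.ceil(n / k)))[:n]
    return rng.permutation(labels)


def fit_poisson_lasso(
    X: pd.DataFrame | np.ndarray,
    cases: np.ndarray,
    total: np.ndarray,
    cfg: LassoConfig | None = None,
    folds: FoldAssignment | np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> LassoResult:
    """Fit the cross-validated Poisson lasso path.

    Parameters
    ----------
    X:
        Zip-by-feature design matrix (no intercept, no missing values).
    cases, total:
        Outcome counts and offsets; the offset is ``log(total)``.
    cfg:
        Path and solver controls; ``cfg.penalty_factor`` defaults to all-ones.
    folds:
        A :class:`FoldAssignment` (spatial blocking), an explicit label array
        in {1..k}, or None for seeded random folds of size ``n_folds``.
    """
    cfg = cfg or LassoConfig()
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        xmat = X.to_numpy(dtype=float)
    else:
        xmat = np.asarray(X, dtype=float)
        feature_names = [f"x{j}" for j in range(xmat.shape[1])]
    cfg.validate(n_features=xmat.shape[1])
    y = np.asarray(cases, dtype=float)
    total = np.asarray(total, dtype=float)
    if not np.all(np.isfinite(xmat)):
        raise ValueError("X contains non-finite values (filter coverage upstream)")
    if np.any(total <= 0):
        raise ValueError("total must be positive (it enters as log offset)")
    n, p = xmat.shape
    offset = np.log(total)
    pf = (
        np.ones(p)
        if cfg.penalty_factor is None
        else np.asarray(cfg.penalty_factor, dtype=float)
    )

    # Drop constant features (their coefficient is unidentified after centering).
    keep = np.ptp(xmat, axis=0) > 0
    if not keep.all():
        dropped = [f for f, k in zip(feature_names, keep) if not k]
        logger.warning("dropping constant feature(s): %s", dropped)
    xk = xmat[:, keep]
    pfk = pf[keep]
    if cfg.standardize:
        means, scales = xk.mean(axis=0), xk.std(axis=0)
    else:
        means, scales = np.zeros(xk.shape[1]), np.ones(xk.shape[1])
    xs = (xk - means) / scales
    unpen_idx = np.nonzero(pfk == 0)[0]

    # lambda_max: smallest lambda zeroing all penalized coefficients, from the
    # KKT conditions at the unpenalized-only fit.
    xa_cols = np.column_stack([np.ones(n), xs[:, unpen_idx]])
    beta_u = _newton_unpenalized(xa_cols, y, offset)
    mu0 = np.exp(np.clip(offset + xa_cols @ beta_u, -700, 700))
    grad = xs.T @ (mu0 - y) / n
    pen = pfk > 0
    if not pen.any():
        raise ConfigurationError("at least one feature must be penalized")
    lam_max = float(np.max(np.abs(grad[pen]) / pfk[pen]))
    lam_max = max(lam_max, 1e-10) * 1.000001
    lambdas = np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)

    # Cross-validation over the shared path.
    if folds is None:
        labels = _random_folds(n, n_folds, seed)
    elif isinstance(folds, FoldAssignment):
        labels = folds.labels
    else:
        labels = np.asarray(folds)
    fold_ids = np.unique(labels)
    if len(fold_ids) < 2:
        raise ConfigurationError("need at least 2 folds")
    dev = np.empty((len(fold_ids), cfg.n_lambda))
    for fi, f in enumerate(fold_ids):
        test = labels == f
        train = ~test
        coefs_f = _fit_path(
            xs[train], y[train], offset[train], pfk, lambdas, unpen_idx, cfg.max_iter, cfg.tol
        )
        eta_test = offset[test, None] + coefs_f[0][None, :] + xs[test] @ coefs_f[1:]
        mu_test = np.exp(np.clip(eta_test, -700, 700))
        for k in range(cfg.n_lambda):
            dev[fi, k] = poisson_deviance(y[test], mu_test[:, k]) / test.sum()
    cvm = dev.mean(axis=0)
    cvse = dev.std(axis=0, ddof=1) / np.sqrt(len(fold_ids))
    k_min = int(np.argmin(cvm))
    lambda_min = float(lambdas[k_min])
    within = cvm <= cvm[k_min] + cvse[k_min]
    lambda_1se = float(lambdas[np.nonzero(within)[0][0]])  # path is decreasing

    # Final fit on all data; back-transform to the original scale.
    coefs = _fit_path(xs, y, offset, pfk, lambdas, unpen_idx, cfg.max_iter, cfg.tol)
    coef_orig = np.zeros((p, cfg.n_lambda))
    coef_orig[keep, :] = coefs[1:] / scales[:, None]
    intercept = coefs[0] - means @ (coefs[1:] / scales[:, None])

    return LassoResult(
        feature_names=feature_names,
        lambdas=lambdas,
        coef=coef_orig,
        intercept=intercept,
        penalty_factor=pf,
        cv_mean_deviance=cvm,
        cv_se_deviance=cvse,
        lambda_min=lambda_min,
        lambda_1se=lambda_1se,
        selection_rule=cfg.selection_rule,
    )
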