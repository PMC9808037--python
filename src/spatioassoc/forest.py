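"""Case-weighted random-forest regression of visit rates on exposures.

The forest regresses the per-zip rate (cases/total) on the feature matrix
with per-zip case weights (default: total visits), so populous zips with
many billable visits — whose observed rates are less noisy — dominate the
loss, mirroring the Poisson model's implicit precision weighting.

Feature relevance is scored by out-of-bag permutation importance: for each
tree, the increase in case-weighted squared error on the tree's out-of-bag
zips when one feature column is shuffled, averaged over trees (and over
``n_permutations`` shuffles). This is flexible to nonlinear and interacting
exposure effects that a linear-in-exposure lasso cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap

_TREE_DTYPE = np.float32  # input dtype expected by sklearn's tree predict

from .config import ForestConfig

__all__ = ["ForestResult", "fit_random_forest"]


@dataclass
class ForestResult:
    """Permutation importances, their ranks, and the out-of-bag error."""

    feature_names: list[str]
    importances: np.ndarray  # mean OOB increase in case-weighted MSE
    oob_error: float  # case-weighted MSE of aggregated OOB predictions
    n_trees: int
    mtry: int

    def importance_series(self) -> pd.Series:
        return pd.Series(self.importances, index=self.feature_names).sort_values(
            ascending=False
        )

    def ranks(self) -> pd.Series:
        """Rank per feature, 1 = most important."""
        order = np.argsort(-self.importances, kind="stable")
        r = np.empty(len(order), dtype=int)
        r[order] = np.arange(1, len(order) + 1)
        return pd.Series(r, index=self.feature_names)


def _weighted_mse(y, pred, w):
    return float(np.average((y - pred) ** 2, weights=w))


def fit_random_forest(
    X: pd.DataFrame | np.ndarray,
    rates: np.ndarray,
    cfg: ForestConfig | None = None,
    case_weights: np.ndarray | None = None,
) -> ForestResult:
    """Fit the forest and compute OOB permutation importances.

    Parameters
    ----------
    X:
        Zip-by-feature matrix (pollutant exposures plus covariates).
    rates:
        Observed rates cases/total, aligned with ``X``.
    cfg:
        ``mtry`` defaults to floor(p/3); ``seed`` fixes both tree growing and
        the permutation shuffles, making importances reproducible.
    case_weights:
        Per-zip nonnegative weights; default all-ones if not given (the
        pipeline passes total visits).
    """
    cfg = cfg or ForestConfig()
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        xmat = X.to_numpy(dtype=float)
    else:
        xmat = np.asarray(X, dtype=float)
        feature_names = [f"x{j}" for j in range(xmat.shape[1])]
    n, p = xmat.shape
    if p == 0:
        raise ValueError("X must have at least one feature")
    cfg.validate(n_features=p)
    y = np.asarray(rates, dtype=float)
    w = np.ones(n) if case_weights is None else np.asarray(case_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("case weights must be nonnegative")
    mtry = cfg.mtry if cfg.mtry is not None else max(1, p // 3)

    forest = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=mtry,
        bootstrap=True,
        random_state=cfg.seed % 2**31,
        n_jobs=1,
    )
    forest.fit(xmat, y, sample_weight=w)

    xf = np.ascontiguousarray(xmat, dtype=_TREE_DTYPE)
    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, w)
    rng = np.random.default_rng(cfg.seed)

    imp = np.zeros(p)
    n_used = 0
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    for tree in forest.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, w)
        if len(oob) == 0:
            continue
        n_used += 1
        block = xf[oob]
        base_pred = tree.tree_.predict(block).ravel()
        oob_sum[oob] += base_pred
        oob_cnt[oob] += 1
        err0 = _weighted_mse(y[oob], base_pred, w[oob])
        for j in range(p):
            saved = block[:, j].copy()
            for _ in range(cfg.n_permutations):
                block[:, j] = saved[rng.permutation(len(oob))]
                pred = tree.tree_.predict(block).ravel()
                imp[j] += (_weighted_mse(y[oob], pred, w[oob]) - err0) / cfg.n_permutations
            block[:, j] = saved
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples; increase n or n_trees")
    imp /= n_used

    seen = oob_cnt > 0
    oob_error = _weighted_mse(y[seen], oob_sum[seen] / oob_cnt[seen], w[seen])

    return ForestResult(
        feature_names=feature_names,
        importances=imp,
        oob_error=oob_error,
        n_trees=cfg.n_trees,
        mtry=mtry,
    )
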