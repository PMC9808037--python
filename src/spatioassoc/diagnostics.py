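"""Collinearity and dose-response diagnostics.

Percentile dose-response tables summarize how the pooled visit rate
(sum of cases / sum of totals, i.e. visit-weighted) moves across equal-count
exposure quantile bins — the tabular form of a percentile plot. The
correlogram is the pairwise Pearson correlation matrix of the aggregated
pollutant exposures over covered zips, which exposes collinear exposure
mixtures (e.g. traffic-related CO/NO2). The monotonic trend score condenses
a dose-response table into a single Spearman correlation between bin index
and bin rate, a quantitative stand-in for judging a percentile plot by eye.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percentile_dose_response",
    "pollutant_correlogram",
    "monotonic_trend_score",
]

logger = logging.getLogger(__name__)


def percentile_dose_response(
    exposure: np.ndarray,
    cases: np.ndarray,
    total: np.ndarray,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Visit-weighted rate per equal-count exposure quantile bin.

    Zips are ranked by exposure (ties broken by stable input order) and split
    into ``n_bins`` bins whose sizes differ by at most one; ``n_bins`` is
    reduced with a warning when there are fewer zips than bins. Each row
    holds the percentile interval, mean exposure, pooled rate
    ``sum(cases)/sum(total)`` and zip count of one bin.
    """
    exposure = np.asarray(exposure, dtype=float)
    cases = np.asarray(cases, dtype=float)
    total = np.asarray(total, dtype=float)
    n = len(exposure)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > n:
        logger.warning("n_bins=%d exceeds %d zips; reduced", n_bins, n)
        n_bins = n
    order = np.argsort(exposure, kind="stable")
    chunks = np.array_split(order, n_bins)
    edges = np.linspace(0, 100, n_bins + 1)
    rows = []
    for b, idx in enumerate(chunks):
        rows.append(
            {
                "bin": b + 1,
                "pct_low": edges[b],
                "pct_high": edges[b + 1],
                "mean_exposure": float(exposure[idx].mean()),
                "rate": float(cases[idx].sum() / total[idx].sum()),
                "n_zips": len(idx),
            }
        )
    return pd.DataFrame(rows)


def pollutant_correlogram(exposure: pd.DataFrame, pollutants: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations of zip-level exposures.

    ``exposure`` is the aggregation output; zips without coverage are dropped
    listwise. Zero-variance pollutants yield NaN entries with a warning.
    """
    if pollutants is None:
        pollutants = [
            c
            for c in exposure.columns
            if c not in ("zip_id", "n_contributing_tracts", "coverage")
        ]
    if len(pollutants) < 2:
        raise ValueError("need at least 2 pollutants for a correlogram")
    sub = exposure
    if "coverage" in exposure.columns:
        sub = exposure[exposure["coverage"]]
    vals = sub[pollutants].dropna()
    if len(vals) < 3:
        raise ValueError("need at least 3 covered zips")
    sd = vals.std(ddof=0)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        logger.warning("zero-variance pollutant(s), correlation undefined: %s", degenerate)
    corr = vals.corr(method="pearson")  # pandas leaves NaN for zero variance
    return corr


def monotonic_trend_score(dose_response: pd.DataFrame) -> float:
    """Spearman correlation of bin index vs bin rate, in [-1, 1].

    Positive values indicate a monotone increasing dose-response gradient
    across exposure percentiles; constant bin rates return 0 by convention.
    """
    if len(dose_response) < 3:
        raise ValueError("need at least 3 bins for a trend score")
    rates = dose_response["rate"].to_numpy(dtype=float)
    if np.all(rates == rates[0]):
        return 0.0
    rho = stats.spearmanr(dose_response["bin"].to_numpy(), rates).statistic
    return float(rho)
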