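"""Tract-to-zip exposure aggregation.

Each zip-code area's exposure to a pollutant is the weighted mean of the
concentrations in the census tracts within a fixed radius (default 50 miles)
of its centroid, weighted by tract population divided by distance:

    w_it = pop_t / max(d_it, floor)   for d_it <= radius, row-normalized.

The 1-mile distance floor keeps the weight finite when a tract centroid
coincides with the zip centroid. Zips with no tract inside the radius get a
missing value and ``coverage = False``; they are reported, not imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import AggregationConfig
from .geo import radius_pairs
from .weights import SpatialWeights

__all__ = ["AggregationConfig", "build_aggregation_weights", "aggregate_exposures"]

logger = logging.getLogger(__name__)


def build_aggregation_weights(
    tracts: pd.DataFrame, zips: pd.DataFrame, cfg: AggregationConfig | None = None
) -> SpatialWeights:
    """Population x inverse-distance weights of tracts onto zips.

    Returns a sparse row-normalized :class:`SpatialWeights` keyed by zip;
    zips with no tract within ``cfg.radius`` have an empty row.
    """
    cfg = cfg or AggregationConfig()
    cfg.validate()
    pop = tracts["population"].to_numpy(dtype=float)

    i, j, d = radius_pairs(
        zips["lon"].to_numpy(dtype=float),
        zips["lat"].to_numpy(dtype=float),
        tracts["lon"].to_numpy(dtype=float),
        tracts["lat"].to_numpy(dtype=float),
        cfg.radius,
    )
    w = pop[j] / np.maximum(d, cfg.distance_floor)
    mat = sp.csr_matrix((w, (i, j)), shape=(len(zips), len(tracts)))

    # Row-normalize where any tract qualifies.
    sums = np.asarray(mat.sum(axis=1)).ravel()
    inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    mat = sp.diags(inv) @ mat

    return SpatialWeights(
        row_ids=zips["zip_id"].astype(str).tolist(),
        col_ids=tracts["tract_id"].astype(str).tolist(),
        matrix=mat.tocsr(),
        scheme="population_times_inverse_distance",
        params={"radius": cfg.radius, "distance_floor": cfg.distance_floor},
    )


def aggregate_exposures(
    tracts: pd.DataFrame,
    zips: pd.DataFrame,
    cfg: AggregationConfig | None = None,
    pollutants: list[str] | None = None,
) -> pd.DataFrame:
    """Weighted-mean pollutant exposure per zip.

    Returns a DataFrame with ``zip_id``, one column per pollutant (NaN where
    no tract is in range), ``n_contributing_tracts`` and a boolean
    ``coverage`` flag.
    """
    from .synthetic import pollutant_columns  # circular at module level

    cfg = cfg or AggregationConfig()
    if pollutants is None:
        pollutants = pollutant_columns(tracts)
    missing = [c for c in pollutants if c not in tracts.columns]
    if missing:
        raise KeyError(f"pollutant column(s) absent from tract table: {missing}")

    weights = build_aggregation_weights(tracts, zips, cfg)
    conc = tracts[pollutants].to_numpy(dtype=float)
    agg = weights.matrix @ conc

    n_contrib = weights.n_neighbors
    coverage = n_contrib > 0
    agg[~coverage, :] = np.nan
    n_uncovered = int((~coverage).sum())
    if n_uncovered:
        logger.warning(
            "%d of %d zips have no tract within %.1f miles; exposures set to NaN",
            n_uncovered,
            len(zips),
            cfg.radius,
        )

    out = pd.DataFrame({"zip_id": zips["zip_id"].astype(str)})
    for k, name in enumerate(pollutants):
        out[name] = agg[:, k]
    out["n_contributing_tracts"] = n_contrib
    out["coverage"] = coverage
    return out
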