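"""Spatial regression features: lagged-outcome autocovariate and spatial folds.

The autocovariate absorbs residual spatial autocorrelation in an ecological
regression: for each zip it is the inverse-distance-weighted mean of the
*observed* visit rates of neighboring zips within a radius (self excluded).
Spatial cross-validation folds are k-means clusters of the zip centroids in
a local planar projection, so held-out zips are geographically blocked from
the training zips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .config import ConfigurationError
from .geo import project_local, radius_pairs
from .weights import SpatialWeights

__all__ = ["FoldAssignment", "build_lag_weights", "autocovariate", "spatial_folds"]

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """Partition of zips into k spatial folds (k-means cluster labels)."""

    zip_ids: list[str]
    labels: np.ndarray  # fold label per zip, values in {1..k}
    k: int
    seed: int
    centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.zip_ids):
            raise ValueError("labels must align with zip_ids")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError("fold labels must cover {1..k} with every fold nonempty")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"zip_id": self.zip_ids, "fold": self.labels})


def build_lag_weights(
    zips: pd.DataFrame, neighbor_radius: float = 50.0, distance_floor: float = 1.0
) -> SpatialWeights:
    """Row-normalized inverse-distance weights between zips, no self-loops."""
    if neighbor_radius <= 0:
        raise ConfigurationError("neighbor_radius must be > 0")
    lon = zips["lon"].to_numpy(dtype=float)
    lat = zips["lat"].to_numpy(dtype=float)
    n = len(zips)
    i, j, d = radius_pairs(lon, lat, lon, lat, neighbor_radius)
    off_diag = i != j  # exclude self-neighbors
    i, j, d = i[off_diag], j[off_diag], d[off_diag]
    w = 1.0 / np.maximum(d, distance_floor)
    mat = sp.csr_matrix((w, (i, j)), shape=(n, n))
    sums = np.asarray(mat.sum(axis=1)).ravel()
    inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    mat = (sp.diags(inv) @ mat).tocsr()
    ids = zips["zip_id"].astype(str).tolist()
    return SpatialWeights(
        row_ids=ids,
        col_ids=ids,
        matrix=mat,
        scheme="inverse_distance_lag",
        params={"neighbor_radius": neighbor_radius, "distance_floor": distance_floor},
    )


def autocovariate(
    zips: pd.DataFrame,
    rates: np.ndarray,
    neighbor_radius: float = 50.0,
    distance_floor: float = 1.0,
) -> np.ndarray:
    """Spatially lagged outcome: inverse-distance mean of neighbor rates.

    Zips with no neighbor inside the radius receive the global mean rate
    (logged); an all-isolated geography triggers a warning.
    """
    rates = np.asarray(rates, dtype=float)
    if len(rates) != len(zips):
        raise ValueError("rates must align with zips")
    weights = build_lag_weights(zips, neighbor_radius, distance_floor)
    ac = weights.matrix @ rates
    isolated = weights.n_neighbors == 0
    if isolated.all():
        logger.warning("every zip is isolated at radius %.1f; autocovariate = global mean", neighbor_radius)
    elif isolated.any():
        logger.info("%d isolated zips assigned the global mean rate", int(isolated.sum()))
    ac[isolated] = rates.mean()
    return ac


def spatial_folds(zips: pd.DataFrame, k: int = 10, seed: int = 0) -> FoldAssignment:
    """k-means spatial blocking of zip centroids.

    Clustering runs on planar coordinates from a local equirectangular
    projection (Euclidean distance ~ miles). Deterministic given ``seed``;
    an empty cluster (possible only with heavy coordinate duplication) is
    retried with a derived sub-seed up to 10 times.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2 for cross-validation")
    if len(zips) < k:
        raise ConfigurationError(f"need at least k={k} zips, got {len(zips)}")
    xy = project_local(zips["lon"].to_numpy(float), zips["lat"].to_numpy(float))
    for attempt in range(10):
        km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=(seed + attempt) % 2**31)
        labels = km.fit_predict(xy)
        if len(np.unique(labels)) == k:
            return FoldAssignment(
                zip_ids=zips["zip_id"].astype(str).tolist(),
                labels=labels + 1,
                k=k,
                seed=seed,
                centers=km.cluster_centers_,
            )
    raise RuntimeError("k-means produced an empty cluster in 10 restarts")
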