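"""Great-circle geometry helpers.

All distances in this package are statute miles on a sphere of radius
3958.8 miles, computed with the haversine formula. A small local
equirectangular projection is provided for planar algorithms (k-means
spatial blocking) where Euclidean distance should approximate miles.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_MILES = 3958.8

__all__ = [
    "EARTH_RADIUS_MILES",
    "great_circle_distance",
    "pairwise_distances",
    "radius_pairs",
    "project_local",
]


def _check_lonlat(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not np.all(np.isfinite(lon)) or not np.all(np.isfinite(lat)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")


def great_circle_distance(a, b) -> float | np.ndarray:
    """Haversine distance in miles between points ``a`` and ``b``.

    Parameters
    ----------
    a, b
        ``(lon, lat)`` pairs in decimal degrees; either may be an array of
        shape ``(n, 2)`` for elementwise distances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_lonlat(a[..., 0], a[..., 1])
    _check_lonlat(b[..., 0], b[..., 1])
    d = _haversine_miles(
        np.radians(a[..., 0]), np.radians(a[..., 1]), np.radians(b[..., 0]), np.radians(b[..., 1])
    )
    return float(d) if np.ndim(d) == 0 else d


def pairwise_distances(lon_a, lat_a, lon_b, lat_b) -> np.ndarray:
    """All-pairs haversine distances, shape ``(len(a), len(b))`` miles."""
    _check_lonlat(lon_a, lat_a)
    _check_lonlat(lon_b, lat_b)
    return _haversine_miles(
        np.radians(np.asarray(lon_a, dtype=float))[:, None],
        np.radians(np.asarray(lat_a, dtype=float))[:, None],
        np.radians(np.asarray(lon_b, dtype=float))[None, :],
        np.radians(np.asarray(lat_b, dtype=float))[None, :],
    )


def _haversine_miles(lon1, lat1, lon2, lat2):
    """Elementwise haversine on radian inputs; the single shared kernel so
    every distance in the package is bitwise-consistent."""
    h = np.sin((lat2 - lat1) / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(
        (lon2 - lon1) / 2.0
    ) ** 2
    return 2.0 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def radius_pairs(
    lon_a, lat_a, lon_b, lat_b, radius: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All pairs (i, j) with great-circle distance <= ``radius`` miles.

    Candidate pairs come from a KD-tree on 3-D unit-sphere coordinates
    (chord-length bound), then exact haversine distances are computed for
    the candidates only, so results match an all-pairs haversine scan while
    scaling to large point sets. Returns ``(i, j, d)`` arrays.
    """
    from scipy.spatial import cKDTree

    _check_lonlat(lon_a, lat_a)
    _check_lonlat(lon_b, lat_b)
    lon_a = np.atleast_1d(np.asarray(lon_a, dtype=float))
    lat_a = np.atleast_1d(np.asarray(lat_a, dtype=float))
    lon_b = np.atleast_1d(np.asarray(lon_b, dtype=float))
    lat_b = np.atleast_1d(np.asarray(lat_b, dtype=float))

    def xyz(lon, lat):
        lam, phi = np.radians(lon), np.radians(lat)
        return np.column_stack(
            [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
        )

    half_angle = min(radius / (2.0 * EARTH_RADIUS_MILES), np.pi / 2.0)
    chord = 2.0 * np.sin(half_angle) * (1.0 + 1e-12) + 1e-12
    tree = cKDTree(xyz(lon_b, lat_b))
    hits = tree.query_ball_point(xyz(lon_a, lat_a), chord)
    i = np.repeat(np.arange(len(lon_a)), [len(h) for h in hits])
    j = np.concatenate([np.sort(h) for h in hits]) if len(i) else np.array([], dtype=int)
    j = j.astype(int)
    d = _haversine_miles(
        np.radians(lon_a[i]), np.radians(lat_a[i]), np.radians(lon_b[j]), np.radians(lat_b[j])
    )
    keep = d <= radius
    return i[keep], j[keep], d[keep]


def project_local(lon, lat, origin: tuple[float, float] | None = None) -> np.ndarray:
    """Equirectangular projection to planar coordinates in miles.

    Projects about ``origin`` (default: the centroid of the points), so that
    Euclidean distance approximates great-circle miles over regional extents.
    Returns an ``(n, 2)`` array of (x, y) miles.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    _check_lonlat(lon, lat)
    if origin is None:
        origin = (float(lon.mean()), float(lat.mean()))
    lon0, lat0 = origin
    mile_per_deg = np.pi / 180.0 * EARTH_RADIUS_MILES
    x = (lon - lon0) * np.cos(np.radians(lat0)) * mile_per_deg
    y = (lat - lat0) * mile_per_deg
    return np.column_stack([x, y])
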