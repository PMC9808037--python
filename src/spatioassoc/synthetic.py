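"""Synthetic region generator with known causal structure.

Emulates the two flat tables the real analysis consumes — tract-level
pollutant concentrations with population, and zip-level psoriasis/total visit
counts with ecological covariates — on a fictitious region where the data
generating process is fully known:

* pollutant concentrations are smooth spatial fields (Gaussian kernel
  smoothing of random knot weights) linearly mixed so that their *realized*
  tract-level sample correlation matches the requested matrix exactly
  (latent fields are empirically orthonormalized before mixing);
* zip outcome counts follow ``cases_i ~ Poisson(total_i * exp(eta_i))``
  truncated at ``total_i``, with ``eta`` a log-linear function of the
  zip-aggregated standardized exposures, standardized covariates, and a
  zip-level random effect (unstructured by default, optionally a smooth
  spatial field);
* the realized effects, exposures and random effects are returned as a
  :class:`GroundTruth` so downstream models can be scored by recovery.

Covariates are smooth spatial fields plus independent noise, so nonzero
``covariate_effects`` turn them into spatial confounders.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import COVARIATE_NAMES, RegionConfig
from .exposure import AggregationConfig, aggregate_exposures
from .geo import project_local

__all__ = [
    "GroundTruth",
    "generate_region",
    "write_region",
    "read_tracts",
    "read_zips",
    "pollutant_columns",
    "validate_tracts",
    "validate_zips",
    "region_to_geojson",
]

TRACT_BASE_COLUMNS = ["tract_id", "lon", "lat", "population"]
ZIP_BASE_COLUMNS = ["zip_id", "lon", "lat", "cases", "total"]

_N_KNOTS = 250  # knot count for kernel-smoothed latent fields


@dataclass
class GroundTruth:
    """Realized generative quantities needed to score recovery."""

    causal_index_set: tuple[int, ...]
    beta: tuple[float, ...]
    beta0: float
    covariate_effects: tuple[float, ...]
    effect_shape: str
    spatial_random_effect: np.ndarray  # per zip, log-rate scale
    exposure_std: np.ndarray  # zip x pollutant standardized exposures used
    pollutant_names: tuple[str, ...]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["spatial_random_effect"] = self.spatial_random_effect.tolist()
        d["exposure_std"] = self.exposure_std.tolist()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["causal_index_set"] = tuple(d["causal_index_set"])
        d["beta"] = tuple(d["beta"])
        d["covariate_effects"] = tuple(d["covariate_effects"])
        d["pollutant_names"] = tuple(d["pollutant_names"])
        d["spatial_random_effect"] = np.asarray(d["spatial_random_effect"])
        d["exposure_std"] = np.asarray(d["exposure_std"])
        return cls(**d)


def pollutant_columns(tracts: pd.DataFrame) -> list[str]:
    """Pollutant concentration columns of a tract table (schema order)."""
    return [c for c in tracts.columns if c not in TRACT_BASE_COLUMNS]


def validate_tracts(tracts: pd.DataFrame) -> None:
    missing = [c for c in TRACT_BASE_COLUMNS if c not in tracts.columns]
    if missing:
        raise ValueError(f"tract table missing columns: {missing}")
    if tracts["tract_id"].duplicated().any():
        raise ValueError("tract_id values must be unique")
    if len(tracts):
        if tracts["lat"].abs().max() > 90 or tracts["lon"].abs().max() > 180:
            raise ValueError("tract coordinates out of range")
        if (tracts["population"] < 0).any():
            raise ValueError("population must be nonnegative")
        conc = tracts[pollutant_columns(tracts)]
        if len(conc.columns) and (conc.to_numpy() < 0).any():
            raise ValueError("concentrations must be nonnegative")


def validate_zips(zips: pd.DataFrame) -> None:
    missing = [c for c in ZIP_BASE_COLUMNS if c not in zips.columns]
    if missing:
        raise ValueError(f"zip table missing columns: {missing}")
    if zips["zip_id"].duplicated().any():
        raise ValueError("zip_id values must be unique")
    if len(zips):
        if zips["lat"].abs().max() > 90 or zips["lon"].abs().max() > 180:
            raise ValueError("zip coordinates out of range")
        if (zips["total"] <= 0).any():
            raise ValueError("total visits must be positive")
        if (zips["cases"] < 0).any() or (zips["cases"] > zips["total"]).any():
            raise ValueError("cases must satisfy 0 <= cases <= total")
        for col in ("age_0_17", "age_18_39", "age_40_64", "specialist_prop"):
            if col in zips.columns and not zips[col].between(0, 1).all():
                raise ValueError(f"{col} proportions must lie in [0, 1]")


def _uniform_points(rng: np.random.Generator, n: int, bbox) -> tuple[np.ndarray, np.ndarray]:
    lon_min, lon_max, lat_min, lat_max = bbox
    lon = rng.uniform(lon_min, lon_max, n)
    lat = rng.uniform(lat_min, lat_max, n)
    return lon, lat


def _smooth_fields(
    rng: np.random.Generator,
    xy: np.ndarray,
    knots_xy: np.ndarray,
    length_scale: float,
    n_fields: int,
) -> np.ndarray:
    """Standardized smooth spatial fields: Gaussian-kernel smoothing of
    iid knot weights, one column per field."""
    d2 = ((xy[:, None, :] - knots_xy[None, :, :]) ** 2).sum(axis=2)
    k = np.exp(-0.5 * d2 / length_scale**2)
    z = rng.standard_normal((knots_xy.shape[0], n_fields))
    f = k @ z
    f -= f.mean(axis=0)
    sd = f.std(axis=0)
    sd[sd == 0] = 1.0
    return f / sd

def _mix_to_correlation(fields: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Linearly mix independent latent fields so the realized sample
    correlation equals ``corr`` exactly.

    The centered latent fields are orthonormalized (QR), which removes the
    incidental sample correlation between smooth fields — substantial when
    the autocorrelation range is large relative to the region — then mixed
    by a symmetric square root of the target matrix.
    """
    n, p = fields.shape
    if n <= p:
        # Too few points to orthonormalize; fall back to plain mixing.
        z = fields - fields.mean(axis=0)
    else:
        q, r = np.linalg.qr(fields - fields.mean(axis=0))
        q *= np.sign(np.diag(r))  # deterministic sign convention
        z = q * np.sqrt(n - 1)
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    return z @ root


def generate_region(config: RegionConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a synthetic (tracts, zips, truth) triple.

    Deterministic: the same ``config`` (including seed) reproduces the same
    tables bit-for-bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_pollutants
    pollutant_names = tuple(f"pollutant_{j + 1}" for j in range(p))

    # --- tract table ---------------------------------------------------
    t_lon, t_lat = _uniform_points(rng, config.n_tracts, config.bbox)
    population = np.exp(rng.normal(8.0, 0.7, config.n_tracts))

    origin = (
        (config.bbox[0] + config.bbox[1]) / 2.0,
        (config.bbox[2] + config.bbox[3]) / 2.0,
    )
    t_xy = project_local(t_lon, t_lat, origin)
    lon_min, lon_max, lat_min, lat_max = config.bbox
    k_lon = rng.uniform(lon_min, lon_max, _N_KNOTS)
    k_lat = rng.uniform(lat_min, lat_max, _N_KNOTS)
    knots_xy = project_local(k_lon, k_lat, origin)

    latent = _smooth_fields(rng, t_xy, knots_xy, config.field_length_scale, p)
    mixed = _mix_to_correlation(latent, config.corr_matrix())
    # Affine per-column transform to nonnegative concentrations; Pearson
    # correlation is invariant to it, so the realized correlation survives.
    scales = np.exp(rng.normal(0.0, 0.5, p))
    conc = (mixed - mixed.min(axis=0)) * scales

    tracts = pd.DataFrame(
        {
            "tract_id": [f"T{i:06d}" for i in range(config.n_tracts)],
            "lon": t_lon,
            "lat": t_lat,
            "population": population,
        }
    )
    for j, name in enumerate(pollutant_names):
        tracts[name] = conc[:, j]

    # --- zip table ------------------------------------------------------
    z_lon, z_lat = _uniform_points(rng, config.n_zips, config.bbox)
    z_xy = project_local(z_lon, z_lat, origin)
    n_cov = len(COVARIATE_NAMES)
    cov_smooth = _smooth_fields(rng, z_xy, knots_xy, config.field_length_scale, n_cov)
    cov_noise = rng.standard_normal((config.n_zips, n_cov))
    cov_latent = (0.7 * cov_smooth + 0.3 * cov_noise) / np.sqrt(0.7**2 + 0.3**2)

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-x))

    covariates = pd.DataFrame(
        {
            "pop_density": np.exp(6.0 + 1.2 * cov_latent[:, 0]),
            "age_0_17": 0.22 + 0.10 * (logistic(cov_latent[:, 1]) - 0.5),
            "age_18_39": 0.30 + 0.12 * (logistic(cov_latent[:, 2]) - 0.5),
            "age_40_64": 0.26 + 0.10 * (logistic(cov_latent[:, 3]) - 0.5),
            "adi": 50.0 + 20.0 * np.tanh(cov_latent[:, 4]),
            "specialist_prop": 0.15 + 0.10 * (logistic(cov_latent[:, 5]) - 0.5),
        }
    )

    totals = np.maximum(
        1,
        np.round(
            np.exp(rng.normal(config.total_visits_log_mean, config.total_visits_log_sd, config.n_zips))
        ).astype(np.int64),
    )

    if config.spatial_re_structure == "smooth":
        re_field = _smooth_fields(rng, z_xy, knots_xy, config.field_length_scale, 1)[:, 0]
    else:
        re_field = rng.standard_normal(config.n_zips)
    spatial_re = config.spatial_re_sd * re_field

    zips = pd.DataFrame(
        {"zip_id": [f"Z{i:05d}" for i in range(config.n_zips)], "lon": z_lon, "lat": z_lat}
    )
    # Aggregate the pollutant fields to zip level with the default scheme so
    # the planted effect acts on the same exposure scale the models see.
    zips_geo = zips.copy()
    exposure = aggregate_exposures(tracts, zips_geo, AggregationConfig())
    x = exposure[list(pollutant_names)].to_numpy(dtype=float)
    # Uncovered zips (possible only in tiny configs) get the column mean,
    # i.e. zero exposure signal after standardization.
    col_mean = np.nanmean(x, axis=0)
    nan_rows = np.isnan(x)
    x[nan_rows] = np.take(col_mean, np.nonzero(nan_rows)[1])
    x_std = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))

    cov_std = covariates.to_numpy(dtype=float)
    cov_std = (cov_std - cov_std.mean(axis=0)) / np.where(
        cov_std.std(axis=0) == 0, 1.0, cov_std.std(axis=0)
    )

    eta = np.full(config.n_zips, config.beta0, dtype=float)
    for b, j in zip(config.beta, config.causal_index_set):
        if config.effect_shape == "threshold":
            eta += b * (x_std[:, j] > np.median(x_std[:, j])).astype(float)
        else:
            eta += b * x_std[:, j]
    eta += cov_std @ np.asarray(config.covariate_effects, dtype=float)
    eta += spatial_re

    mu = totals * np.exp(eta)
    cases = np.minimum(rng.poisson(mu), totals).astype(np.int64)

    zips["cases"] = cases
    zips["total"] = totals
    for name in COVARIATE_NAMES:
        zips[name] = covariates[name]

    truth = GroundTruth(
        causal_index_set=tuple(config.causal_index_set),
        beta=tuple(config.beta),
        beta0=config.beta0,
        covariate_effects=tuple(config.covariate_effects),
        effect_shape=config.effect_shape,
        spatial_random_effect=spatial_re,
        exposure_std=x_std,
        pollutant_names=pollutant_names,
    )
    validate_tracts(tracts)
    validate_zips(zips)
    return tracts, zips, truth


def write_region(
    tracts: pd.DataFrame,
    zips: pd.DataFrame,
    path: str | Path,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write ``tracts.csv``/``zips.csv`` (and ``truth.json``) under ``path``.

    CSV schemas match the real-data input exactly; a write/read round trip
    reproduces the tables value-for-value.
    """
    validate_tracts(tracts)
    validate_zips(zips)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {
        "tracts": path / "tracts.csv",
        "zips": path / "zips.csv",
    }
    tracts.to_csv(out["tracts"], index=False)
    zips.to_csv(out["zips"], index=False)
    if truth is not None:
        out["truth"] = path / "truth.json"
        out["truth"].write_text(truth.to_json())
    return out


def read_tracts(path: str | Path) -> pd.DataFrame:
    tracts = pd.read_csv(path, dtype={"tract_id": str})
    validate_tracts(tracts)
    return tracts


def read_zips(path: str | Path) -> pd.DataFrame:
    zips = pd.read_csv(path, dtype={"zip_id": str})
    validate_zips(zips)
    return zips


def region_to_geojson(table: pd.DataFrame, id_column: str) -> dict:
    """Point FeatureCollection for either table (optional export format)."""
    features = []
    props = [c for c in table.columns if c not in (id_column, "lon", "lat")]
    for _, row in table.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row["lon"], row["lat"]]},
                "properties": {id_column: row[id_column], **{c: row[c] for c in props}},
            }
        )
    return {"type": "FeatureCollection", "features": features}
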