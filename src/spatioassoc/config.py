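"""Configuration objects for every pipeline stage.

Defaults encode the analysis constants: a 50-mile exposure radius with a
1-mile distance floor, 10 spatial cross-validation folds, a 100-point lasso
lambda path, and a 1000-tree forest with mtry = p/3 and case weights equal
to total visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RegionConfig",
    "AggregationConfig",
    "LassoConfig",
    "ForestConfig",
    "PipelineConfig",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


# Covariates emitted by the synthetic generator, in column order. They emulate
# the ecological covariates of the real extract: population density, bracketed
# age-range proportions, an area deprivation score, and the proportion of
# visits made to specialists.
COVARIATE_NAMES = (
    "pop_density",
    "age_0_17",
    "age_18_39",
    "age_40_64",
    "adi",
    "specialist_prop",
)


def _exchangeable_corr(p: int, rho: float) -> np.ndarray:
    m = np.full((p, p), float(rho))
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class RegionConfig:
    """Parameters of the synthetic tract/zip region generator.

    The generator plants a known log-linear Poisson outcome model on top of
    spatially autocorrelated, cross-correlated pollutant fields so that every
    downstream stage can be checked by parameter recovery.

    Attributes
    ----------
    n_tracts, n_zips:
        Numbers of exposure source units (census tracts) and outcome units
        (zip-code areas), both as centroid points.
    bbox:
        ``(lon_min, lon_max, lat_min, lat_max)`` in decimal degrees.
    n_pollutants:
        Number of pollutant concentration fields.
    field_length_scale:
        Spatial autocorrelation range of the latent fields, miles.
    pollutant_corr:
        Target cross-pollutant correlation matrix (unit diagonal, PSD), or a
        scalar for an exchangeable matrix.
    causal_index_set:
        Indices of pollutants with a planted effect on the outcome.
    beta:
        Log-rate effect per 1 SD of aggregated exposure, one entry per causal
        pollutant (aligned with ``causal_index_set``).
    beta0:
        Baseline log rate (log cases per billable visit).
    covariate_effects:
        Log-rate effects of the standardized covariates (len 6, see
        ``COVARIATE_NAMES``).
    effect_shape:
        ``"linear"`` or ``"threshold"``; threshold applies ``beta`` times an
        indicator that the standardized exposure is above its median.
    spatial_re_sd:
        Standard deviation of the zip-level random effect on the log rate.
    spatial_re_structure:
        ``"iid"`` for unstructured zip-level heterogeneity (the unstructured
        component of a disease-mapping model) or ``"smooth"`` for a spatially
        autocorrelated field with range ``field_length_scale``.
    total_visits_log_mean, total_visits_log_sd:
        Lognormal parameters of total billable visits per zip.
    """

    n_tracts: int = 8000
    n_zips: int = 1500
    bbox: tuple[float, float, float, float] = (-100.0, -93.0, 35.0, 41.0)
    n_pollutants: int = 10
    field_length_scale: float = 30.0
    pollutant_corr: float | np.ndarray = 0.6
    causal_index_set: tuple[int, ...] = (0,)
    beta: tuple[float, ...] = (0.5,)
    beta0: float = -5.5
    covariate_effects: tuple[float, ...] = (0.10, 0.0, 0.0, 0.0, 0.05, 0.0)
    effect_shape: str = "linear"
    spatial_re_sd: float = 0.2
    spatial_re_structure: str = "iid"
    total_visits_log_mean: float = 7.6
    total_visits_log_sd: float = 0.8
    seed: int = 0

    def corr_matrix(self) -> np.ndarray:
        if np.isscalar(self.pollutant_corr):
            m = _exchangeable_corr(self.n_pollutants, float(self.pollutant_corr))
        else:
            m = np.asarray(self.pollutant_corr, dtype=float)
        return m

    def validate(self) -> None:
        if self.n_tracts < 1 or self.n_zips < 1 or self.n_pollutants < 1:
            raise ConfigurationError("counts must be >= 1")
        lon_min, lon_max, lat_min, lat_max = self.bbox
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ConfigurationError("bbox is degenerate")
        m = self.corr_matrix()
        if m.shape != (self.n_pollutants, self.n_pollutants):
            raise ConfigurationError("pollutant_corr has wrong shape")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
            raise ConfigurationError("pollutant_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ConfigurationError("pollutant_corr must be positive semidefinite")
        if any(j < 0 or j >= self.n_pollutants for j in self.causal_index_set):
            raise ConfigurationError("causal_index_set out of range")
        if len(self.beta) != len(self.causal_index_set):
            raise ConfigurationError("beta must align with causal_index_set")
        if len(self.covariate_effects) != len(COVARIATE_NAMES):
            raise ConfigurationError(
                f"covariate_effects must have length {len(COVARIATE_NAMES)}"
            )
        if self.effect_shape not in ("linear", "threshold"):
            raise ConfigurationError("effect_shape must be 'linear' or 'threshold'")
        if self.spatial_re_sd < 0:
            raise ConfigurationError("spatial_re_sd must be >= 0")
        if self.spatial_re_structure not in ("iid", "smooth"):
            raise ConfigurationError("spatial_re_structure must be 'iid' or 'smooth'")
        if self.field_length_scale <= 0:
            raise ConfigurationError("field_length_scale must be > 0")


@dataclass
class AggregationConfig:
    """Radius-limited population x inverse-distance exposure aggregation.

    ``weight_form`` is a tag for provenance; the only implemented form is
    ``population_times_inverse_distance``: w_it = pop_t / max(d_it, floor)
    for d_it <= radius, row-normalized.
    """

    radius: float = 50.0
    distance_floor: float = 1.0
    weight_form: str = "population_times_inverse_distance"

    def validate(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("radius must be > 0")
        if self.distance_floor <= 0:
            raise ConfigurationError("distance_floor must be > 0")
        if self.weight_form != "population_times_inverse_distance":
            raise ConfigurationError(f"unknown weight_form {self.weight_form!r}")


@dataclass
class LassoConfig:
    """Penalized Poisson regression path and cross-validation controls."""

    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    penalty_factor: Sequence[float] | None = None
    standardize: bool = True
    max_iter: int = 100
    tol: float = 1e-8
    selection_rule: str = "lambda_min"

    def validate(self, n_features: int | None = None) -> None:
        if self.n_lambda < 2:
            raise ConfigurationError("n_lambda must be >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ConfigurationError("lambda_min_ratio must be in (0, 1)")
        if self.tol <= 0:
            raise ConfigurationError("tol must be > 0")
        if self.selection_rule not in ("lambda_min", "lambda_1se"):
            raise ConfigurationError("selection_rule must be lambda_min or lambda_1se")
        if self.penalty_factor is not None:
            pf = np.asarray(self.penalty_factor, dtype=float)
            if np.any(pf < 0):
                raise ConfigurationError("penalty_factor must be nonnegative")
            if n_features is not None and pf.shape[0] != n_features:
                raise ConfigurationError("penalty_factor length must equal feature count")


@dataclass
class ForestConfig:
    """Case-weighted random-forest regression controls.

    ``mtry`` defaults to floor(p/3) at fit time when left as None; case
    weights default to the total visit counts.
    """

    n_trees: int = 1000
    mtry: int | None = None
    n_permutations: int = 1
    seed: int = 0

    def validate(self, n_features: int | None = None) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.mtry is not None:
            if self.mtry < 1:
                raise ConfigurationError("mtry must be >= 1")
            if n_features is not None and self.mtry > n_features:
                raise ConfigurationError("mtry cannot exceed the feature count")


@dataclass
class PipelineConfig:
    """End-to-end run configuration: exactly one of synthetic/real-data mode."""

    region: RegionConfig | None = None
    tracts_path: str | None = None
    zips_path: str | None = None
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    n_folds: int = 10
    neighbor_radius: float = 50.0
    lasso: LassoConfig = field(default_factory=LassoConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    n_bins: int = 100
    rf_rank_threshold: int = 2
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        synthetic = self.region is not None
        real = self.tracts_path is not None or self.zips_path is not None
        if synthetic == real:
            raise ConfigurationError(
                "exactly one of synthetic (region) or real-data (paths) mode required"
            )
        if real and (self.tracts_path is None or self.zips_path is None):
            raise ConfigurationError("real-data mode requires both tracts and zips paths")
        if synthetic:
            self.region.validate()
        self.aggregation.validate()
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.neighbor_radius <= 0:
            raise ConfigurationError("neighbor_radius must be > 0")
        self.lasso.validate()
        self.forest.validate()
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
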