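"""End-to-end orchestration: generate/load -> aggregate -> features -> fit -> diagnose.

A single global seed deterministically derives per-stage sub-seeds by
hashing the stage name, so each stage is individually reproducible without
user-side seed bookkeeping. Every run produces an :class:`AssociationReport`
whose payload is byte-identical across reruns with the same seed and config.

In synthetic mode the report additionally contains a recovery block scoring
the fitted models against the generator's ground truth, and
:func:`recovery_experiment` repeats the whole pipeline across seeds to
estimate causal-selection and false-selection frequencies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .compare import compare_models
from .config import COVARIATE_NAMES, ConfigurationError, PipelineConfig
from .diagnostics import monotonic_trend_score, percentile_dose_response, pollutant_correlogram
from .exposure import aggregate_exposures
from .forest import fit_random_forest
from .lasso import fit_poisson_lasso
from .spatial import autocovariate, spatial_folds
from .synthetic import GroundTruth, generate_region, read_tracts, read_zips, write_region

__all__ = ["AssociationReport", "run_pipeline", "recovery_experiment", "stage_seed"]

logger = logging.getLogger(__name__)

AUTOCOV_NAME = "autocovariate"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % 2**31


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o: Any):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AssociationReport:
    """Serializable record of one pipeline run."""

    seed: int
    config_hash: str
    exposure_summary: dict
    comparison: pd.DataFrame
    spatial_selected: list[str]
    nonspatial_selected: list[str]
    rf_ranks: dict[str, int]
    trend_scores: dict[str, float]
    correlogram: pd.DataFrame
    recovery: dict | None = None
    artifacts: dict = field(default_factory=dict)

    def payload(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "exposure_summary": self.exposure_summary,
            "comparison": self.comparison.to_dict(orient="records"),
            "spatial_selected": self.spatial_selected,
            "nonspatial_selected": self.nonspatial_selected,
            "rf_ranks": self.rf_ranks,
            "trend_scores": self.trend_scores,
            "correlogram": {
                "pollutants": list(self.correlogram.columns),
                "matrix": self.correlogram.to_numpy().tolist(),
            },
            "recovery": self.recovery,
        }

    def to_json(self) -> str:
        return json.dumps(self.payload(), indent=1, sort_keys=True)


def _model_frames(
    zips: pd.DataFrame, exposure: pd.DataFrame, pollutants: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Join exposures onto covered zips; return (zips, X_pollutants+covariates, rates)."""
    merged = zips.merge(exposure, on="zip_id", how="inner")
    covered = merged[merged["coverage"]].reset_index(drop=True)
    n_drop = len(merged) - len(covered)
    if n_drop:
        logger.info("excluding %d zips without exposure coverage", n_drop)
    covs = [c for c in COVARIATE_NAMES if c in covered.columns]
    x = covered[pollutants + covs]
    rates = covered["cases"].to_numpy(float) / covered["total"].to_numpy(float)
    return covered, x, rates


def run_pipeline(cfg: PipelineConfig) -> AssociationReport:
    """Execute all stages and assemble the association report."""
    cfg.validate()
    seed = cfg.seed
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- stage: data ----------------------------------------------------
    truth: GroundTruth | None = None
    if cfg.region is not None:
        region_cfg = dataclasses.replace(cfg.region, seed=stage_seed(seed, "generate"))
        tracts, zips, truth = generate_region(region_cfg)
        if out_dir:
            artifacts.update(write_region(tracts, zips, out_dir, truth))
    else:
        tracts = read_tracts(cfg.tracts_path)
        zips = read_zips(cfg.zips_path)
    logger.info("data: %d tracts, %d zips", len(tracts), len(zips))

    # --- stage: exposure aggregation ------------------------------------
    from .synthetic import pollutant_columns

    pollutants = pollutant_columns(tracts)
    exposure = aggregate_exposures(tracts, zips, cfg.aggregation)
    if out_dir:
        p = out_dir / "exposure.csv"
        exposure.to_csv(p, index=False)
        artifacts["exposure"] = p
    covered, x_base, rates = _model_frames(zips, exposure, pollutants)
    exposure_summary = {
        "n_zips": int(len(zips)),
        "n_modeled": int(len(covered)),
        "n_uncovered": int(len(zips) - len(covered)),
        "pollutants": pollutants,
    }

    # --- stage: spatial features ----------------------------------------
    folds = spatial_folds(covered, k=cfg.n_folds, seed=stage_seed(seed, "folds"))
    ac = autocovariate(covered, rates, neighbor_radius=cfg.neighbor_radius)
    if out_dir:
        folds.to_frame().to_csv(out_dir / "folds.csv", index=False)
        pd.DataFrame({"zip_id": covered["zip_id"], AUTOCOV_NAME: ac}).to_csv(
            out_dir / "autocov.csv", index=False
        )
    logger.info("features: %d folds, autocovariate over %.0f-mile neighbors", cfg.n_folds, cfg.neighbor_radius)

    cases = covered["cases"].to_numpy(float)
    total = covered["total"].to_numpy(float)
    covs = [c for c in x_base.columns if c not in pollutants]
    pf_base = np.array([1.0] * len(pollutants) + [0.0] * len(covs))

    # --- stage: models ---------------------------------------------------
    ns_cfg = dataclasses.replace(cfg.lasso, penalty_factor=pf_base)
    nonspatial = fit_poisson_lasso(
        x_base, cases, total, ns_cfg,
        folds=None, n_folds=cfg.n_folds, seed=stage_seed(seed, "cv_nonspatial"),
    )
    x_spatial = x_base.copy()
    x_spatial[AUTOCOV_NAME] = ac
    sp_cfg = dataclasses.replace(cfg.lasso, penalty_factor=np.append(pf_base, 0.0))
    spatial = fit_poisson_lasso(x_spatial, cases, total, sp_cfg, folds=folds)
    forest_cfg = dataclasses.replace(cfg.forest, seed=stage_seed(seed, "forest"))
    forest = fit_random_forest(x_base, rates, forest_cfg, case_weights=total)
    comparison = compare_models(nonspatial, spatial, forest, cfg.rf_rank_threshold)
    logger.info(
        "models: nonspatial selected %s; spatial selected %s; RF top = %s",
        nonspatial.selected(), spatial.selected(), forest.importance_series().index[0],
    )

    # --- stage: diagnostics ----------------------------------------------
    corr = pollutant_correlogram(exposure, pollutants)
    trend_scores = {}
    for pol in pollutants:
        dr = percentile_dose_response(
            covered[pol].to_numpy(float), cases, total, n_bins=min(cfg.n_bins, len(covered))
        )
        trend_scores[pol] = monotonic_trend_score(dr)
        if out_dir:
            dr.to_csv(out_dir / f"dose_response_{pol}.csv", index=False)
    if out_dir:
        corr.to_csv(out_dir / "correlogram.csv")
        comparison.to_csv(out_dir / "selected.csv", index=False)

    # --- stage: recovery (synthetic mode) --------------------------------
    recovery = None
    if truth is not None:
        causal = [truth.pollutant_names[j] for j in truth.causal_index_set]
        nulls = [p for p in truth.pollutant_names if p not in causal]
        ranks = forest.ranks()
        recovery = {
            "causal_pollutants": causal,
            "spatial_true_selections": sorted(set(spatial.selected()) & set(causal)),
            "spatial_false_selections": sorted(set(spatial.selected()) & set(nulls)),
            "nonspatial_true_selections": sorted(set(nonspatial.selected()) & set(causal)),
            "nonspatial_false_selections": sorted(set(nonspatial.selected()) & set(nulls)),
            "rf_rank_causal": {c: int(ranks[c]) for c in causal},
            "trend_score_causal": {c: trend_scores[c] for c in causal},
            "trend_score_null_mean": float(np.mean([trend_scores[p] for p in nulls]))
            if nulls
            else None,
            "consistent_flagged": comparison.loc[comparison["consistent"], "feature"].tolist(),
        }

    report = AssociationReport(
        seed=seed,
        config_hash=_config_hash(cfg),
        exposure_summary=exposure_summary,
        comparison=comparison,
        spatial_selected=spatial.selected(),
        nonspatial_selected=nonspatial.selected(),
        rf_ranks={f: int(r) for f, r in forest.ranks().items()},
        trend_scores=trend_scores,
        correlogram=corr,
        recovery=recovery,
        artifacts=artifacts,
    )
    if out_dir:
        (out_dir / "report.json").write_text(report.to_json())
    return report


def recovery_experiment(base_cfg: PipelineConfig, n_seeds: int) -> dict:
    """Repeat the synthetic pipeline across seeds and summarize recovery.

    Returns a dict with causal-selection frequencies for both lassos,
    per-null-pollutant false-selection frequencies, the frequency with which
    the forest ranks every causal pollutant in the top 2, and mean trend
    scores of causal vs null pollutants. Per-seed rows are under ``"runs"``.
    """
    if base_cfg.region is None:
        raise ConfigurationError("recovery_experiment requires synthetic mode")
    if n_seeds < 2:
        raise ConfigurationError("n_seeds must be >= 2")
    rows = []
    null_counts: dict[str, int] = {}
    for i in range(n_seeds):
        cfg = dataclasses.replace(base_cfg, seed=(base_cfg.seed + i) % 2**31, output_dir=None)
        rep = run_pipeline(cfg)
        rec = rep.recovery
        causal = rec["causal_pollutants"]
        nulls = [p for p in rep.exposure_summary["pollutants"] if p not in causal]
        for p in rec["spatial_false_selections"]:
            null_counts[p] = null_counts.get(p, 0) + 1
        rows.append(
            {
                "seed": cfg.seed,
                "spatial_hit": set(rec["spatial_true_selections"]) == set(causal),
                "nonspatial_hit": set(rec["nonspatial_true_selections"]) == set(causal),
                "n_false_spatial": len(rec["spatial_false_selections"]),
                "rf_top2": all(r <= 2 for r in rec["rf_rank_causal"].values()),
                "trend_causal_mean": float(np.mean(list(rec["trend_score_causal"].values()))),
                "trend_null_mean": rec["trend_score_null_mean"],
            }
        )
    runs = pd.DataFrame(rows)
    nulls_all = [
        p
        for p in (f"pollutant_{j+1}" for j in range(base_cfg.region.n_pollutants))
        if p not in {f"pollutant_{j+1}" for j in base_cfg.region.causal_index_set}
    ]
    return {
        "n_seeds": n_seeds,
        "spatial_selection_freq": float(runs["spatial_hit"].mean()),
        "nonspatial_selection_freq": float(runs["nonspatial_hit"].mean()),
        "false_selection_freq": {p: null_counts.get(p, 0) / n_seeds for p in nulls_all},
        "rf_top2_freq": float(runs["rf_top2"].mean()),
        "trend_causal_mean": float(runs["trend_causal_mean"].mean()),
        "trend_null_mean": float(runs["trend_null_mean"].mean()),
        "runs": runs,
    }
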