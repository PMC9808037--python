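# spatioassoc

Ecological spatial association analysis between ambient pollutant exposures
and disease visit rates, for epidemiologists working with areal claims data
(zip-code visit counts) and modeled exposure surfaces (census-tract
concentrations).

Given a tract table (centroid, population, one column per pollutant) and a
zip table (centroid, disease-coded visit count, total billable visits,
ecological covariates), the pipeline:

1. **aggregates** tract concentrations to zip level with a radius-limited,
   population × inverse-distance weighted mean
   (w<sub>it</sub> = pop<sub>t</sub> / max(d<sub>it</sub>, 1 mi) for
   d<sub>it</sub> ≤ 50 mi, row-normalized);
2. **builds spatial features**: a spatially lagged autocovariate (inverse-
   distance mean of neighboring zips' observed rates) and k-means spatial
   cross-validation folds (k = 10) on projected centroids;
3. **fits association models**: non-spatial and spatial L1-penalized Poisson
   rate regressions with log total visits as offset,

   min (1/n) Σᵢ [ totalᵢ·e^{ηᵢ} − casesᵢ·(log totalᵢ + ηᵢ) ] + λ Σⱼ pfⱼ|βⱼ|,
   ηᵢ = β₀ + xᵢᵀβ,

   with pollutants penalized (pf = 1) and covariates/autocovariate not
   (pf = 0), λ chosen by cross-validated Poisson deviance; plus a
   case-weighted random forest (1000 trees, mtry = p/3, case weights =
   total visits) scored by out-of-bag permutation importance;
4. **diagnoses** collinearity (exposure correlogram) and dose-response
   (visit-weighted rates across exposure percentile bins, summarized by a
   Spearman trend score).

Because real claims extracts are proprietary, the package ships a
**synthetic region generator** with known causal structure — spatially
autocorrelated pollutant fields with exactly controlled cross-correlation, a
log-linear Poisson outcome with planted effects, confounding covariates and
zip-level heterogeneity — so every stage is verified by parameter recovery.
See `docs/methods.md` for models, defaults and caveats.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic region (8,000 tracts, 1,500 zips, 10 pollutants with pairwise
exposure correlation 0.6, pollutant_1 causal at 0.5 log-rate per SD):

```
$ python analysis/01_simulate_region.py
8000 tracts, 1500 zips
visit rate: median 0.0041, IQR [0.0024, 0.0062]
causal pollutant: pollutant_1 (beta=0.5 per SD)

$ python analysis/02_aggregate_exposures.py
wrote results/exposure.csv: 1500/1500 zips covered
median contributing tracts per zip: 385

$ python analysis/03_spatial_features.py
wrote results/folds.csv: fold sizes 121-169
wrote results/autocov.csv: autocovariate range [0.0016, 0.0112]

$ python analysis/04_fit_models.py
non-spatial lasso selected: ['pollutant_1']
spatial lasso selected:     ['pollutant_1', 'pollutant_2', 'pollutant_4', ...]
forest top importances:     ['pollutant_1', 'pollutant_6', 'pollutant_8']
consistent associations:    ['pollutant_1']
```

Reading: the planted pollutant is recovered by all three models; at
`lambda_min` the spatial lasso also drags in correlated null pollutants with
near-zero coefficients (the known liberality of the minimum-deviance rule
under collinearity), which is why the pipeline's *consistent association*
flag requires agreement of both lassos **and** a top forest rank — here it
isolates exactly `pollutant_1`. `analysis/05_diagnostics.py` then shows the
causal pollutant's percentile trend score (+0.98) against the correlated
nulls' (~+0.8), and `analysis/06_recovery_experiment.py` repeats the whole
exercise across 20 fresh regions to turn single-run anecdotes into
selection frequencies.

The same stages are scriptable via the CLI (`spatioassoc simulate`,
`aggregate`, `features`, `run --config cfg.yaml`, `recover`, `diagnose`) or
the library API (`generate_region`, `aggregate_exposures`, `spatial_folds`,
`autocovariate`, `fit_poisson_lasso`, `fit_random_forest`,
`run_pipeline`, ...).

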