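# Methods

`spatioassoc` implements an ecological association analysis between ambient
pollutant exposures and the rate of disease-coded clinic visits across
zip-code areas, together with a synthetic-region generator that makes every
stage of the analysis testable by parameter recovery. This note records the
models, the defaults and why, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## The analysis

### Exposure aggregation

Pollutant concentrations live on census-tract centroids; outcomes live on
zip-code-area centroids. A zip's exposure to pollutant *k* is a weighted
mean over the tracts within a fixed radius of its centroid:

    x_ik = Σ_t w_it c_tk / Σ_t w_it,
    w_it = pop_t / max(d_it, d_floor),   d_it ≤ r

with great-circle distance `d_it` (haversine, sphere radius 3958.8 miles).
Defaults: radius `r` = 50 miles, distance floor `d_floor` = 1 mile. The
floor prevents a tract whose centroid coincides with the zip centroid from
receiving unbounded weight; below one mile, centroid-to-centroid distance is
not a meaningful proximity measure for areal units anyway. The functional
form (population × 1/d, row-normalized) is the simplest that weights by
both population and proximity; the exponent on distance is configurable in
principle but 1/d is the shipped form. Zips with no tract in range are
flagged (`coverage = False`), reported, and excluded from modeling — never
imputed.

Distances use a KD-tree on 3-D unit-sphere coordinates to find candidate
pairs within the chord-length bound, then exact haversine distances on the
candidates, so the result is identical to an all-pairs scan at any size
(verified against a double-loop reference to 1e-12).

### Spatial features

Two features carry the spatial structure of the regression:

* **Spatially lagged autocovariate.** For each zip, the inverse-distance
  weighted mean of the *observed* visit rates of the other zips within 50
  miles (same radius and floor as aggregation, one spatial scale for the
  whole pipeline). Zips with no neighbor receive the global mean rate with a
  log message. The autocovariate is computed once on all data; because the
  outcome of held-out zips leaks into their neighbors' autocovariate, the
  spatially blocked cross-validation is not perfectly clean — this matches
  the plain reading of the method being emulated and is accepted as a
  documented caveat rather than re-computed per fold.
* **Spatial folds.** k-means (k = 10) on zip centroids in a local
  equirectangular projection (miles), so held-out zips are geographically
  blocked from training zips. Clustering on raw lon/lat would distort
  east–west distances at high latitude. Deterministic given the seed; in the
  degenerate case of an empty cluster the seed is re-derived up to 10 times.

### Poisson lasso

Both lasso variants minimize

    (1/n) Σ_i [ total_i e^{η_i} − cases_i (log total_i + η_i) ]
        + λ Σ_j pf_j |β_j|,      η_i = β0 + x_iᵀβ

i.e. a Poisson rate model with log total visits as offset and an L1 penalty
with per-feature penalty factors. Pollutants carry pf = 1; the ecological
covariates (population density, age brackets, ADI, specialist proportion)
and the autocovariate carry pf = 0, so variable selection operates on the
pollutants while confounders stay in the model. The intercept is never
penalized. The non-spatial variant omits the autocovariate and uses seeded
random 10-fold CV; the spatial variant adds the autocovariate and uses the
spatial folds.

Numerics: features are standardized internally (coefficients are returned
on the original scale); the λ path is geometric with 100 points from the
smallest λ that zeroes every penalized coefficient (computed from the KKT
conditions at the unpenalized-features-only fit) down to 1e-4 of it. The
solver is iteratively reweighted least squares with a coordinate-descent
inner loop on the weighted quadratic subproblem (Gram-matrix updates),
warm-started along the path, with a step-halving safeguard that keeps the
penalized objective non-increasing. Convergence is declared when the max
coefficient change is below `tol` (default 1e-8 on the standardized scale).
The weighted working response is formed as `w·z = μ·η_c + (y − μ)`, which
avoids the 0/0 of the textbook formula at μ → 0. The solver is validated
against direct numerical minimization of the objective (L-BFGS-B with
positive/negative coefficient splitting) to 1e-5 along the whole path.

CV scores each λ by the mean held-out Poisson deviance
`2 Σ [y log(y/μ) − (y − μ)]` (0·log 0 ≡ 0), averaged across folds, with the
between-fold standard error. Both `lambda_min` (minimum mean deviance) and
`lambda_1se` (largest λ within one SE of the minimum) are reported; the
default selection rule is `lambda_min`. With correlated exposures
`lambda_min` is known to be liberal — the CV curve is nearly flat past the
entry of the true signal and its argmin can land deep in the path where the
support is dense; `lambda_1se` is the conservative alternative and is one
switch away.

### Random forest

A regression forest of the visit rate on pollutants + covariates: 1000
trees, `mtry = floor(p/3)` (untuned), per-zip case weights equal to total
visits so high-volume zips — whose observed rates are least noisy —
dominate both the bootstrap sampling and the split criterion. Importance is
out-of-bag permutation importance: per tree, the increase in case-weighted
squared error on the tree's out-of-bag zips when one feature column is
shuffled, averaged over trees. Tree growing and the permutation shuffles
share one seed, so importances are exactly reproducible. The forest exists
to catch effect shapes the linear-in-exposure lasso cannot represent
(thresholds, saturation, interactions).

### Diagnostics

* **Correlogram:** pairwise Pearson correlations of the aggregated
  exposures over covered zips (listwise deletion), exposing collinear
  exposure mixtures such as traffic-related CO/NO₂.
* **Percentile dose-response:** zips ranked by exposure and cut into
  equal-count bins (default 100; sizes differ by at most one; ties broken
  by stable order); the bin rate is the pooled `Σcases/Σtotal`, i.e.
  visit-weighted, matching the rate's definition as a pooled proportion
  rather than a mean of zip rates.
* **Monotonic trend score:** Spearman correlation between bin index and bin
  rate, in [−1, 1]; constant bins give 0 by convention. This is a package
  addition that operationalizes "is there a visible dose-response gradient"
  as a number; reports label it as such.

A pollutant is flagged as a **consistent association** when both lassos
select it and its forest rank is within a threshold (default top 2) — three
models with different assumptions agreeing.

## The synthetic region generator

The generator emulates the two real input tables with known ground truth.

* **Geography:** tract and zip centroids uniform in a bounding box
  (default ≈ 390 × 415 miles, 8,000 tracts, 1,500 zips — tract density
  comparable to a mid-density US region).
* **Pollutant fields:** Gaussian-kernel smoothing (length scale 30 miles)
  of iid knot weights on 250 random knots gives cheap, seedable spatial
  autocorrelation without a GP library. The latent fields are empirically
  orthonormalized (QR) and mixed by a symmetric square root of the target
  correlation matrix, so the *realized* tract-level correlation equals the
  requested one exactly — important because smooth fields on a finite region
  otherwise carry large incidental sample correlations. An affine per-column
  transform (shift to nonnegative, scale) sets concentration units; Pearson
  correlation is invariant to it. Units are arbitrary-but-consistent; the
  models standardize, so units never enter any contract.
* **Covariates:** smooth field + iid noise mixtures mapped to plausible
  ranges (lognormal density, logistic-bounded proportions, tanh-bounded
  deprivation score). The marginal distributions of the real covariates are
  not documented anywhere usable, so these are stand-ins; with nonzero
  `covariate_effects` they act as spatially structured confounders.
* **Outcome:** `cases_i ~ Poisson(total_i · exp(η_i))` truncated at
  `total_i` (preserving cases ≤ total while keeping the Poisson story),
  with `η` = β0 + planted pollutant effects on the *aggregated,
  standardized* exposures (the same quantity the models see) + covariate
  effects + a zip-level random effect. Totals are lognormal (median ≈ 2,000
  billable visits per zip). Defaults: β0 = −5.5 (baseline rate ≈ 0.4%),
  one causal pollutant at 0.5 log-rate per SD, exchangeable exposure
  correlation 0.6, random-effect sd 0.2.
* **Random effect structure:** configurable. `iid` (default) is
  unstructured zip-level heterogeneity — the unstructured component of a
  disease-mapping model; `smooth` is a spatially autocorrelated field with
  the pollutant length scale. The default matters: with a *smooth* random
  effect, every smooth null pollutant field genuinely predicts part of the
  held-out spatial variation, so the spatially blocked CV deviance decreases
  along the entire λ path and `lambda_min` degenerates to the densest model
  for any correct solver. The unstructured default keeps residual
  variation unpredictable-by-construction, which is the regime in which
  CV-based selection is meaningful. Under the smooth setting users should
  expect `lambda_min` to overselect and prefer `lambda_1se`.
* **Effect shapes:** `linear` or `threshold` (effect switches on above the
  median exposure) — the latter exercises the forest's advantage.

Determinism: a fixed `RegionConfig` (including seed) reproduces the tables
bit-for-bit; the pipeline derives per-stage sub-seeds by hashing the stage
name with the global seed.

### What the synthetic experiments show — and what they don't

Passing recovery tests demonstrate that the pipeline's machinery is correct
and powerful enough to find a planted signal of the stated size under
controlled collinearity and heterogeneity. They do not validate the causal
interpretation of any real-data association: the generator has uniform
geography (no urban clustering), exact unit-level exposure (no measurement
error beyond aggregation), stationary fields, and no unmeasured confounding
beyond what is planted. Real claims data violate all of these.

## Problem sizes and experiment design

Recovery experiments use 20 independent seeds at the full default region
size (1,500 zips × 8,000 tracts), which puts Monte-Carlo error on a
frequency at ≈ ±11 percentage points (binomial, worst case) — adequate to
distinguish "nearly always" from "often" without burning compute. The
oracle-equivalence checks run on deliberately tiny inputs (≤ 20 tracts, 6
zips) where brute-force references are exact and fast.

## Known limitations

* The autocovariate leaks held-out outcomes into training features (above);
  fold-internal recomputation is a possible extension.
* `lambda_min` overselects correlated null pollutants by design of the rule;
  per-null false-selection frequencies in the shipped recovery experiment
  run in the 30-65% range (seed-base dependent) rather than far below it.
  Users who need conservative selection should switch the rule to
  `lambda_1se`.
* Real-data mode expects pre-averaged multi-year concentrations per tract;
  no temporal modeling is attempted.
* Points-with-centroids geometry only: no polygon areal weighting, no
  CAR/SAR models, no kriging.
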