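#!/usr/bin/env python
"""Fit the three association models and compare their selections.

Fits (i) the non-spatial Poisson lasso (random 10-fold CV, no autocovariate),
(ii) the spatial Poisson lasso (spatial folds + unpenalized autocovariate),
and (iii) the case-weighted random forest (1000 trees, mtry = p/3, case
weights = total visits) with out-of-bag permutation importance. Pollutants
are penalized; ecological covariates are not, so lasso selection operates on
the pollutants. Writes results/selected.csv and results/model_report.json.
"""

import json

import numpy as np
import pandas as pd

from spatioassoc import (
    ForestConfig,
    LassoConfig,
    compare_models,
    fit_poisson_lasso,
    fit_random_forest,
    read_zips,
    spatial_folds,
)
from spatioassoc.config import COVARIATE_NAMES

SEED = 20250901


def main() -> None:
    zips = read_zips("results/region/zips.csv")
    exposure = pd.read_csv("results/exposure.csv", dtype={"zip_id": str})
    autocov = pd.read_csv("results/autocov.csv", dtype={"zip_id": str})
    frame = zips.merge(exposure, on="zip_id").merge(autocov, on="zip_id")
    frame = frame[frame["coverage"]].reset_index(drop=True)
    pollutants = [c for c in exposure.columns if c.startswith("pollutant_")]

    cases = frame["cases"].to_numpy(float)
    total = frame["total"].to_numpy(float)
    x = frame[pollutants + list(COVARIATE_NAMES)]
    pf = np.array([1.0] * len(pollutants) + [0.0] * len(COVARIATE_NAMES))

    nonspatial = fit_poisson_lasso(
        x, cases, total, LassoConfig(penalty_factor=pf), n_folds=10, seed=SEED
    )
    print(f"non-spatial lasso selected: {nonspatial.selected()}")

    folds = spatial_folds(frame, k=10, seed=SEED)
    x_sp = x.copy()
    x_sp["autocovariate"] = frame["autocovariate"]
    spatial = fit_poisson_lasso(
        x_sp, cases, total, LassoConfig(penalty_factor=np.append(pf, 0.0)), folds=folds
    )
    print(f"spatial lasso selected:     {spatial.selected()}")

    forest = fit_random_forest(x, cases / total, ForestConfig(seed=SEED), case_weights=total)
    top = forest.importance_series().index[:3].tolist()
    print(f"forest top importances:     {top}")

    table = compare_models(nonspatial, spatial, forest)
    table.to_csv("results/selected.csv", index=False)
    consistent = table.loc[table["consistent"], "feature"].tolist()
    print(f"consistent associations:    {consistent}")

    report = {
        "nonspatial": {
            "selected": nonspatial.selected(),
            "lambda_min": nonspatial.lambda_min,
            "lambda_1se": nonspatial.lambda_1se,
        },
        "spatial": {
            "selected": spatial.selected(),
            "lambda_min": spatial.lambda_min,
            "lambda_1se": spatial.lambda_1se,
            "coef_at_lambda_min": spatial.coef_at().round(6).to_dict(),
        },
        "forest": {
            "importances": forest.importance_series().round(10).to_dict(),
            "oob_error": forest.oob_error,
        },
        "consistent": consistent,
    }
    with open("results/model_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    print("wrote results/selected.csv and results/model_report.json")


if __name__ == "__main__":
    main()
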