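#!/usr/bin/env python
"""Build the spatial regression features.

Constructs 10 k-means spatial cross-validation folds on projected zip
centroids and the spatially lagged visit-rate autocovariate (inverse-distance
mean of neighbor rates within 50 miles). Writes results/folds.csv and
results/autocov.csv.
"""

import pandas as pd

from spatioassoc import autocovariate, read_zips, spatial_folds

SEED = 20250901


def main() -> None:
    zips = read_zips("results/region/zips.csv")
    folds = spatial_folds(zips, k=10, seed=SEED)
    folds.to_frame().to_csv("results/folds.csv", index=False)
    sizes = folds.to_frame()["fold"].value_counts().sort_index()
    print(f"wrote results/folds.csv: fold sizes {sizes.min()}-{sizes.max()}")

    rates = zips["cases"].to_numpy(float) / zips["total"].to_numpy(float)
    ac = autocovariate(zips, rates, neighbor_radius=50.0)
    pd.DataFrame({"zip_id": zips["zip_id"], "autocovariate": ac}).to_csv(
        "results/autocov.csv", index=False
    )
    print(f"wrote results/autocov.csv: autocovariate range [{ac.min():.4f}, {ac.max():.4f}]")


if __name__ == "__main__":
    main()
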