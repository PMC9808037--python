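#!/usr/bin/env python
"""Multi-seed recovery experiments: does the pipeline find the planted signal?

Repeats three targeted experiments across 20 fresh regions each and writes
results/recovery.json:

* spatial Poisson lasso: causal-selection and per-null false-selection
  frequencies at lambda_min;
* case-weighted random forest under a threshold-shaped effect: frequency of
  the causal pollutant ranking in the top 2 permutation importances;
* diagnostics with planted 0.9 cross-correlation: correlogram recovery and
  percentile trend scores of causal vs null pollutants.
"""

import json

from spatioassoc import diagnostics_recovery, forest_recovery, spatial_lasso_recovery

SEED = 20250901
N_SEEDS = 20


def main() -> None:
    lasso = spatial_lasso_recovery(n_seeds=N_SEEDS, base_seed=SEED)
    print(f"spatial lasso: causal selected {lasso['causal_selection_freq']:.0%}, "
          f"max null {lasso['max_null_selection_freq']:.0%}")

    forest = forest_recovery(n_seeds=N_SEEDS, base_seed=SEED)
    print(f"forest: causal in top 2 importances {forest['causal_top_k_freq']:.0%}")

    diag = diagnostics_recovery(n_seeds=N_SEEDS, base_seed=SEED)
    print(f"diagnostics: corr estimate {diag['mean_corr_estimate']:.3f} (target 0.9), "
          f"causal trend {diag['mean_causal_trend']:.2f}, null trend {diag['mean_null_trend']:.2f}")

    out = {
        "spatial_lasso": {k: v for k, v in lasso.items() if k != "runs"},
        "forest": forest,
        "diagnostics": diag,
    }
    with open("results/recovery.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    print("wrote results/recovery.json")


if __name__ == "__main__":
    main()
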