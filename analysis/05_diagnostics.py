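#!/usr/bin/env python
"""Collinearity and dose-response diagnostics for the fitted region.

Writes the pollutant correlogram (results/correlogram.csv), per-pollutant
percentile dose-response tables (results/dose_response_<pollutant>.csv) and
prints the monotonic trend score of each pollutant.
"""

import pandas as pd

from spatioassoc import (
    monotonic_trend_score,
    percentile_dose_response,
    pollutant_correlogram,
    read_zips,
)


def main() -> None:
    zips = read_zips("results/region/zips.csv")
    exposure = pd.read_csv("results/exposure.csv", dtype={"zip_id": str})
    frame = zips.merge(exposure, on="zip_id")
    frame = frame[frame["coverage"]].reset_index(drop=True)
    pollutants = [c for c in exposure.columns if c.startswith("pollutant_")]

    corr = pollutant_correlogram(exposure, pollutants)
    corr.to_csv("results/correlogram.csv")
    print("wrote results/correlogram.csv")
    print(f"pollutant_1 x pollutant_2 correlation: {corr.iloc[0, 1]:.3f}")

    cases = frame["cases"].to_numpy(float)
    total = frame["total"].to_numpy(float)
    print("\npollutant        trend score")
    for pol in pollutants:
        dr = percentile_dose_response(frame[pol].to_numpy(float), cases, total, n_bins=100)
        dr.to_csv(f"results/dose_response_{pol}.csv", index=False)
        print(f"{pol:<16} {monotonic_trend_score(dr):+.3f}")


if __name__ == "__main__":
    main()
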