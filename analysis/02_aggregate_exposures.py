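#!/usr/bin/env python
"""Aggregate tract pollutant concentrations to zip level.

Applies the radius-limited (50-mile), population x inverse-distance
weighted mean to every pollutant, reports coverage, and writes
results/exposure.csv.
"""

from spatioassoc import AggregationConfig, aggregate_exposures, read_tracts, read_zips

def main() -> None:
    tracts = read_tracts("results/region/tracts.csv")
    zips = read_zips("results/region/zips.csv")
    exposure = aggregate_exposures(tracts, zips, AggregationConfig())
    exposure.to_csv("results/exposure.csv", index=False)
    covered = int(exposure["coverage"].sum())
    print(f"wrote results/exposure.csv: {covered}/{len(exposure)} zips covered")
    print(f"median contributing tracts per zip: {exposure['n_contributing_tracts'].median():.0f}")


if __name__ == "__main__":
    main()
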