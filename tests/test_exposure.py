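import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatioassoc import (
    AggregationConfig,
    aggregate_exposures,
    build_aggregation_weights,
    great_circle_distance,
)

MILE_DEG = np.pi / 180.0 * 3958.8  # miles per degree of latitude


def naive_aggregate(tracts, zips, cfg, pollutants):
    """Double-loop reference implementation of the weighted mean."""
    out = {}
    for _, z in zips.iterrows():
        ws, cs = [], []
        for _, t in tracts.iterrows():
            d = great_circle_distance((z["lon"], z["lat"]), (t["lon"], t["lat"]))
            if d <= cfg.radius:
                ws.append(t["population"] / max(d, cfg.distance_floor))
                cs.append([t[p] for p in pollutants])
        if ws:
            w = np.array(ws) / np.sum(ws)
            out[z["zip_id"]] = w @ np.array(cs)
        else:
            out[z["zip_id"]] = np.full(len(pollutants), np.nan)
    return out


def test_single_tract_gets_weight_one(toy_tracts, toy_zip):
    w = build_aggregation_weights(toy_tracts.iloc[:1], toy_zip)
    assert w.row("Z1") == {"T1": pytest.approx(1.0)}


def test_two_equal_population_tracts_weights_follow_inverse_distance(toy_tracts, toy_zip):
    w = build_aggregation_weights(toy_tracts, toy_zip)
    row = w.row("Z1")
    assert row["T1"] == pytest.approx(2.0 / 3.0, rel=1e-9)
    assert row["T2"] == pytest.approx(1.0 / 3.0, rel=1e-9)


def test_tract_outside_radius_gets_zero_weight(toy_zip):
    far = pd.DataFrame(
        {
            "tract_id": ["T1"],
            "lon": [0.0],
            "lat": [51.0 / MILE_DEG],
            "population": [100.0],
            "pm": [30.0],
        }
    )
    w = build_aggregation_weights(far, toy_zip, AggregationConfig(radius=50.0))
    assert w.row("Z1") == {}
    assert w.n_neighbors[0] == 0


def test_weighted_mean_matches_hand_computation(toy_tracts, toy_zip):
    agg = aggregate_exposures(toy_tracts, toy_zip)
    # weights 2/3, 1/3 on concentrations 30, 60
    assert agg.loc[0, "pm"] == pytest.approx(40.0, rel=1e-9)
    assert agg.loc[0, "n_contributing_tracts"] == 2
    assert bool(agg.loc[0, "coverage"])


def test_constant_field_aggregates_to_constant(small_region):
    _, tracts, zips, _ = small_region
    flat = tracts.copy()
    flat["pollutant_1"] = 7.5
    agg = aggregate_exposures(flat, zips, pollutants=["pollutant_1"])
    covered = agg[agg["coverage"]]
    assert np.allclose(covered["pollutant_1"], 7.5, atol=1e-12)


def test_uncovered_zip_is_flagged_not_error(toy_tracts):
    remote = pd.DataFrame(
        {"zip_id": ["Z9"], "lon": [10.0], "lat": [10.0], "cases": [0], "total": [10]}
    )
    agg = aggregate_exposures(toy_tracts, remote)
    assert not bool(agg.loc[0, "coverage"])
    assert np.isnan(agg.loc[0, "pm"])


def test_missing_pollutant_column_raises_named_error(toy_tracts, toy_zip):
    with pytest.raises(KeyError, match="no2"):
        aggregate_exposures(toy_tracts, toy_zip, pollutants=["no2"])


def test_matches_naive_double_loop_to_1e12():
    rng = np.random.default_rng(7)
    n_t, n_z = 18, 9
    tracts = pd.DataFrame(
        {
            "tract_id": [f"T{i}" for i in range(n_t)],
            "lon": rng.uniform(-98, -97, n_t),
            "lat": rng.uniform(37, 38, n_t),
            "population": rng.uniform(10, 5000, n_t),
            "a": rng.uniform(0, 50, n_t),
            "b": rng.uniform(0, 5, n_t),
        }
    )
    zips = pd.DataFrame(
        {
            "zip_id": [f"Z{i}" for i in range(n_z)],
            "lon": rng.uniform(-98, -97, n_z),
            "lat": rng.uniform(37, 38, n_z),
            "cases": 0,
            "total": 1,
        }
    )
    cfg = AggregationConfig(radius=30.0)
    agg = aggregate_exposures(tracts, zips, cfg).set_index("zip_id")
    ref = naive_aggregate(tracts, zips, cfg, ["a", "b"])
    for zid, expected in ref.items():
        got = agg.loc[zid, ["a", "b"]].to_numpy(dtype=float)
        assert np.allclose(got, expected, atol=1e-12, equal_nan=True)


@settings(max_examples=30, deadline=None)
@given(
    concs=st.lists(st.floats(0, 100), min_size=2, max_size=8),
    seed=st.integers(0, 100),
)
def test_aggregate_is_convex_combination(concs, seed):
    """Every aggregate lies within [min, max] of contributing concentrations."""
    rng = np.random.default_rng(seed)
    n = len(concs)
    tracts = pd.DataFrame(
        {
            "tract_id": [f"T{i}" for i in range(n)],
            "lon": rng.uniform(-97.5, -97, n),
            "lat": rng.uniform(37, 37.5, n),
            "population": rng.uniform(1, 100, n),
            "c": concs,
        }
    )
    zips = pd.DataFrame(
        {"zip_id": ["Z0"], "lon": [-97.25], "lat": [37.25], "cases": [0], "total": [1]}
    )
    agg = aggregate_exposures(tracts, zips)
    val = agg.loc[0, "c"]
    assert min(concs) - 1e-9 <= val <= max(concs) + 1e-9


def test_increasing_a_concentration_never_decreases_aggregate(toy_tracts, toy_zip):
    base = aggregate_exposures(toy_tracts, toy_zip).loc[0, "pm"]
    bumped = toy_tracts.copy()
    bumped.loc[1, "pm"] += 10.0
    assert aggregate_exposures(bumped, toy_zip).loc[0, "pm"] >= base


def test_larger_radius_never_loses_contributing_tracts(small_region):
    _, tracts, zips, _ = small_region
    n30 = aggregate_exposures(tracts, zips, AggregationConfig(radius=30))["n_contributing_tracts"]
    n50 = aggregate_exposures(tracts, zips, AggregationConfig(radius=50))["n_contributing_tracts"]
    assert (n50 >= n30).all()
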