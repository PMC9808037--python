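import numpy as np
import pandas as pd
import pytest

from spatioassoc import (
    ConfigurationError,
    RegionConfig,
    aggregate_exposures,
    generate_region,
    pollutant_columns,
    read_tracts,
    read_zips,
    region_to_geojson,
    write_region,
)
from spatioassoc.geo import radius_pairs
from spatioassoc.synthetic import GroundTruth


def test_fixed_seed_reproduces_tables_exactly(tmp_path):
    cfg = RegionConfig(n_tracts=300, n_zips=80, seed=11)
    t1, z1, g1 = generate_region(cfg)
    t2, z2, g2 = generate_region(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(z1, z2)
    assert np.array_equal(g1.spatial_random_effect, g2.spatial_random_effect)
    # and byte-identical files
    write_region(t1, z1, tmp_path / "a", g1)
    write_region(t2, z2, tmp_path / "b", g2)
    assert (tmp_path / "a/tracts.csv").read_bytes() == (tmp_path / "b/tracts.csv").read_bytes()
    assert (tmp_path / "a/zips.csv").read_bytes() == (tmp_path / "b/zips.csv").read_bytes()


def test_cases_never_exceed_totals(small_region):
    _, _, zips, _ = small_region
    assert (zips["cases"] <= zips["total"]).all()
    assert (zips["cases"] >= 0).all()


def test_null_model_mean_rate_matches_baseline():
    cfg = RegionConfig(
        n_tracts=400,
        n_zips=800,
        beta=(0.0,),
        covariate_effects=(0.0,) * 6,
        spatial_re_sd=0.0,
        beta0=-4.0,
        seed=5,
    )
    _, zips, _ = generate_region(cfg)
    mean_rate = (zips["cases"] / zips["total"]).mean()
    expected = np.exp(-4.0)
    # Monte-Carlo error of the mean rate over 800 zips
    assert mean_rate == pytest.approx(expected, rel=0.05)


def test_identity_correlation_gives_uncorrelated_fields():
    cfg = RegionConfig(n_tracts=5000, n_zips=10, n_pollutants=4, pollutant_corr=0.0, seed=3)
    tracts, _, _ = generate_region(cfg)
    conc = tracts[pollutant_columns(tracts)].to_numpy()
    corr = np.corrcoef(conc.T)
    off = corr[~np.eye(4, dtype=bool)]
    assert np.all(np.abs(off) < 0.1)


def test_requested_cross_correlation_is_realized():
    corr = np.eye(3)
    corr[0, 1] = corr[1, 0] = 0.9
    cfg = RegionConfig(n_tracts=2000, n_zips=300, n_pollutants=3, pollutant_corr=corr, seed=9)
    tracts, zips, _ = generate_region(cfg)
    # oracle: direct Pearson correlation of the emitted columns
    r_tract = np.corrcoef(tracts["pollutant_1"], tracts["pollutant_2"])[0, 1]
    assert r_tract == pytest.approx(0.9, abs=1e-6)  # exact by construction
    agg = aggregate_exposures(tracts, zips)
    cov = agg[agg["coverage"]]
    r_zip = np.corrcoef(cov["pollutant_1"], cov["pollutant_2"])[0, 1]
    assert r_zip == pytest.approx(0.9, abs=0.1)


def test_pollutant_field_is_spatially_autocorrelated():
    """Lag correlation at sub-length-scale distances is positive."""
    cfg = RegionConfig(n_tracts=2000, n_zips=10, n_pollutants=1, pollutant_corr=1.0, seed=4)
    tracts, _, _ = generate_region(cfg)
    x = tracts["pollutant_1"].to_numpy()
    xc = x - x.mean()
    i, j, d = radius_pairs(
        tracts["lon"].to_numpy(), tracts["lat"].to_numpy(),
        tracts["lon"].to_numpy(), tracts["lat"].to_numpy(),
        cfg.field_length_scale,
    )
    off = i != j
    moran = np.sum(xc[i[off]] * xc[j[off]]) / (np.sum(off) * x.var())
    assert moran > 0.1


def test_non_psd_correlation_rejected():
    bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
    cfg = RegionConfig(n_pollutants=3, pollutant_corr=bad)
    with pytest.raises(ConfigurationError, match="semidefinite"):
        cfg.validate()


def test_degenerate_bbox_rejected():
    with pytest.raises(ConfigurationError, match="bbox"):
        RegionConfig(bbox=(-95.0, -95.0, 35.0, 41.0)).validate()


def test_write_read_round_trip(tmp_path, small_region):
    _, tracts, zips, truth = small_region
    paths = write_region(tracts, zips, tmp_path, truth)
    t2 = read_tracts(paths["tracts"])
    z2 = read_zips(paths["zips"])
    pd.testing.assert_frame_equal(tracts.reset_index(drop=True), t2)
    pd.testing.assert_frame_equal(zips.reset_index(drop=True), z2)
    g2 = GroundTruth.from_json(paths["truth"].read_text())
    assert g2.causal_index_set == truth.causal_index_set
    np.testing.assert_allclose(g2.exposure_std, truth.exposure_std)


def test_empty_zip_table_round_trips_as_header_only(tmp_path, small_region):
    _, tracts, zips, _ = small_region
    empty = zips.iloc[:0]
    paths = write_region(tracts, empty, tmp_path)
    lines = paths["zips"].read_text().strip().splitlines()
    assert len(lines) == 1  # header only
    assert len(read_zips(paths["zips"])) == 0


def test_csv_has_documented_column_order_and_row_count(tmp_path, small_region):
    _, tracts, zips, _ = small_region
    paths = write_region(tracts.head(3), zips.head(3), tmp_path)
    lines = paths["tracts"].read_text().strip().splitlines()
    assert len(lines) == 4  # header + 3 rows
    header = lines[0].split(",")
    assert header[:4] == ["tract_id", "lon", "lat", "population"]
    assert header[4].startswith("pollutant_")
    zheader = paths["zips"].read_text().splitlines()[0].split(",")
    assert zheader[:5] == ["zip_id", "lon", "lat", "cases", "total"]


def test_geojson_export_is_point_feature_collection(small_region):
    _, _, zips, _ = small_region
    gj = region_to_geojson(zips.head(5), "zip_id")
    assert gj["type"] == "FeatureCollection"
    assert len(gj["features"]) == 5
    f = gj["features"][0]
    assert f["geometry"]["type"] == "Point"
    assert "cases" in f["properties"]
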