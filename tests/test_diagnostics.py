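import numpy as np
import pandas as pd
import pytest

from spatioassoc import (
    monotonic_trend_score,
    percentile_dose_response,
    pollutant_correlogram,
)


class TestDoseResponse:
    def test_hand_computed_three_bins(self):
        # 6 zips ranked by exposure -> bins {0,1}, {2,3}, {4,5}
        exposure = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        cases = np.array([1.0, 1.0, 2.0, 2.0, 5.0, 5.0])
        total = np.array([100.0, 100.0, 100.0, 100.0, 100.0, 100.0])
        dr = percentile_dose_response(exposure, cases, total, n_bins=3)
        assert dr["rate"].tolist() == [2 / 200, 4 / 200, 10 / 200]
        assert dr["n_zips"].tolist() == [2, 2, 2]
        assert dr["mean_exposure"].tolist() == [1.5, 3.5, 5.5]

    def test_bin_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        dr = percentile_dose_response(rng.normal(size=103), rng.poisson(5, 103).astype(float), np.full(103, 100.0), n_bins=10)
        sizes = dr["n_zips"].to_numpy()
        assert sizes.sum() == 103
        assert sizes.max() - sizes.min() <= 1

    def test_more_bins_than_zips_reduced_with_warning(self, caplog):
        dr = percentile_dose_response(np.arange(5.0), np.ones(5), np.full(5, 10.0), n_bins=100)
        assert len(dr) == 5

    def test_monotone_rates_give_monotone_bins(self):
        exposure = np.linspace(0, 1, 50)
        total = np.full(50, 1000.0)
        cases = total * (0.01 + 0.05 * exposure)  # noiseless increasing rate
        dr = percentile_dose_response(exposure, cases, total, n_bins=10)
        assert (np.diff(dr["rate"]) > 0).all()

    def test_bin_rate_bounded_by_member_zip_rates(self):
        rng = np.random.default_rng(1)
        exposure = rng.normal(size=40)
        total = rng.integers(10, 100, 40).astype(float)
        cases = rng.integers(0, 10, 40).astype(float)
        dr = percentile_dose_response(exposure, cases, total, n_bins=8)
        order = np.argsort(exposure, kind="stable")
        chunks = np.array_split(order, 8)
        for row, idx in zip(dr.itertuples(), chunks):
            zr = cases[idx] / total[idx]
            assert zr.min() - 1e-12 <= row.rate <= zr.max() + 1e-12


class TestCorrelogram:
    def test_self_correlation_is_one_and_antisymmetry(self):
        x = np.random.default_rng(0).normal(size=30)
        df = pd.DataFrame({"zip_id": range(30), "a": x, "b": -x, "coverage": True})
        corr = pollutant_correlogram(df, ["a", "b"])
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert corr.loc["b", "a"] == corr.loc["a", "b"]

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=50), rng.normal(size=50)
        d1 = pd.DataFrame({"zip_id": range(50), "a": a, "b": b, "coverage": True})
        d2 = pd.DataFrame({"zip_id": range(50), "a": 100 * a + 3, "b": b, "coverage": True})
        c1 = pollutant_correlogram(d1, ["a", "b"])
        c2 = pollutant_correlogram(d2, ["a", "b"])
        assert c1.loc["a", "b"] == pytest.approx(c2.loc["a", "b"], rel=1e-12)

    def test_uncovered_zips_excluded_listwise(self):
        df = pd.DataFrame(
            {
                "zip_id": range(6),
                "a": [1.0, 2.0, 3.0, 4.0, np.nan, np.nan],
                "b": [2.0, 4.0, 6.0, 8.0, np.nan, np.nan],
                "coverage": [True] * 4 + [False] * 2,
            }
        )
        corr = pollutant_correlogram(df, ["a", "b"])
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_pollutant_yields_missing(self, caplog):
        df = pd.DataFrame(
            {"zip_id": range(10), "a": np.arange(10.0), "b": 5.0, "coverage": True}
        )
        corr = pollutant_correlogram(df, ["a", "b"])
        assert np.isnan(corr.loc["a", "b"])

    def test_too_few_pollutants_or_rows_rejected(self):
        df = pd.DataFrame({"zip_id": [1, 2], "a": [1.0, 2.0], "b": [1.0, 3.0], "coverage": True})
        with pytest.raises(ValueError):
            pollutant_correlogram(df, ["a"])
        with pytest.raises(ValueError):
            pollutant_correlogram(df, ["a", "b"])


class TestTrendScore:
    @staticmethod
    def _dr(rates):
        return pd.DataFrame({"bin": np.arange(1, len(rates) + 1), "rate": rates})

    def test_strictly_increasing_scores_one(self):
        assert monotonic_trend_score(self._dr([0.01, 0.02, 0.03, 0.05])) == 1.0

    def test_strictly_decreasing_scores_minus_one(self):
        assert monotonic_trend_score(self._dr([0.05, 0.03, 0.02, 0.01])) == -1.0

    def test_constant_rates_score_zero_by_convention(self):
        assert monotonic_trend_score(self._dr([0.02, 0.02, 0.02])) == 0.0

    def test_requires_three_bins(self):
        with pytest.raises(ValueError):
            monotonic_trend_score(self._dr([0.01, 0.02]))
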