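"""Unit conversion, seasonal accounting, bootstrap CIs, correlations."""

import numpy as np
import pandas as pd
import pytest

from caatingaflux.aggregate import (SeasonCalendar, bootstrap_ci,
                                    carbon_use_efficiency, ci_overlap,
                                    correlation_matrix, daily_sums,
                                    gc_to_umol, seasonal_summary, umol_to_gc,
                                    window_mean)


class TestUnitConversion:
    def test_zero(self):
        assert umol_to_gc(0.0) == 0.0

    def test_one_umol_over_a_day(self):
        assert umol_to_gc(1.0, 86400.0) == pytest.approx(1.0378, abs=1e-4)

    def test_one_umol_over_half_hour(self):
        assert umol_to_gc(1.0, 1800.0) == pytest.approx(0.021620, abs=1e-6)

    def test_round_trip(self):
        vals = np.array([-12.3, 0.0, 2.961, 1e-6])
        back = gc_to_umol(umol_to_gc(vals))
        assert np.allclose(back, vals, rtol=1e-12)

    def test_bad_dt(self):
        with pytest.raises(ValueError):
            umol_to_gc(1.0, 0.0)


class TestSeasonCalendar:
    def test_default_partitions_year(self):
        cal = SeasonCalendar()
        days = pd.date_range("2014-01-01", "2014-12-31", freq="D")
        labels = cal.labels(days)
        assert labels.notna().all()
        assert set(labels.unique()) == {"wet", "wet-dry", "dry", "dry-wet"}

    def test_wrapping_interval(self):
        cal = SeasonCalendar()
        assert cal.labels(pd.DatetimeIndex(["2014-12-15"])).iloc[0] == "dry-wet"
        assert cal.labels(pd.DatetimeIndex(["2014-01-10"])).iloc[0] == "dry-wet"

    def test_incomplete_coverage_rejected(self):
        with pytest.raises(ValueError):
            SeasonCalendar(intervals={"wet": ("01-01", "06-30")})


class TestSeasonalSums:
    def test_constant_flux_annual_sum(self):
        idx = pd.date_range("2014-01-01 00:30", periods=365 * 48, freq="30min")
        s = pd.Series(-1.0, index=idx)
        summary = seasonal_summary(s, n_boot=10)
        assert summary.loc["annual", "sum"] == pytest.approx(-378.8, abs=0.1)
        assert summary.loc["annual", "n_days"] == 365

    def test_seasonal_sums_partition_annual(self, default_year):
        series, _ = default_year
        summary = seasonal_summary(series["nee"], n_boot=10)
        seasonal = summary.drop(index="annual")["sum"].sum()
        assert seasonal == pytest.approx(summary.loc["annual", "sum"],
                                         rel=1e-12)

    def test_incomplete_day_prorated(self):
        idx = pd.date_range("2014-01-01 00:30", periods=72, freq="30min")
        s = pd.Series(-1.0, index=idx)  # day 1 complete, day 2 half
        daily = daily_sums(s)
        assert daily.iloc[0] == pytest.approx(umol_to_gc(-1.0, 86400.0))
        assert daily.iloc[1] == pytest.approx(umol_to_gc(-1.0, 86400.0))


class TestCarbonUseEfficiency:
    @pytest.mark.parametrize("nee, gpp, expected", [
        (-169.0, -414.7, 0.41),
        (-145.0, -334.0, 0.43),
        (-100.0, -100.0, 1.00),
    ])
    def test_reported_ratios(self, nee, gpp, expected):
        assert carbon_use_efficiency(nee, gpp) == pytest.approx(expected)

    def test_scale_invariance(self):
        assert carbon_use_efficiency(-50.0, -120.0) == \
            carbon_use_efficiency(-500.0, -1200.0)

    def test_zero_gpp_rejected(self):
        with pytest.raises(ValueError):
            carbon_use_efficiency(-10.0, 0.0)


class TestWindowMean:
    def test_constant_series(self):
        idx = pd.date_range("2014-01-01 00:30", periods=48 * 30, freq="30min")
        s = pd.Series(4.2, index=idx)
        res = window_mean(s, ("10:00", "12:00"))
        assert res.loc["annual", "mean"] == pytest.approx(4.2)
        assert res.loc["annual", "sd"] == pytest.approx(0.0)

    def test_full_day_window_equals_mean(self, default_year):
        series, _ = default_year
        res = window_mean(series["nee"], ("00:00", "00:00"))
        assert res.loc["annual", "mean"] == pytest.approx(series["nee"].mean())
        assert res.loc["annual", "n"] == len(series)

    def test_midnight_wrapping_window(self):
        idx = pd.date_range("2014-01-01 00:30", periods=48 * 2, freq="30min")
        hours = (idx - pd.Timedelta(minutes=15)).hour
        s = pd.Series(np.where((hours >= 22), -7.0, 1.0), index=idx)
        res = window_mean(s, ("22:00", "00:00"))
        assert res.loc["annual", "mean"] == pytest.approx(-7.0)

    def test_planted_midday_plateau_recovered(self):
        rng = np.random.default_rng(0)
        idx = pd.date_range("2014-02-01 00:30", periods=48 * 60, freq="30min")
        hours = (idx - pd.Timedelta(minutes=15)).hour
        vals = np.where((hours >= 10) & (hours < 12), -12.0, 0.0)
        s = pd.Series(vals + rng.normal(0, 0.5, len(idx)), index=idx)
        res = window_mean(s, ("10:00", "12:00"))
        assert res.loc["wet", "mean"] == pytest.approx(-12.0, abs=0.15)

    def test_empty_window_rejected(self):
        idx = pd.date_range("2014-01-01 00:30", periods=10, freq="30min")
        s = pd.Series(np.nan, index=idx)
        with pytest.raises(ValueError):
            window_mean(s, ("10:00", "12:00"))


class TestBootstrap:
    def test_constant_data_zero_width(self):
        mean, lo, hi = bootstrap_ci(np.full(50, 3.3), seed=0)
        assert mean == lo == hi == pytest.approx(3.3)

    def test_reproducible_under_seed(self):
        data = np.random.default_rng(0).normal(size=40)
        assert bootstrap_ci(data, seed=7) == bootstrap_ci(data, seed=7)

    def test_coverage(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(200):
            data = rng.normal(0, 1, 100)
            _, lo, hi = bootstrap_ci(data, n_boot=400,
                                     rng=np.random.default_rng(rng.integers(2**31)))
            hits += lo <= 0.0 <= hi
        assert hits / 200 >= 0.90

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (25, 100, 400):
            w = [(lambda r: r[2] - r[1])(bootstrap_ci(
                rng.normal(0, 1, n), n_boot=400,
                rng=np.random.default_rng(k))) for k in range(30)]
            widths.append(np.mean(w))
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.35)

    def test_too_few_values_flagged(self):
        mean, lo, hi = bootstrap_ci([1.0, 2.0], seed=0)
        assert mean == 1.5 and np.isnan(lo) and np.isnan(hi)

    def test_overlap_rule(self):
        assert ci_overlap((0.0, 1.0), (0.5, 2.0))
        assert not ci_overlap((0.0, 1.0), (1.1, 2.0))


class TestCorrelationMatrix:
    def test_self_and_exact_anticorrelation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": -x, "z": rng.normal(size=100)})
        r, p = correlation_matrix(df)
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert p.loc["x", "y"] < 1e-10
        assert ((r.fillna(0) <= 1) & (r.fillna(0) >= -1)).all().all()
        pd.testing.assert_frame_equal(r, r.T)

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"x": np.arange(20.0), "c": np.ones(20)})
        r, _ = correlation_matrix(df)
        assert np.isnan(r.loc["x", "c"])

    def test_planted_flux_dependence_signs(self, default_year):
        series, truth = default_year
        cal = SeasonCalendar()
        labels = cal.labels(series.index)
        wet = labels == "wet"
        df = pd.DataFrame({
            "nee": series["nee"][wet.values],
            "gpp": -truth.true_gpp[wet.values],  # signed, uptake negative
            "reco": truth.true_reco[wet.values],
        })
        r, p = correlation_matrix(df)
        assert r.loc["nee", "gpp"] > 0  # more uptake -> more negative NEE
        assert r.loc["gpp", "reco"] < 0  # productive times respire more
        assert p.loc["nee", "gpp"] < 0.01
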