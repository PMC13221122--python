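import numpy as np
import pandas as pd
import pytest

from heatmort import climate


class TestHeatIndex:
    def test_simple_formula_branch(self):
        # 20 C / 50 %: 0.5*(66.85 + 68) = 67.425 F = 19.6806 C
        assert climate.heat_index(20.0, 50.0) == pytest.approx(19.6806, abs=1e-3)

    def test_rothfusz_branch(self):
        # 86 F / 70 % lands in the regression region, ~95.07 F
        hi_f = climate.heat_index(30.0, 70.0) * 9 / 5 + 32
        assert hi_f == pytest.approx(95.07, abs=0.05)

    def test_cool_regime_tracks_temperature(self):
        assert abs(climate.heat_index(10.0, 80.0) - 10.0) < 1.5

    def test_out_of_range_humidity_raises(self):
        with pytest.raises(ValueError):
            climate.heat_index(25.0, 101.0)
        with pytest.raises(ValueError):
            climate.heat_index(25.0, -3.0)

    def test_monotone_in_humidity_when_warm(self):
        for t in np.arange(27.0, 40.0, 1.0):
            rh = np.arange(40.0, 100.5, 2.5)
            hi = climate.heat_index(np.full_like(rh, t), rh)
            assert np.all(np.diff(hi) >= -1e-9), f"non-monotone at T={t}"

    def test_never_far_below_temperature_outside_dry_extremes(self):
        # in hot-dry air (RH <~ 20 %) the NOAA index legitimately dips several
        # degrees below T; everywhere else it stays within 2 C of T or above
        tg, rg = np.meshgrid(np.arange(0.0, 45.0, 1.0), np.arange(25.0, 101.0, 5.0))
        hi = climate.heat_index(tg.ravel(), rg.ravel())
        assert np.all(hi >= tg.ravel() - 2.0)

    def test_adjustment_regions_are_continuousish(self):
        # low-RH and high-RH adjustments apply only in their NOAA windows
        base = climate.heat_index(32.3, 86.0)   # ~90 F, high-RH region
        off = climate.heat_index(32.3, 84.0)
        assert base > off  # monotone across the adjustment boundary


class TestCityHourlyMedian:
    def test_single_station_passthrough(self):
        df = pd.DataFrame({"datetime": [pd.Timestamp("2023-01-01 12:00")],
                           "station_id": ["A"], "temp_c": [25.0], "rh_pct": [60.0]})
        out = climate.city_hourly_median(df)
        assert out.loc[0, "t_median_c"] == 25.0
        assert out.loc[0, "hi_median_c"] == pytest.approx(climate.heat_index(25.0, 60.0))
        assert out.loc[0, "n_stations_used"] == 1

    def test_median_robust_to_extreme_station(self):
        ts = pd.Timestamp("2023-01-01 12:00")
        df = pd.DataFrame({"datetime": [ts] * 3, "station_id": list("ABC"),
                           "temp_c": [20.0, 25.0, 40.0], "rh_pct": [50.0] * 3})
        assert climate.city_hourly_median(df).loc[0, "t_median_c"] == 25.0

    def test_even_count_median_is_midpoint(self):
        ts = pd.Timestamp("2023-01-01 12:00")
        df = pd.DataFrame({"datetime": [ts] * 2, "station_id": list("AB"),
                           "temp_c": [20.0, 30.0], "rh_pct": [50.0] * 2})
        assert climate.city_hourly_median(df).loc[0, "t_median_c"] == 25.0

    def test_invariant_to_station_order(self, small_station_frame):
        shuffled = small_station_frame.sample(frac=1.0, random_state=1)
        a = climate.city_hourly_median(small_station_frame)
        b = climate.city_hourly_median(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_humidity_keeps_t_median(self):
        ts = pd.Timestamp("2023-01-01 12:00")
        df = pd.DataFrame({"datetime": [ts] * 3, "station_id": list("ABC"),
                           "temp_c": [20.0, 25.0, 30.0],
                           "rh_pct": [50.0, np.nan, 50.0]})
        out = climate.city_hourly_median(df)
        assert out.loc[0, "t_median_c"] == 25.0  # all three temperatures
        # HI median over the two stations with humidity
        his = [climate.heat_index(20.0, 50.0), climate.heat_index(30.0, 50.0)]
        assert out.loc[0, "hi_median_c"] == pytest.approx(np.mean(his))

    def test_empty_input(self):
        assert len(climate.city_hourly_median(pd.DataFrame(
            columns=["datetime", "station_id", "temp_c", "rh_pct"]))) == 0


class TestDailyMetrics:
    def _hours(self, values, day="2023-01-01"):
        ts = pd.date_range(day, periods=len(values), freq="h")
        return pd.DataFrame({"timestamp": ts, "t_median_c": values,
                             "hi_median_c": values, "n_stations_used": 1})

    def test_mean_of_constants(self):
        out = climate.daily_metrics(self._hours([20.0] * 24))
        assert out.loc[0, "t_med"] == 20.0

    def test_half_and_half(self):
        out = climate.daily_metrics(self._hours([20.0] * 12 + [30.0] * 12))
        assert out.loc[0, "t_med"] == 25.0

    def test_availability_rule(self):
        out23 = climate.daily_metrics(self._hours([20.0] * 22 + [43.0]), min_hours=18)
        assert out23.loc[0, "t_med"] == pytest.approx(np.mean([20.0] * 22 + [43.0]))
        out17 = climate.daily_metrics(self._hours([20.0] * 17), min_hours=18)
        assert not out17.loc[0, "complete"]
        assert np.isnan(out17.loc[0, "t_med"])


class TestThresholds:
    def _city_hours(self, hi_values, start="2020-01-01"):
        ts = pd.date_range(start, periods=len(hi_values), freq="h")
        return pd.DataFrame({"timestamp": ts, "t_median_c": hi_values,
                             "hi_median_c": hi_values, "n_stations_used": 1})

    def test_constant_series_collapses_quantiles(self):
        hours = self._city_hours(np.full(370 * 24, 28.0))
        th = climate.fit_thresholds(hours)
        assert th.hi_hourly_q90 == th.hi_hourly_q95 == th.hi_hourly_q975 == 28.0

    def test_quantiles_match_sort_oracle(self, rng):
        vals = rng.normal(26.0, 4.0, size=366 * 24)
        th = climate.fit_thresholds(self._city_hours(vals))
        # type-7 oracle via explicit order-statistic interpolation
        srt = np.sort(vals)
        for q, got in ((0.90, th.hi_hourly_q90), (0.95, th.hi_hourly_q95),
                       (0.975, th.hi_hourly_q975)):
            h = (len(srt) - 1) * q
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            expected = srt[lo] + (h - lo) * (srt[hi] - srt[lo])
            assert got == pytest.approx(expected, abs=1e-10)

    def test_insufficient_history_raises(self):
        with pytest.raises(ValueError, match="one year"):
            climate.fit_thresholds(self._city_hours(np.full(100 * 24, 28.0)))

    def test_count_cut_is_quantile_of_daily_counts(self, rng):
        vals = rng.normal(26.0, 4.0, size=400 * 24)
        hours = self._city_hours(vals)
        th = climate.fit_thresholds(hours)
        counts = (pd.Series(vals > th.hi_hourly_q90)
                  .groupby(np.arange(len(vals)) // 24).sum())
        assert th.count_cut_q90 == pytest.approx(np.quantile(counts, 0.90))

    def test_yaml_roundtrip(self, tmp_path):
        th = climate.ThresholdSet(32.14, 34.55, 36.39, 9.0, 6.0, 2.0)
        th.to_yaml(tmp_path / "th.yaml")
        assert climate.ThresholdSet.from_yaml(tmp_path / "th.yaml") == th


class TestDurationIndicator:
    @pytest.mark.parametrize("count,cut,expected", [
        (10, 9, 1),   # strictly above the cutoff -> high
        (9, 9, 0),    # equal to the cutoff -> normal
        (0, 0, 0),
        (0, 5, 0),
        (24, 23, 1),
    ])
    def test_strict_inequality(self, count, cut, expected):
        assert climate.duration_indicator(count, cut) == expected

    def test_hours_above_monotone_in_threshold(self, rng):
        vals = rng.normal(26.0, 4.0, size=366 * 24)
        ts = pd.date_range("2020-01-01", periods=len(vals), freq="h")
        hours = pd.DataFrame({"timestamp": ts, "t_median_c": vals,
                              "hi_median_c": vals, "n_stations_used": 1})
        th = climate.fit_thresholds(hours)
        counts = climate.hours_above(hours, th)
        assert (counts["hours_above_q90"] >= counts["hours_above_q95"]).all()
        assert (counts["hours_above_q95"] >= counts["hours_above_q975"]).all()
        assert counts[["hours_above_q90", "hours_above_q95", "hours_above_q975"]].max().max() <= 24
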