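import datetime as dt
import io

import numpy as np
import pandas as pd
import pytest

from alliumsim.weather import (CO2Trajectory, WeatherFormatError, WeatherSeries,
                               downscale_daily_to_hourly, read_weather,
                               synthesize_weather)


def _hourly_csv(n=24, rh=60.0):
    ts = pd.date_range("2020-01-01", periods=n, freq="h")
    df = pd.DataFrame({
        "timestamp": ts, "T_air": 10.0, "solar": 0.0,
        "RH": rh, "wind": 2.0, "CO2": 400.0,
    })
    return io.StringIO(df.to_csv(index=False))


def _daily_series(days):
    """days: list of (T_max, T_min, solar_total) tuples."""
    rows = [{"date": dt.date(2020, 1, 1) + dt.timedelta(days=i),
             "T_max": tx, "T_min": tn, "solar_total": s,
             "RH_mean": 70.0, "wind_mean": 2.0}
            for i, (tx, tn, s) in enumerate(days)]
    return WeatherSeries(pd.DataFrame(rows), cadence="daily")


class TestReadWeather:
    def test_hourly_identity_read(self):
        series = read_weather(_hourly_csv(24))
        assert series.cadence == "hourly"
        assert len(series) == 24

    def test_rh_out_of_range_names_row(self):
        with pytest.raises(WeatherFormatError, match="row 0.*RH"):
            read_weather(_hourly_csv(24, rh=120.0))

    def test_daily_read_flagged_for_downscaling(self):
        ws = _daily_series([(10, 0, 10)] * 3)
        buf = io.StringIO(ws.data.to_csv(index=False))
        series = read_weather(buf)
        assert series.cadence == "daily"
        assert len(series) == 3

    def test_non_monotone_timestamps_rejected(self):
        df = pd.read_csv(_hourly_csv(24))
        df.loc[5, "timestamp"] = df.loc[3, "timestamp"]
        with pytest.raises(WeatherFormatError, match="1-h step"):
            read_weather(io.StringIO(df.to_csv(index=False)))

    def test_unknown_header_rejected(self):
        with pytest.raises(WeatherFormatError, match="neither hourly"):
            read_weather(io.StringIO("a,b\n1,2\n"))


class TestDownscale:
    def test_degenerate_amplitude_constant(self):
        hourly = downscale_daily_to_hourly(_daily_series([(10, 10, 15)]), 33.0)
        assert np.allclose(hourly.data["T_air"], 10.0)

    def test_min_max_recovered_with_afternoon_peak(self):
        hourly = downscale_daily_to_hourly(_daily_series([(10, 0, 15)]), 33.0)
        t = hourly.data["T_air"].to_numpy()
        assert abs(t.min() - 0.0) <= 0.01
        assert abs(t.max() - 10.0) <= 0.01
        # monotone rise from dawn to the mid-afternoon peak
        assert t.argmax() == 14
        dawn = t.argmin()
        assert np.all(np.diff(t[dawn:15]) >= 0)

    def test_solar_integral_matches_daily_total(self):
        hourly = downscale_daily_to_hourly(_daily_series([(10, 0, 20)]), 33.0)
        total_mj = hourly.data["solar"].sum() * 3600 * 1e-6
        assert total_mj == pytest.approx(20.0, rel=0.01)
        # no solar when sun below horizon
        assert hourly.data["solar"].iloc[0] == 0.0
        assert hourly.data["solar"].iloc[23] == 0.0

    def test_empty_series_rejected(self):
        empty = WeatherSeries(pd.DataFrame(columns=[
            "date", "T_max", "T_min", "solar_total", "RH_mean", "wind_mean"]),
            cadence="daily")
        with pytest.raises(ValueError, match="empty"):
            downscale_daily_to_hourly(empty, 33.0)

    def test_round_trip_over_random_days(self):
        rng = np.random.default_rng(7)
        n = 1000
        t_min = rng.uniform(-20, 25, n)
        t_max = t_min + rng.uniform(0, 15, n)
        solar = rng.uniform(1, 30, n)
        days = list(zip(t_max, t_min, solar))
        hourly = downscale_daily_to_hourly(_daily_series(days), 35.0)
        t = hourly.data["T_air"].to_numpy().reshape(n, 24)
        s = hourly.data["solar"].to_numpy().reshape(n, 24)
        assert np.all(np.abs(t.min(axis=1) - t_min) <= 0.01)
        assert np.all(np.abs(t.max(axis=1) - t_max) <= 0.01)
        np.testing.assert_allclose(s.sum(axis=1) * 3600e-6, solar, rtol=0.01)


class TestSynthesize:
    def test_same_seed_reproducible(self):
        a = synthesize_weather("subtropical", years=1, seed=11)
        b = synthesize_weather("subtropical", years=1, seed=11)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_continental_winter_is_hard(self, continental_weather):
        df = continental_weather.data
        ts = pd.to_datetime(df["timestamp"])
        jan = df[ts.dt.month == 1]
        daily_min = jan.groupby(ts[ts.dt.month == 1].dt.date)["T_air"].min()
        assert daily_min.mean() < -10.0
        assert (df["T_air"] < -15.0).sum() >= 1

    def test_subtropical_winter_is_mild(self, subtropical_weather):
        df = subtropical_weather.data
        ts = pd.to_datetime(df["timestamp"])
        jan = df[ts.dt.month == 1]
        daily_min = jan.groupby(ts[ts.dt.month == 1].dt.date)["T_air"].min()
        assert daily_min.mean() > 0.0
        assert (df["T_air"] < -5.0).sum() == 0

    def test_monthly_means_track_profile(self):
        from alliumsim.weather import PROFILES
        series = synthesize_weather("subtropical", years=10, seed=5)
        df = series.data
        ts = pd.to_datetime(df["timestamp"])
        doy = ts.dt.dayofyear.to_numpy()
        target = PROFILES["subtropical"].seasonal_mean(doy)
        by_month = pd.DataFrame({
            "month": ts.dt.month, "t": df["T_air"].to_numpy(), "tgt": target,
        }).groupby("month").mean()
        assert np.all(np.abs(by_month["t"] - by_month["tgt"]) <= 1.0)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            synthesize_weather("subtropical", years=0, seed=1)
        with pytest.raises(ValueError, match="unknown profile"):
            synthesize_weather("tundra", years=1, seed=1)


class TestCO2Trajectory:
    def test_linear_segment_and_anchor_identity(self):
        traj = CO2Trajectory({2020: 400.0, 2030: 420.0}, "test")
        assert traj.at(2025.0) == pytest.approx(410.0)
        assert traj.at(2020.0) == pytest.approx(400.0)

    def test_piecewise_interpolation(self):
        traj = CO2Trajectory({2020: 400.0, 2030: 420.0, 2040: 450.0}, "test")
        assert traj.at(2035.0) == pytest.approx(435.0)
        assert traj.at(dt.date(2030, 1, 1)) == pytest.approx(420.0)

    def test_no_extrapolation(self):
        traj = CO2Trajectory({2020: 400.0, 2030: 420.0}, "test")
        with pytest.raises(ValueError, match="outside anchor range"):
            traj.at(2045.0)

    def test_invalid_anchors_rejected(self):
        with pytest.raises(ValueError):
            CO2Trajectory({2030: 400.0, 2020: 420.0}, "bad")
        with pytest.raises(ValueError):
            CO2Trajectory({2020: -5.0, 2030: 400.0}, "bad")
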