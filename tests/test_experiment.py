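import datetime as dt

import numpy as np
import pandas as pd
import pytest

from alliumsim import (DEFAULT_DOYS, ScanDesign, SimulationConfig, build_scan,
                       fresh_yield, optimal_planting, run_scan, run_season,
                       summarize_by_doy)
from alliumsim.experiment import group_periods


class TestFreshYield:
    def test_dry_to_fresh_conversion(self):
        # 3 g dry at 85% moisture -> 20 g fresh per plant
        assert fresh_yield(3.0, 1000.0, 0.85) == pytest.approx(20.0)

    def test_zero_moisture_identity(self):
        assert fresh_yield(3.0, 1000.0, 0.0) == pytest.approx(3.0)

    def test_per_area_yield(self):
        assert fresh_yield(3.0, 50.0, 0.85) == pytest.approx(1.0)

    def test_moisture_bound(self):
        with pytest.raises(ValueError):
            fresh_yield(3.0, 50.0, 1.0)


class TestScanDesign:
    def test_default_grid_is_twelve_dates(self):
        assert DEFAULT_DOYS == tuple(range(240, 351, 10))
        assert len(DEFAULT_DOYS) == 12

    def test_historical_scan_count(self):
        design = ScanDesign(weather_seeds=tuple(range(10)))
        assert design.n_runs == 120
        assert len(build_scan(design)) == 120

    def test_rcp_scan_count(self):
        design = ScanDesign(weather_seeds=tuple(range(80)))
        assert len(build_scan(design)) == 960

    def test_single_cell(self):
        design = ScanDesign(doys=(250,), weather_seeds=(0,))
        assert len(build_scan(design)) == 1

    def test_configs_cross_year_boundary(self):
        design = ScanDesign(doys=(350,), weather_seeds=(0,), start_year=2020)
        _, doy, cfg = build_scan(design)[0]
        assert cfg.planting_date == dt.date(2020, 12, 15)
        assert cfg.resolved_harvest_date() == dt.date(2021, 5, 15)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            ScanDesign(doys=())


class TestOptimalPlanting:
    def test_argmax_over_doys(self):
        df = pd.DataFrame({"seed": 0, "doy": [240, 250, 260],
                           "fresh_yield": [5.0, 7.0, 6.0]})
        out = optimal_planting(df)
        assert out.loc[0, "optimal_doy"] == 250

    def test_tie_broken_toward_earlier_doy(self):
        df = pd.DataFrame({"seed": 0, "doy": [260, 250],
                           "fresh_yield": [7.0, 7.0]})
        out = optimal_planting(df)
        assert out.loc[0, "optimal_doy"] == 250

    def test_future_grouping_pools_fifty_samples(self):
        # 10 weather seeds x 5 decades per period -> 50 samples per point
        rows = [{"seed": s, "decade": d, "doy": 240, "fresh_yield": 1.0}
                for s in range(10) for d in range(8)]
        out = group_periods(pd.DataFrame(rows), decades_per_period=5)
        assert set(out["n"]) <= {50, 30}
        assert out.loc[out["period"] == 0, "n"].iloc[0] == 50


class TestRunSeason:
    def test_deterministic_for_identical_config(self, rue_config, subtropical_weather):
        r1 = run_season(rue_config, subtropical_weather)
        r2 = run_season(rue_config, subtropical_weather)
        pd.testing.assert_frame_equal(r1.daily, r2.daily)
        assert r1.fresh_yield == r2.fresh_yield

    def test_benign_year_grows_a_bulb_without_mortality(self, subtropical_season,
                                                        rue_config):
        assert subtropical_season.bulb_dry > 0
        assert subtropical_season.final_pd == rue_config.cold_damage.pd_0

    def test_continental_winter_collapses_yield(self, continental_season):
        assert continental_season.fresh_yield < 0.2
        assert continental_season.final_pd < 1.0

    def test_event_log_covers_the_season(self, subtropical_season):
        kinds = [e for _, e in subtropical_season.events]
        assert "vegetative" in kinds          # emergence
        assert any(k.startswith("leaf_") for k in kinds)
        assert "R2" in kinds and "scape_removed" in kinds
        assert kinds[-1] == "harvest"

    def test_weather_gap_is_an_error(self, rue_config, subtropical_weather):
        from alliumsim.weather import WeatherSeries
        truncated = WeatherSeries(
            subtropical_weather.data.iloc[: 300 * 24].reset_index(drop=True),
            cadence="hourly")
        with pytest.raises(ValueError, match="weather gap"):
            run_season(rue_config.with_(
                planting_date=dt.date(2020, 10, 10)), truncated)


@pytest.fixture(scope="module")
def small_scan(rue_config):
    design = ScanDesign(doys=(250, 290, 330), weather_seeds=(0, 1),
                        base_config=rue_config)
    return run_scan(design)


class TestScan:

    def test_tidy_output_shape(self, small_scan):
        assert len(small_scan) == 6
        assert set(small_scan["doy"]) == {250, 290, 330}

    def test_summary_mean_sd(self, small_scan):
        summary = summarize_by_doy(small_scan)
        assert len(summary) == 3
        assert (summary["n"] == 2).all()
        assert (summary["sd_yield"] >= 0).all()

    def test_clamping_cold_never_lowers_yield(self, rue_config):
        """Removing sub-zero hours can only help: cold stress only harms."""
        from alliumsim.weather import WeatherSeries, synthesize_weather
        w = synthesize_weather("continental", years=2, seed=0)
        clamped = WeatherSeries(
            w.data.assign(T_air=w.data["T_air"].clip(lower=0.0)),
            cadence="hourly")
        for doy in (250, 290, 330):
            planting = dt.date(2020, 1, 1) + dt.timedelta(days=doy - 1)
            cfg = rue_config.with_(planting_date=planting,
                                   harvest_date=dt.date(2021, 5, 15))
            y_cold = run_season(cfg, w).fresh_yield
            y_clamped = run_season(cfg, clamped).fresh_yield
            assert y_clamped >= y_cold
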