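"""Planting-date x climate-scenario experiment design and analysis.

The factorial follows the published design: planting dates from DOY 240 to
350 in 10-day steps (12 dates), each crossed with a set of seeded weather
datasets.  The historical scenario uses one 30-year window with 10
stochastic repetitions (120 runs); each future scenario uses 8 decade
windows x 10 repetitions = 80 weather datasets (960 runs).  Yield-vs-DOY
curves are summarized as mean +/- SD; the optimal planting date for a
year/replicate is the argmax over DOYs, ties broken toward the earlier
date.  Future period groupings pool 10 seeds x 5 decades = 50 samples per
data point.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .simulation import SeasonResult, run_season
from .weather import WeatherSeries, synthesize_weather

__all__ = ["ScanDesign", "build_scan", "run_scan", "optimal_planting",
           "summarize_by_doy", "DEFAULT_DOYS"]

DEFAULT_DOYS = tuple(range(240, 351, 10))   # 240, 250, ..., 350


def _doy_to_date(year: int, doy: int) -> dt.date:
    return dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)


@dataclass(frozen=True)
class ScanDesign:
    """Planting-date grid crossed with seeded weather datasets."""

    doys: tuple = DEFAULT_DOYS
    profile: str = "subtropical"
    weather_seeds: tuple = tuple(range(10))
    severity: float = 1.0
    start_year: int = 2020
    co2: float = 400.0
    base_config: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not self.doys or not self.weather_seeds:
            raise ValueError("need at least one DOY and one weather dataset")

    @property
    def n_runs(self) -> int:
        return len(self.doys) * len(self.weather_seeds)


def build_scan(design: ScanDesign) -> list[tuple[int, int, SimulationConfig]]:
    """Cartesian product of DOYs and weather seeds as (seed, doy, config)."""
    configs = []
    for seed in design.weather_seeds:
        for doy in design.doys:
            cfg = design.base_config.with_(
                planting_date=_doy_to_date(design.start_year, doy),
                harvest_date=dt.date(design.start_year + 1, 5, 15),
            )
            configs.append((seed, doy, cfg))
    return configs


def run_scan(design: ScanDesign, weather_cache: dict | None = None) -> pd.DataFrame:
    """Run the full factorial; one synthetic weather dataset per seed.

    Returns a tidy frame with columns seed, doy, fresh_yield, bulb_dry,
    scape_yield, final_pd.
    """
    cache = weather_cache if weather_cache is not None else {}
    records = []
    for seed, doy, cfg in build_scan(design):
        if seed not in cache:
            cache[seed] = synthesize_weather(
                design.profile, years=2, seed=seed,
                severity=design.severity, start_year=design.start_year,
                co2=design.co2,
            )
        result = run_season(cfg, cache[seed])
        records.append({
            "seed": seed,
            "doy": doy,
            "fresh_yield": result.fresh_yield,
            "bulb_dry": result.bulb_dry,
            "scape_yield": result.scape_yield,
            "final_pd": result.final_pd,
        })
    return pd.DataFrame(records)


def summarize_by_doy(results: pd.DataFrame) -> pd.DataFrame:
    """Yield-vs-DOY curve: mean, SD and n across replicates per DOY."""
    g = results.groupby("doy")["fresh_yield"]
    out = pd.DataFrame({
        "mean_yield": g.mean(),
        "sd_yield": g.std(ddof=1).fillna(0.0),
        "n": g.size(),
    }).reset_index()
    return out


def optimal_planting(results: pd.DataFrame, by: str = "seed") -> pd.DataFrame:
    """Optimal planting DOY per replicate group: argmax yield, earliest-DOY ties.

    ``results`` must carry columns [by, 'doy', 'fresh_yield'] with at least
    one row per DOY per group.
    """
    rows = []
    for key, grp in results.groupby(by):
        grp = grp.sort_values("doy")   # earliest DOY wins ties
        best = grp.loc[grp["fresh_yield"].idxmax()] if len(grp) else None
        # idxmax returns the first occurrence of the max after the sort
        rows.append({by: key,
                     "optimal_doy": int(best["doy"]),
                     "max_yield": float(best["fresh_yield"])})
    return pd.DataFrame(rows)


def group_periods(results: pd.DataFrame, decades_per_period: int = 5) -> pd.DataFrame:
    """Pool decade windows into periods; n = seeds x decades per data point."""
    if "decade" not in results.columns:
        raise ValueError("results must carry a 'decade' column to group periods")
    results = results.copy()
    results["period"] = (
        results["decade"] - results["decade"].min()
    ) // decades_per_period
    g = results.groupby(["period", "doy"])["fresh_yield"]
    return pd.DataFrame({
        "mean_yield": g.mean(),
        "sd_yield": g.std(ddof=1).fillna(0.0),
        "n": g.size(),
    }).reset_index()
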