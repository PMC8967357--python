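"""Whole-season simulation loop binding phenology, cold stress, carbon
assimilation, allocation and morphology on an hourly weather clock.

Hourly processes: leaf-tip appearance accumulation, scape-appearance
progress, canopy assimilation (vectorized over each day's 24 hours).
Daily processes: cold injury/mortality from the daily minimum temperature,
leaf elongation and senescence at the daily mean, carbon pool drainage and
partitioning, stage transitions, state logging.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import carbon
from .allocation import (CarbonPool, OrganBiomass, PartitionTable, partition,
                         remove_scape, step_pool)
from .coldstress import ColdState
from .config import SimulationConfig
from .morphology import Canopy, lai
from .phenology import (STAGE_NAMES, DevStage, PhyllochronState, StageTracker,
                        StorageConditions, initial_ltar)
from .thermal import growing_degree_days
from .weather import WeatherSeries

__all__ = ["SeasonResult", "run_season", "fresh_yield"]


def fresh_yield(bulb_dry: float, plant_density: float, moisture: float = 0.85) -> float:
    """Fresh bulb yield, kg m^-2, from dry mass per plant at given moisture."""
    if not 0.0 <= moisture < 1.0:
        raise ValueError("moisture must lie in [0, 1)")
    if bulb_dry < 0 or plant_density < 0:
        raise ValueError("inputs must be >= 0")
    return bulb_dry / (1.0 - moisture) * plant_density / 1000.0


@dataclass
class SeasonResult:
    """Outcome of one planting-to-harvest simulation."""

    daily: pd.DataFrame
    bulb_dry: float          # g per plant at harvest
    fresh_yield: float       # kg m^-2
    scape_yield: float       # g per plant (removed scape mass)
    final_pd: float          # plants m^-2
    events: list = field(default_factory=list)
    config: SimulationConfig | None = None


def _scape_removal_date(cfg: SimulationConfig):
    if cfg.scape_removal.startswith("date:"):
        return dt.date.fromisoformat(cfg.scape_removal[5:])
    return None


def run_season(cfg: SimulationConfig, weather: WeatherSeries) -> SeasonResult:
    """Simulate one season; deterministic for a given config and weather."""
    planting = cfg.planting_date
    harvest = cfg.resolved_harvest_date()
    hourly = weather.slice_dates(planting, harvest)
    ts = pd.to_datetime(hourly["timestamp"])
    days = pd.unique(ts.dt.date)

    storage = StorageConditions(sd=cfg.storage_duration(),
                                st=cfg.phyllochron.storage_temp)
    phyllo = PhyllochronState(r0=initial_ltar(storage, cfg.phyllochron),
                              params=cfg.phyllochron)
    stages = StageTracker(emergence_gdd=cfg.emergence_gdd,
                          repro_gdd=cfg.repro_gdd)
    cold = ColdState(injury=cfg.cold_injury, damage=cfg.cold_damage)
    canopy = Canopy(params=cfg.leaf, response=cfg.ler_response,
                    total_leaves=cfg.phyllochron.total_leaves)
    pool = CarbonPool(mass=cfg.growth.initial_reserve)
    table = PartitionTable(cfg.partition_table)
    biomass = OrganBiomass()
    scape_yield = 0.0
    removal_date = _scape_removal_date(cfg)
    dt_hour = 1.0 / 24.0

    rows = []
    values = hourly[["T_air", "solar", "RH", "wind", "CO2"]].to_numpy()
    n_days = len(days)
    for di in range(n_days):
        day = days[di]
        block = values[di * 24:(di + 1) * 24]
        t_air = block[:, 0]
        t_min, t_mean = float(t_air.min()), float(t_air.mean())

        # --- daily cold stress from the day's minimum temperature
        e_t = cold.step_day(t_min)

        # --- hourly phenology
        appearances = 0
        if stages.stage >= DevStage.VEGETATIVE:
            for t_h in t_air:
                n = phyllo.step(float(t_h), dt_hour, cfg.ltar_response)
                appearances += n
                f = float(cfg.ltar_response(float(t_h)))
                stages.add_scape_progress(phyllo.ltar_max, f, dt_hour, day)
                if stages.stage == DevStage.R2:
                    break
        for _ in range(appearances):
            if len(canopy.leaves) < cfg.phyllochron.total_leaves:
                canopy.add_leaf()
                stages.events.append((day, f"leaf_{len(canopy.leaves)}"))

        # --- scape removal policy
        if stages.stage == DevStage.R2:
            due = (cfg.scape_removal == "immediate"
                   or (removal_date is not None and day >= removal_date))
            if due:
                biomass, removed = remove_scape(biomass, cfg.scape_visible_fraction)
                scape_yield += removed
                stages.remove_scape(day)
                stages.events.append((day, "scape_removed"))

        # --- canopy carbon assimilation (per plant)
        green = canopy.green_area()
        lai_now = lai(green, cold.pd)
        assim = 0.0
        if lai_now > 0:
            env = carbon.CanopyEnvironment(
                solar=block[:, 1], t_air=t_air, rh=block[:, 2],
                wind=block[:, 3], co2=block[:, 4], lai=lai_now,
            )
            if cfg.carbon_source == "coupled":
                assim = carbon.canopy_assimilation(env, cfg.gas_exchange, cold.pd)
            else:
                assim = carbon.rue_assimilation(env, cfg.rue, cold.pd)

        # --- pool drainage and partitioning
        step = step_pool(pool, assim, biomass, t_mean, cfg.growth)
        increments = partition(step.allocation_rate, stages.stage, table)
        biomass = biomass.add(increments)

        # --- leaf elongation (injury-scaled) and senescence
        gdd = growing_degree_days(t_mean, cfg.gdd_base)
        if stages.stage >= DevStage.VEGETATIVE:
            canopy.grow(t_mean, e_t)
            canopy.senesce(gdd)

        # --- stage thermal time (may fire emergence / reproductive onset)
        stages.add_gdd(gdd, day)

        rows.append({
            "date": day,
            "stage": STAGE_NAMES[stages.stage],
            "T_min": t_min,
            "T_mean": t_mean,
            "leaf_count": len(canopy.leaves),
            "green_area": green,
            "lai": lai_now,
            "assimilate": assim,
            "allocation": step.allocation_rate,
            "maintenance": step.maintenance_paid,
            "pool": pool.mass,
            "E_cold": e_t,
            "PD": cold.pd,
            "root": biomass.root,
            "leaf": biomass.leaf,
            "sheath": biomass.sheath,
            "scape": biomass.scape,
            "bulb": biomass.bulb,
            "stalk": biomass.stalk,
        })

    daily = pd.DataFrame(rows)
    stages.events.append((harvest, "harvest"))
    return SeasonResult(
        daily=daily,
        bulb_dry=biomass.bulb,
        fresh_yield=fresh_yield(biomass.bulb, cold.pd, cfg.moisture),
        scape_yield=scape_yield,
        final_pd=cold.pd,
        events=list(stages.events),
        config=cfg,
    )
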