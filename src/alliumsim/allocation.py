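"""Carbon pool bookkeeping and stage-dependent partitioning to organs.

Assimilate enters a whole-plant carbon pool which is drained within the
same timestep it is filled (supply rate = pool / dt).  Maintenance
respiration, a Q10 function of temperature and organ biomass, is paid
first; the remainder is converted to structural growth with carbohydrate
synthesis efficiency Y_g (the (1 - Y_g) share is growth respiration) and
split among root, leaf, sheath, scape and bulb by the stage-row of the
partitioning table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import DEFAULT_PARTITION, GrowthParams
from .phenology import DevStage, STAGE_NAMES

ORGANS = ("root", "leaf", "sheath", "scape", "bulb")
LIVING_STAGES = ("seed", "vegetative", "R1", "R2", "R3")


@dataclass(frozen=True)
class OrganBiomass:
    """Dry structural biomass per organ, g per plant."""

    root: float = 0.0
    leaf: float = 0.0
    sheath: float = 0.0
    scape: float = 0.0
    bulb: float = 0.0

    def __post_init__(self) -> None:
        for organ in ORGANS:
            if getattr(self, organ) < 0:
                raise ValueError(f"{organ} biomass must be >= 0")

    @property
    def stalk(self) -> float:
        return self.sheath + self.scape

    @property
    def total(self) -> float:
        return sum(getattr(self, o) for o in ORGANS)

    def add(self, increments: dict) -> "OrganBiomass":
        return replace(self, **{
            o: getattr(self, o) + increments.get(o, 0.0) for o in ORGANS
        })


class PartitionTable:
    """Stage x organ matrix of partitioning coefficients.

    Living-stage rows must sum to one; the death row is all zeros; the
    scape column is zero in the vegetative stage (no scape yet) and in R3
    (organ removed).
    """

    def __init__(self, rows: dict | None = None):
        rows = rows if rows is not None else DEFAULT_PARTITION
        self.rows = {}
        for stage in list(LIVING_STAGES) + ["death"]:
            if stage not in rows:
                raise ValueError(f"partition table missing row for stage {stage!r}")
            row = np.asarray(rows[stage], dtype=float)
            if row.shape != (len(ORGANS),):
                raise ValueError(f"stage {stage!r}: expected {len(ORGANS)} coefficients")
            if np.any(row < 0) or np.any(row > 1):
                raise ValueError(f"stage {stage!r}: coefficients must lie in [0, 1]")
            self.rows[stage] = row
        if np.any(self.rows["death"] != 0):
            raise ValueError("death row must be all zeros")
        for stage in LIVING_STAGES:
            if abs(self.rows[stage].sum() - 1.0) > 1e-9:
                raise ValueError(f"stage {stage!r}: row must sum to 1")
        scape_idx = ORGANS.index("scape")
        for stage in ("vegetative", "R3"):
            if self.rows[stage][scape_idx] != 0:
                raise ValueError(f"stage {stage!r}: scape coefficient must be 0")

    def row(self, stage) -> np.ndarray:
        name = STAGE_NAMES[stage] if isinstance(stage, DevStage) else stage
        if name not in self.rows:
            raise ValueError(f"no partition row for stage {name!r}")
        return self.rows[name]


@dataclass
class CarbonPool:
    """Whole-plant assimilate pool, g CH2O; never negative."""

    mass: float = 0.0

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("pool mass must be >= 0")


def maintenance_rate(biomass: OrganBiomass, t_air: float, p: GrowthParams) -> float:
    """Maintenance respiration, g CH2O d^-1 (Q10 about 25 degC)."""
    q = p.q10 ** ((t_air - 25.0) / 10.0)
    coeffs = (p.maint_root, p.maint_leaf, p.maint_sheath, p.maint_scape, p.maint_bulb)
    return q * sum(c * getattr(biomass, o) for c, o in zip(coeffs, ORGANS))


@dataclass
class PoolStep:
    """One timestep of pool accounting (all in g CH2O or g CH2O d^-1)."""

    allocation_rate: float   # structural growth rate (Y_g applied)
    maintenance_paid: float  # respiration actually paid this step, g
    pool_after: float


def step_pool(
    pool: CarbonPool, assimilate: float, biomass: OrganBiomass,
    t_air: float, p: GrowthParams, dt_days: float = 1.0,
) -> PoolStep:
    """Drain the pool for one step: maintenance first, then growth at Y_g.

    Net-negative assimilation hours can make the incoming supply negative;
    the pool floors at zero (carbon debt is not tracked) and allocation is
    capped at what the pool plus incoming assimilate can pay.
    """
    if dt_days <= 0:
        raise ValueError("dt must be positive")
    available = max(pool.mass + assimilate, 0.0)   # g over the step
    supply = available / dt_days                   # g d^-1
    maint = maintenance_rate(biomass, t_air, p)    # g d^-1
    maint_paid = min(maint, supply) * dt_days
    growth_carbon = max(supply - maint, 0.0) * dt_days
    allocation = growth_carbon * p.y_g / dt_days   # g d^-1 structural
    pool.mass = available - maint_paid - growth_carbon
    if pool.mass < 1e-12:
        pool.mass = 0.0
    return PoolStep(allocation_rate=allocation,
                    maintenance_paid=maint_paid,
                    pool_after=pool.mass)


def partition(
    allocation_rate: float, stage, table: PartitionTable, dt_days: float = 1.0,
) -> dict:
    """Split an allocation rate into per-organ increments (g) for one step.

    Increments sum to allocation_rate * dt exactly (rows are renormalized
    against float drift); the death row yields all zeros.
    """
    if allocation_rate < 0:
        raise ValueError("allocation rate must be >= 0")
    row = table.row(stage)
    total = row.sum()
    if total == 0:
        return {o: 0.0 for o in ORGANS}
    weights = row / total
    amount = allocation_rate * dt_days
    return {o: float(w * amount) for o, w in zip(ORGANS, weights)}


def remove_scape(biomass: OrganBiomass, visible_fraction: float = 1.0):
    """Cut the visible portion of the scape; returns (biomass, removed g)."""
    if not 0.0 <= visible_fraction <= 1.0:
        raise ValueError("visible_fraction must lie in [0, 1]")
    removed = biomass.scape * visible_fraction
    return replace(biomass, scape=biomass.scape - removed), removed
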