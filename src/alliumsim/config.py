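"""Configuration dataclasses for the garlic simulator.

Defaults reproduce the published Namdo (ND) cultivar parameter set for the
dynamic phyllochron and cold-stress responses, plus documented estimates for
quantities the underlying model family requires but which are calibrated
per-site (partitioning coefficients, gas-exchange constants, planting
density).  Every dataclass validates its invariants on construction.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

from .thermal import BetaResponse

__all__ = [
    "PhyllochronParams",
    "ColdInjuryParams",
    "ColdDamageParams",
    "GasExchangeParams",
    "GrowthParams",
    "LeafParams",
    "SimulationConfig",
    "load_config",
]


@dataclass(frozen=True)
class PhyllochronParams:
    """Dynamic phyllochron parameters (storage-conditioned leaf appearance)."""

    ltar_max_a: float = 0.4421   # d^-1, maximal leaf tip appearance asymptote
    sd_m: float = 117.7523       # d, storage days at half asymptote
    alpha: float = 0.0256        # d^-1, sigmoid steepness
    n_g: int = 10                # generic leaf number (convergence rank)
    iln: int = 6                 # initial leaf number in the seed clove
    storage_temp: float = 8.0    # degC; retained in config but inert (see docs)
    total_leaves: int = 16       # cap on initiable leaves (plausibility default)

    def __post_init__(self) -> None:
        if self.ltar_max_a <= 0:
            raise ValueError("ltar_max_a must be positive")
        if self.n_g < 1:
            raise ValueError("n_g must be >= 1")
        if self.total_leaves < self.iln:
            raise ValueError("total_leaves must be >= iln")


@dataclass(frozen=True)
class ColdInjuryParams:
    """Recoverable cold-injury parameters (leaf elongation scaling)."""

    t_c_i: float = 0.0   # degC, critical temperature for cold injury
    a: float = -0.1      # injury factor 1
    b: float = 1.6       # injury factor 2


@dataclass(frozen=True)
class ColdDamageParams:
    """Irreversible cold-damage (mortality) parameters."""

    t_c_d: float = -15.0   # degC, critical temperature for cold damage
    s: float = 0.9         # logistic shape factor
    pd_0: float = 45.0     # plants m^-2, initial planting density (estimate)

    def __post_init__(self) -> None:
        if self.pd_0 <= 0:
            raise ValueError("pd_0 must be positive")


@dataclass(frozen=True)
class GasExchangeParams:
    """Coupled C3 gas-exchange constants.

    The garlic-specific values live in earlier leaf-level studies; the
    defaults here are standard C3 kinetics (Bernacchi temperature responses,
    Ball-Berry stomatal model) and are flagged as estimates.  None of the
    package's analytic results depend on their exact values.
    """

    vcmax25: float = 100.0   # umol m^-2 s^-1
    jmax25: float = 180.0    # umol m^-2 s^-1
    rd25: float = 1.5        # umol m^-2 s^-1, dark respiration at 25 degC
    theta: float = 0.7       # curvature of light response
    phi: float = 0.3         # mol e- per mol photon, quantum yield
    g0: float = 0.02         # mol m^-2 s^-1, Ball-Berry intercept
    g1: float = 9.0          # Ball-Berry slope
    gb: float = 1.5          # mol m^-2 s^-1, boundary-layer conductance base
    k_beam: float = 0.5      # canopy extinction, direct beam
    k_diff: float = 0.7      # canopy extinction, diffuse
    beam_fraction: float = 0.7   # direct fraction of PAR when sun is up
    ppfd_per_watt: float = 2.3   # umol photons J^-1 shortwave (half is PAR)
    leaf_absorptance: float = 0.85

    # Arrhenius/peaked temperature-response constants (J mol^-1)
    ea_vcmax: float = 65330.0
    ea_jmax: float = 43540.0
    hd: float = 152040.0
    sv: float = 495.0
    ea_rd: float = 46390.0


@dataclass(frozen=True)
class GrowthParams:
    """Carbon pool bookkeeping: synthesis efficiency and maintenance costs."""

    y_g: float = 0.75   # carbohydrate synthesis efficiency
    # maintenance coefficients, g CH2O per g organ per day at 25 degC
    maint_root: float = 0.008
    maint_leaf: float = 0.012
    maint_sheath: float = 0.006
    maint_scape: float = 0.006
    maint_bulb: float = 0.003
    q10: float = 2.0
    initial_reserve: float = 2.0   # g CH2O, seed-clove reserve fueling emergence

    def __post_init__(self) -> None:
        if not 0.0 < self.y_g <= 1.0:
            raise ValueError("y_g must lie in (0, 1]")


@dataclass(frozen=True)
class LeafParams:
    """Individual leaf growth, geometry and senescence parameters."""

    ler_max: float = 5.56       # cm d^-1, maximal leaf elongation rate
    lm_min: float = 100.0       # cm, minimum length of the longest leaf
    sg: float = 1.5             # stay green, multiplier on green duration
    expansion_days: int = 18    # days to full expansion at optimum
    width_ratio: float = 0.02   # leaf max width as fraction of final length
    form_factor: float = 0.75   # area = length * width * form_factor
    peak_rank_fraction: float = 0.7   # rank of the longest leaf / total leaves
    base_length_fraction: float = 0.3  # rank-1 length as fraction of lm_min
    green_duration_gdd: float = 500.0  # degC d of full greenness before decline
    senescence_gdd: float = 300.0      # degC d over which green fraction falls

    def __post_init__(self) -> None:
        if self.ler_max <= 0 or self.lm_min <= 0:
            raise ValueError("ler_max and lm_min must be positive")
        # the cultivar defaults tie elongation rate to expansion duration
        if abs(self.ler_max * self.expansion_days - self.lm_min) > 0.02 * self.lm_min:
            raise ValueError(
                "ler_max * expansion_days should equal lm_min (within 2%)"
            )


DEFAULT_PARTITION = {
    #            root  leaf  sheath scape bulb
    "seed":       [0.35, 0.45, 0.20, 0.00, 0.00],
    "vegetative": [0.15, 0.45, 0.30, 0.00, 0.10],
    "R1":         [0.05, 0.15, 0.20, 0.10, 0.50],
    "R2":         [0.05, 0.10, 0.10, 0.15, 0.60],
    "R3":         [0.05, 0.05, 0.05, 0.00, 0.85],
    "death":      [0.00, 0.00, 0.00, 0.00, 0.00],
}


@dataclass(frozen=True)
class SimulationConfig:
    """Whole-season simulation configuration."""

    planting_date: dt.date = dt.date(2020, 10, 10)
    harvest_date: Optional[dt.date] = None  # default: May 15 of the next year
    seed_harvest_date: tuple[int, int] = (6, 30)  # month, day of seed harvest
    scape_removal: str = "immediate"  # none | immediate | date:YYYY-MM-DD
    moisture: float = 0.85            # bulb fresh moisture fraction
    carbon_source: str = "coupled"    # coupled | rue
    rue: float = 1.5                  # g CH2O MJ^-1 (RUE fallback)
    emergence_gdd: float = 100.0      # degC d (base 4) planting -> emergence
    repro_gdd: float = 800.0          # degC d (base 4) emergence -> R1 onset
    gdd_base: float = 4.0
    phyllochron: PhyllochronParams = field(default_factory=PhyllochronParams)
    cold_injury: ColdInjuryParams = field(default_factory=ColdInjuryParams)
    cold_damage: ColdDamageParams = field(default_factory=ColdDamageParams)
    gas_exchange: GasExchangeParams = field(default_factory=GasExchangeParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    leaf: LeafParams = field(default_factory=LeafParams)
    ltar_response: BetaResponse = field(default_factory=lambda: BetaResponse(22.0, 34.0))
    ler_response: BetaResponse = field(default_factory=lambda: BetaResponse(20.0, 34.0))
    partition_table: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_PARTITION.items()
    })
    scape_visible_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.moisture < 1.0:
            raise ValueError("moisture must lie in [0, 1)")
        if self.carbon_source not in ("coupled", "rue"):
            raise ValueError("carbon_source must be 'coupled' or 'rue'")
        if self.scape_removal not in ("none", "immediate") and not self.scape_removal.startswith("date:"):
            raise ValueError("scape_removal must be none | immediate | date:YYYY-MM-DD")
        if self.resolved_harvest_date() <= self.planting_date:
            raise ValueError("harvest must follow planting")

    def resolved_harvest_date(self) -> dt.date:
        if self.harvest_date is not None:
            return self.harvest_date
        return dt.date(self.planting_date.year + 1, 5, 15)

    def storage_duration(self) -> float:
        """Days from the assumed seed-bulb harvest (June 30) to planting."""
        m, d = self.seed_harvest_date
        sh = dt.date(self.planting_date.year, m, d)
        if sh > self.planting_date:
            sh = dt.date(self.planting_date.year - 1, m, d)
        return float((self.planting_date - sh).days)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _build(section: dict, cls):
    return cls(**section) if section else cls()


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML document with per-module sections."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    simple = {
        "planting_date", "harvest_date", "scape_removal", "moisture",
        "carbon_source", "rue", "emergence_gdd", "repro_gdd", "gdd_base",
        "partition_table", "scape_visible_fraction",
    }
    for key in simple & set(doc):
        val = doc[key]
        if key.endswith("_date") and isinstance(val, str):
            val = dt.date.fromisoformat(val)
        kwargs[key] = val
    sections = {
        "phyllochron": PhyllochronParams,
        "cold_injury": ColdInjuryParams,
        "cold_damage": ColdDamageParams,
        "gas_exchange": GasExchangeParams,
        "growth": GrowthParams,
        "leaf": LeafParams,
    }
    for name, cls in sections.items():
        if name in doc:
            kwargs[name] = _build(doc[name], cls)
    return SimulationConfig(**kwargs)
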