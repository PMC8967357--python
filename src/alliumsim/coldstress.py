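"""Cold stress: recoverable injury to leaf elongation and frost mortality.

Two pathways, both driven by daily minimum air temperature:

* **Cold injury** slows leaf elongation reversibly.  A cold-day counter D
  rises by one for each day below the injury threshold T_c_i and falls by
  one (floored at zero) for each day at or above it.  The apparent injury
  C = clip(ln(a*(T - T_c_i) + b), 0, 1) deepens as temperature falls; the
  applied effect E = 1 - C^(1/D) worsens with exposure length and, within
  an episode (D > 0), can only ratchet downward: E(t) = min(E, E(t-1)).
  When D returns to zero E resets to 1.  Actual elongation is
  LER = E(t) * LER_p.

* **Cold damage** kills plants outright.  Mortality is logistic about the
  damage threshold T_c_d (one half at T_c_d), and surviving plant density
  is reduced multiplicatively per frost day: PD <- PD * (1 - M(T_min)).
  With the published parameters mortality is negligible above about -10 degC
  and near-total below about -20 degC.  Density updates are evaluated only
  on days whose minimum falls below T_c_i, so a frost-free season leaves
  the stand untouched exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ColdDamageParams, ColdInjuryParams

__all__ = [
    "update_cold_days",
    "apparent_injury",
    "injury_effect",
    "apply_injury",
    "mortality",
    "update_density",
    "ColdState",
]


def update_cold_days(d_cum: float, t_daily: float, p: ColdInjuryParams) -> float:
    """Advance the cold-day counter by one day's indicator, floored at 0."""
    if d_cum < 0:
        raise ValueError("cumulative cold days must be >= 0")
    step = 1.0 if t_daily < p.t_c_i else -1.0
    return max(d_cum + step, 0.0)


def apparent_injury(t: float, p: ColdInjuryParams) -> float:
    """Apparent cold injury C in [0, 1]; natural log, clamped."""
    arg = p.a * (t - p.t_c_i) + p.b
    if arg <= 0.0:
        # log undefined; ln(arg) -> -inf as arg -> 0+, so the clamp
        # boundary approached is zero injury (the warm side for a < 0)
        return 0.0
    return max(0.0, min(math.log(arg), 1.0))


def injury_effect(c: float, d_cum: float, e_prev: float) -> float:
    """Applied injury effect E(t): 1 outside episodes, ratcheting within."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("C must lie in [0, 1]")
    if d_cum < 0:
        raise ValueError("D must be >= 0")
    if d_cum == 0:
        return 1.0
    e = 1.0 - c ** (1.0 / d_cum)
    return min(e, e_prev)


def apply_injury(ler_p: float, e_t: float) -> float:
    """Scale potential leaf elongation rate by the injury effect."""
    if ler_p < 0 or not 0.0 <= e_t <= 1.0:
        raise ValueError("require LER_p >= 0 and E in [0, 1]")
    return e_t * ler_p


def mortality(t: float, p: ColdDamageParams) -> float:
    """Frost mortality fraction, logistic in T with midpoint at T_c_d."""
    z = -p.s * (t - p.t_c_d)
    # numerically stable logistic
    if z >= 0:
        ez = math.exp(-z)
        return 1.0 / (1.0 + ez)
    ez = math.exp(z)
    return ez / (1.0 + ez)


def update_density(pd_now: float, t_event: float, p: ColdDamageParams) -> float:
    """Apply one frost event's survival multiplicatively to plant density."""
    if pd_now <= 0:
        raise ValueError("plant density must be positive")
    return pd_now * (1.0 - mortality(t_event, p))


@dataclass
class ColdState:
    """Daily-updated cold injury accumulator plus surviving plant density."""

    injury: ColdInjuryParams
    damage: ColdDamageParams
    d_cum: float = 0.0
    e_prev: float = 1.0
    pd: float = 0.0

    def __post_init__(self) -> None:
        if self.pd == 0.0:
            self.pd = self.damage.pd_0

    def step_day(self, t_min: float) -> float:
        """Update from one day's minimum temperature; return E(t)."""
        self.d_cum = update_cold_days(self.d_cum, t_min, self.injury)
        c = apparent_injury(t_min, self.injury)
        e_t = injury_effect(c, self.d_cum, self.e_prev)
        self.e_prev = e_t
        # density update only on cold days; warm days leave PD bit-identical
        if t_min < self.injury.t_c_i:
            self.pd = update_density(self.pd, t_min, self.damage)
        return e_t
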