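"""Individual leaf growth, senescence, and aggregation to green area / LAI.

Each appeared leaf elongates at a temperature-driven potential rate
LER_p = LER_max * f(T) (scaled by the cold-injury effect upstream) toward a
rank-dependent potential final length, peaking at LM_min for the longest
rank.  Area follows a length * width * form-factor allometry.  After full
expansion a leaf stays fully green for a thermal-time span scaled by the
stay-green parameter SG, then its green fraction declines linearly to zero.
Green leaf area is the green-fraction-weighted sum over leaves; LAI is
green area per plant times plant density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import LeafParams
from .thermal import BetaResponse

__all__ = ["Leaf", "Canopy", "potential_final_length", "potential_ler",
           "grow_leaf", "leaf_area", "lai"]


def potential_final_length(rank: int, total_leaves: int, p: LeafParams) -> float:
    """Rank profile of potential final length (cm), peaking at LM_min.

    A half-sine rise from a basal fraction at rank 1 to the maximum at the
    configured peak rank, flat thereafter; the exact shape is a documented
    modeling choice (only the maximum is a cultivar parameter).
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    peak = max(p.peak_rank_fraction * total_leaves, 1.0)
    x = min(rank / peak, 1.0)
    frac = p.base_length_fraction + (1.0 - p.base_length_fraction) * math.sin(
        0.5 * math.pi * x
    )
    return p.lm_min * frac


def potential_ler(t_air: float, p: LeafParams, response: BetaResponse) -> float:
    """Potential leaf elongation rate, cm d^-1."""
    return p.ler_max * float(response(t_air))


def leaf_area(length: float, final_length: float, p: LeafParams) -> float:
    """Blade area (cm2) from length via a width allometry on final length."""
    width = p.width_ratio * final_length
    return length * width * p.form_factor


@dataclass
class Leaf:
    rank: int
    final_length: float
    length: float = 0.0
    green_fraction: float = 1.0
    maturity_gdd: float | None = None   # thermal time at full expansion

    @property
    def expanding(self) -> bool:
        return self.length < self.final_length

    def area(self, p: LeafParams) -> float:
        return leaf_area(self.length, self.final_length, p)

    def green_area(self, p: LeafParams) -> float:
        return self.area(p) * self.green_fraction


def grow_leaf(leaf: Leaf, ler: float, dt_days: float = 1.0) -> Leaf:
    """Elongate by ler * dt, truncated at the potential final length."""
    if ler < 0:
        raise ValueError("LER must be >= 0 (injury scaling happens upstream)")
    leaf.length = min(leaf.length + ler * dt_days, leaf.final_length)
    return leaf


@dataclass
class Canopy:
    """The plant's set of appeared leaves plus senescence bookkeeping."""

    params: LeafParams
    response: BetaResponse
    total_leaves: int
    leaves: list = field(default_factory=list)
    gdd: float = 0.0   # thermal time since emergence, for senescence clocks

    def add_leaf(self) -> Leaf:
        rank = len(self.leaves) + 1
        leaf = Leaf(rank=rank,
                    final_length=potential_final_length(
                        rank, self.total_leaves, self.params))
        self.leaves.append(leaf)
        return leaf

    def grow(self, t_mean: float, injury_effect: float, dt_days: float = 1.0) -> None:
        ler_p = potential_ler(t_mean, self.params, self.response)
        ler = injury_effect * ler_p
        for leaf in self.leaves:
            if leaf.expanding:
                grow_leaf(leaf, ler, dt_days)
                if not leaf.expanding and leaf.maturity_gdd is None:
                    leaf.maturity_gdd = self.gdd
            elif leaf.maturity_gdd is None:
                leaf.maturity_gdd = self.gdd

    def senesce(self, gdd_increment: float) -> None:
        """Advance senescence clocks by one step of thermal time.

        A leaf stays fully green for green_duration_gdd * SG after full
        expansion, then fades linearly over senescence_gdd * SG.
        """
        self.gdd += gdd_increment
        p = self.params
        for leaf in self.leaves:
            if leaf.maturity_gdd is None:
                continue
            onset = leaf.maturity_gdd + p.green_duration_gdd * p.sg
            if self.gdd <= onset:
                continue
            span = p.senescence_gdd * p.sg
            leaf.green_fraction = max(0.0, 1.0 - (self.gdd - onset) / span)

    def green_area(self) -> float:
        """Green leaf area per plant, cm2."""
        return sum(leaf.green_area(self.params) for leaf in self.leaves)

    def total_area(self) -> float:
        return sum(leaf.area(self.params) for leaf in self.leaves)


def lai(green_area_cm2: float, plant_density: float) -> float:
    """Leaf area index (m2 m^-2) from per-plant green area and density."""
    if green_area_cm2 < 0 or plant_density < 0:
        raise ValueError("inputs must be >= 0")
    return green_area_cm2 * 1e-4 * plant_density
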