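"""Developmental stages and the storage-conditioned dynamic phyllochron.

Leaf tips appear at a rate LTAR_max * f(T), with f the beta thermal
response.  LTAR_max starts from a sigmoid of seed-bulb storage duration,

    r0 = LTAR_max,a / (1 + exp(-alpha * (SD - SD_m))),

and after each appearance is re-interpolated linearly toward half the
asymptote, r1 = LTAR_max,a / 2, reaching it when the leaf rank k equals the
generic leaf number N_g (and staying there for k > N_g).  The scape appears
three phyllochron-equivalents after the onset of the reproductive stage,
accumulated at the current dynamic rate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .config import PhyllochronParams
from .thermal import BetaResponse


class DevStage(enum.IntEnum):
    """Developmental stage; transitions are strictly forward."""

    SEED = 0
    VEGETATIVE = 1
    R1 = 2       # scape initiation -> appearance
    R2 = 3       # scape appearance -> removal
    R3 = 4       # after scape removal (only if removal occurs)
    DEATH = 5


STAGE_NAMES = {
    DevStage.SEED: "seed",
    DevStage.VEGETATIVE: "vegetative",
    DevStage.R1: "R1",
    DevStage.R2: "R2",
    DevStage.R3: "R3",
    DevStage.DEATH: "death",
}


@dataclass(frozen=True)
class StorageConditions:
    """Seed-bulb storage: duration drives the phyllochron sigmoid.

    Storage temperature is carried for forward compatibility but does not
    enter the rate equation in this implementation.
    """

    sd: float          # storage duration, days
    st: float = 8.0    # storage temperature, degC (inert)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("storage duration must be >= 0")


def initial_ltar(storage: StorageConditions, p: PhyllochronParams) -> float:
    """Initial maximal leaf tip appearance rate r0 (d^-1), sigmoid in SD."""
    return p.ltar_max_a / (1.0 + math.exp(-p.alpha * (storage.sd - p.sd_m)))


def converge_ltar(r0: float, k: int, p: PhyllochronParams) -> float:
    """Dynamic LTAR_max at leaf rank k, converging linearly to r1 = a/2."""
    if k < 0:
        raise ValueError("leaf rank must be >= 0")
    r1 = p.ltar_max_a / 2.0
    frac = min(k, p.n_g) / p.n_g
    return r0 + (r1 - r0) * frac


@dataclass
class PhyllochronState:
    """Leaf appearance accumulator and its dynamic rate."""

    r0: float
    params: PhyllochronParams
    k: int = 0                    # appeared leaf rank
    accumulator: float = 0.0      # progress toward the next appearance
    initiated: float = 0.0        # leaves initiated (plastochron), set on init

    def __post_init__(self) -> None:
        self.ltar_max = converge_ltar(self.r0, self.k, self.params)
        if self.initiated == 0.0:
            self.initiated = float(self.params.iln)

    def step(self, t_air: float, dt_days: float, response: BetaResponse) -> int:
        """Advance by dt; return the number of leaves appearing this step."""
        if dt_days <= 0:
            raise ValueError("dt must be positive")
        f = float(response(t_air))
        # leaf initiation runs ahead of appearance at twice the tip rate,
        # capped at the total initiable leaf number
        self.initiated = min(
            self.initiated + 2.0 * self.ltar_max * f * dt_days,
            float(self.params.total_leaves),
        )
        self.accumulator += self.ltar_max * f * dt_days
        appeared = 0
        while self.accumulator >= 1.0 and self.k < int(self.initiated):
            self.accumulator -= 1.0
            self.k += 1
            appeared += 1
            self.ltar_max = converge_ltar(self.r0, self.k, self.params)
        # cannot bank progress past the next uninitiated leaf
        if self.k >= int(self.initiated):
            self.accumulator = min(self.accumulator, 1.0)
        return appeared


@dataclass
class StageTracker:
    """Forward-only stage machine with thermal-time triggers.

    Emergence (seed -> vegetative) and reproductive onset (vegetative -> R1)
    fire on growing-degree-day thresholds; scape appearance (R1 -> R2) fires
    after three phyllochron-equivalents accumulated at the current dynamic
    rate; R2 -> R3 fires on scape removal.
    """

    emergence_gdd: float
    repro_gdd: float
    stage: DevStage = DevStage.SEED
    gdd_since_planting: float = 0.0
    gdd_since_emergence: float = 0.0
    scape_acc: float = 0.0
    events: list = field(default_factory=list)

    def _advance(self, new: DevStage, date) -> None:
        if new < self.stage:
            raise ValueError(f"stage cannot move backward: {self.stage} -> {new}")
        self.stage = new
        self.events.append((date, STAGE_NAMES[new]))

    def add_gdd(self, gdd: float, date) -> None:
        self.gdd_since_planting += gdd
        if self.stage == DevStage.SEED and self.gdd_since_planting >= self.emergence_gdd:
            self._advance(DevStage.VEGETATIVE, date)
        if self.stage >= DevStage.VEGETATIVE:
            self.gdd_since_emergence += gdd
        if self.stage == DevStage.VEGETATIVE and self.gdd_since_emergence >= self.repro_gdd:
            self._advance(DevStage.R1, date)

    def add_scape_progress(self, ltar_max: float, f_t: float, dt_days: float, date) -> None:
        if self.stage != DevStage.R1:
            return
        self.scape_acc += ltar_max * f_t * dt_days
        if self.scape_acc >= 3.0:
            self._advance(DevStage.R2, date)

    def remove_scape(self, date) -> None:
        if self.stage != DevStage.R2:
            raise ValueError("scape removal only valid in stage R2")
        self._advance(DevStage.R3, date)

    def mark_death(self, date) -> None:
        if self.stage != DevStage.DEATH:
            self._advance(DevStage.DEATH, date)
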