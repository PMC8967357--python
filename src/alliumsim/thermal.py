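"""Temperature response functions shared across developmental processes.

Leaf appearance and leaf elongation are both driven by a dimensionless
beta-function thermal response, the standard form in this model lineage:
zero at or below the base temperature, unity at the optimum, zero again at
the ceiling, with the skew set by the optimum/ceiling pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BetaResponse:
    """Beta thermal response factor in [0, 1].

    f(T) = ((T_ceil - T) / (T_ceil - T_opt)) * (T / T_opt)^(T_opt / (T_ceil - T_opt))

    for 0 < T < T_ceil (base temperature fixed at 0 degC), else 0.
    """

    t_opt: float = 22.0
    t_ceil: float = 34.0

    def __post_init__(self) -> None:
        if not 0.0 < self.t_opt < self.t_ceil:
            raise ValueError("require 0 < t_opt < t_ceil")

    def __call__(self, t_air):
        t = np.asarray(t_air, dtype=float)
        span = self.t_ceil - self.t_opt
        with np.errstate(invalid="ignore", divide="ignore"):
            f = ((self.t_ceil - t) / span) * (t / self.t_opt) ** (self.t_opt / span)
        f = np.where((t <= 0.0) | (t >= self.t_ceil), 0.0, f)
        f = np.clip(f, 0.0, 1.0)
        return float(f) if np.isscalar(t_air) else f


def growing_degree_days(t_mean: float, t_base: float = 4.0) -> float:
    """Daily thermal-time increment (degC d) above a base temperature."""
    return max(t_mean - t_base, 0.0)
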