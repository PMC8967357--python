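"""Canopy carbon assimilation: coupled C3 gas exchange or an RUE fallback.

The coupled route follows the Farquhar-von Caemmerer-Berry C3 kinetics with
Bernacchi temperature responses, a Ball-Berry stomatal conductance model and
a linearized leaf energy balance, solved simultaneously per canopy layer by
damped fixed-point iteration on intercellular CO2 (Ci) and leaf temperature.
The canopy is split into two big leaves -- sunlit and shaded -- by beam
extinction through the leaf area index (LAI), and layer assimilation rates
are aggregated to ground area and converted to grams of carbohydrate
(mol CO2 -> 30 g CH2O).

The radiation-use-efficiency (RUE) route replaces all of this with
Beer-law light interception times a fixed conversion efficiency; it keeps
every downstream process independent of the gas-exchange parameterization.

All gas-exchange functions are vectorized over hourly arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GasExchangeParams

R_GAS = 8.314            # J mol^-1 K^-1
O2 = 210.0               # mmol mol^-1
CP_MOL = 29.3            # J mol^-1 K^-1, molar heat capacity of air
LAMBDA = 44100.0         # J mol^-1, latent heat of vaporization
P_ATM = 101.325          # kPa
CH2O_PER_MOL_CO2 = 30.0  # g

# Bernacchi et al. kinetic constants at 25 degC with activation energies
KC25, EA_KC = 404.9, 79430.0     # umol mol^-1
KO25, EA_KO = 278.4, 36380.0     # mmol mol^-1
GSTAR25, EA_GSTAR = 42.75, 37830.0  # umol mol^-1


@dataclass
class CanopyEnvironment:
    """Hourly driving variables for the canopy, as arrays or scalars."""

    solar: np.ndarray    # W m^-2 shortwave
    t_air: np.ndarray    # degC
    rh: np.ndarray       # %
    wind: np.ndarray     # m s^-1
    co2: np.ndarray      # umol mol^-1
    lai: float           # m2 m^-2

    def __post_init__(self) -> None:
        self.solar = np.atleast_1d(np.asarray(self.solar, dtype=float))
        n = self.solar.shape
        for name in ("t_air", "rh", "wind", "co2"):
            setattr(self, name, np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), n).copy())
        if self.lai < 0:
            raise ValueError("LAI must be >= 0")
        if np.any(self.solar < 0):
            raise ValueError("solar radiation must be >= 0")


def _arrhenius(k25, ea, tk):
    return k25 * np.exp(ea * (tk - 298.15) / (298.15 * R_GAS * tk))


def _peaked(k25, ea, hd, sv, tk):
    num = 1 + np.exp((298.15 * sv - hd) / (298.15 * R_GAS))
    den = 1 + np.exp((tk * sv - hd) / (tk * R_GAS))
    return _arrhenius(k25, ea, tk) * num / den


def _saturation_vp(t_c):
    """Saturation vapour pressure (kPa), Tetens."""
    return 0.6108 * np.exp(17.27 * t_c / (t_c + 237.3))


def electron_transport(ppfd, t_leaf_k, p: GasExchangeParams):
    jmax = _peaked(p.jmax25, p.ea_jmax, p.hd, p.sv, t_leaf_k)
    q = p.phi * ppfd
    disc = np.sqrt(np.maximum((q + jmax) ** 2 - 4 * p.theta * q * jmax, 0.0))
    return (q + jmax - disc) / (2 * p.theta)


def net_assimilation(ci, ppfd, t_leaf_c, p: GasExchangeParams):
    """Leaf net CO2 assimilation (umol m^-2 s^-1) at given Ci."""
    tk = np.asarray(t_leaf_c, dtype=float) + 273.15
    vcmax = _peaked(p.vcmax25, p.ea_vcmax, p.hd, p.sv, tk)
    rd = _arrhenius(p.rd25, p.ea_rd, tk)
    kc = _arrhenius(KC25, EA_KC, tk)
    ko = _arrhenius(KO25, EA_KO, tk)
    gstar = _arrhenius(GSTAR25, EA_GSTAR, tk)
    j = electron_transport(ppfd, tk, p)
    ci = np.maximum(ci, gstar)  # avoid negative carboxylation regime
    ac = vcmax * (ci - gstar) / (ci + kc * (1 + O2 / ko))
    aj = j * (ci - gstar) / (4 * ci + 8 * gstar)
    return np.minimum(ac, aj) - rd


def solve_coupled(
    ppfd, t_air, rh, wind, ca, p: GasExchangeParams,
    tol: float = 1e-3, max_iter: int = 100,
):
    """Solve the coupled Ci / stomatal conductance / energy-balance system.

    Damped fixed-point iteration: from Ci compute A; from A the Ball-Berry
    stomatal conductance and the diffusion chain Ca -> Cs -> Ci; from the
    latent and radiative fluxes a linearized leaf temperature update.
    Returns (A, gs, ci, t_leaf) arrays.
    """
    ppfd = np.asarray(ppfd, dtype=float)
    t_air = np.broadcast_to(np.asarray(t_air, dtype=float), ppfd.shape)
    rh = np.broadcast_to(np.asarray(rh, dtype=float), ppfd.shape)
    wind = np.broadcast_to(np.asarray(wind, dtype=float), ppfd.shape)
    ca = np.broadcast_to(np.asarray(ca, dtype=float), ppfd.shape)

    hs = np.clip(rh / 100.0, 0.05, 1.0)
    gb = p.gb * np.sqrt(np.maximum(wind, 0.5) / 2.0)  # mol m^-2 s^-1

    ci = 0.7 * ca
    t_leaf = t_air.copy()
    gs = np.full_like(ci, p.g0)
    for _ in range(max_iter):
        a = net_assimilation(ci, ppfd, t_leaf, p)
        cs = np.maximum(ca - a * 1.37 / gb, 1.0)
        gs = p.g0 + p.g1 * np.maximum(a, 0.0) * hs / cs
        ci_new = np.clip(cs - a * 1.6 / gs, 1.0, 2.0 * ca)

        # linearized energy balance: absorbed shortwave less latent heat,
        # dumped through the boundary layer as sensible heat
        sw_abs = p.leaf_absorptance * ppfd / p.ppfd_per_watt  # W m^-2
        vpd = np.maximum(_saturation_vp(t_leaf) - hs * _saturation_vp(t_air), 0.0)
        gv = 1.0 / (1.0 / np.maximum(gs, 1e-6) + 1.0 / gb)
        le = LAMBDA * gv * vpd / P_ATM
        dt_leaf = np.clip((sw_abs - le) / (2.0 * CP_MOL * gb + 8.0), -10.0, 10.0)
        t_leaf_new = t_air + dt_leaf

        if (np.max(np.abs(ci_new - ci)) < tol
                and np.max(np.abs(t_leaf_new - t_leaf)) < 0.01):
            ci, t_leaf = ci_new, t_leaf_new
            break
        # light damping on Ci stabilizes the stomatal feedback; the leaf
        # temperature map is a contraction and can step fully
        ci = 0.3 * ci + 0.7 * ci_new
        t_leaf = t_leaf_new
    a = net_assimilation(ci, ppfd, t_leaf, p)
    return a, gs, ci, t_leaf


def two_leaf_irradiance(ppfd0, lai: float, p: GasExchangeParams):
    """Partition incident PPFD into (sunlit LAI, shaded LAI, I_sun, I_shade).

    Simplified two-big-leaf scheme: a fixed beam/diffuse split, sunlit leaf
    area from beam extinction, per-leaf shaded irradiance as the attenuated
    diffuse flux at mid-canopy depth, sunlit leaves adding the beam load.
    """
    ppfd0 = np.asarray(ppfd0, dtype=float)
    if lai <= 0:
        zeros = np.zeros_like(ppfd0)
        return 0.0, 0.0, zeros, zeros
    lai_sun = (1.0 - np.exp(-p.k_beam * lai)) / p.k_beam
    lai_sh = max(lai - lai_sun, 0.0)
    i_beam = p.beam_fraction * ppfd0
    i_diff = (1.0 - p.beam_fraction) * ppfd0
    i_shade = p.k_diff * i_diff * np.exp(-p.k_diff * lai / 2.0)
    i_sun = p.k_beam * i_beam + i_shade
    return lai_sun, lai_sh, i_sun, i_shade


def canopy_assimilation(
    env: CanopyEnvironment, p: GasExchangeParams, plant_density: float,
    dt_hours: float = 1.0,
) -> float:
    """Net canopy assimilation over the series, g CH2O per plant.

    Sunlit and shaded big leaves are solved independently each hour and
    their net rates aggregated to ground area; negative net hours (dark
    respiration) are carried through -- flooring happens at the carbon pool.
    """
    if dt_hours <= 0:
        raise ValueError("dt must be positive")
    if plant_density <= 0:
        raise ValueError("plant density must be positive")
    if env.lai <= 0:
        return 0.0
    ppfd0 = env.solar * p.ppfd_per_watt
    lai_sun, lai_sh, i_sun, i_sh = two_leaf_irradiance(ppfd0, env.lai, p)
    a_sun, *_ = solve_coupled(i_sun, env.t_air, env.rh, env.wind, env.co2, p)
    a_sh, *_ = solve_coupled(i_sh, env.t_air, env.rh, env.wind, env.co2, p)
    a_ground = a_sun * lai_sun + a_sh * lai_sh          # umol CO2 m^-2 s^-1
    mol = np.sum(a_ground) * dt_hours * 3600.0 * 1e-6   # mol CO2 m^-2
    return float(mol * CH2O_PER_MOL_CO2 / plant_density)


def intercepted_radiation(solar_mj: float, lai: float, k: float = 0.5) -> float:
    """Beer-law intercepted shortwave, MJ m^-2."""
    if solar_mj < 0 or lai < 0:
        raise ValueError("inputs must be >= 0")
    return solar_mj * (1.0 - np.exp(-k * lai))


def rue_assimilation(
    env: CanopyEnvironment, rue: float, plant_density: float = 1.0,
    dt_hours: float = 1.0, k: float = 0.5,
) -> float:
    """RUE fallback: intercepted radiation times efficiency, g CH2O per plant."""
    if rue <= 0:
        raise ValueError("rue must be positive")
    solar_mj = float(np.sum(env.solar)) * dt_hours * 3600.0 * 1e-6
    return intercepted_radiation(solar_mj, env.lai, k) * rue / plant_density
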