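"""Seawater CO2-system solver: aragonite saturation state from TA and DIC.

Given total alkalinity and dissolved inorganic carbon at in-situ surface
temperature and salinity, the solver finds the total-scale hydrogen-ion
concentration at which the modeled alkalinity

    TA = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]_T

balances the input, then evaluates the carbonate-ion concentration and the
saturation states Ω = [Ca²⁺][CO3²⁻]/K'sp for aragonite and calcite.

Equilibrium constants follow the conventional open-ocean surface choices:
K1/K2 from Lueker et al. (2000, total scale), KB from Dickson (1990), KW
from Millero (1995, converted from the seawater to the total scale), the
stoichiometric solubility products from Mucci (1983), total boron from
salinity after Uppström (1974) and calcium proportional to salinity after
Riley & Tongudai (1967).  Nutrient (phosphate/silicate) and HF alkalinity
terms are neglected — an approximation good to well under 1% of TA at
surface-ocean nutrient levels; the −[H+] term is on the total scale, which
absorbs the bisulfate term exactly.  Pressure is fixed at 0 dbar; pH is on
the total scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .grids import Raster

_PH_BRACKET = (2.0, 12.0)


@dataclass(frozen=True)
class CarbonateInput:
    """Surface seawater state: TA/DIC in μmol kg⁻¹, T in °C, S in psu."""

    TA: float
    DIC: float
    T: float
    S: float
    pressure: float = 0.0

    def __post_init__(self) -> None:
        if not (self.TA > 0 and self.DIC > 0):
            raise ValueError(f"TA and DIC must be positive, got TA={self.TA}, DIC={self.DIC}")
        if not (0.0 < self.S < 50.0):
            raise ValueError(f"salinity {self.S} outside (0, 50)")
        if not (-2.0 < self.T < 40.0):
            raise ValueError(f"temperature {self.T} outside (-2, 40)")
        if self.pressure != 0.0:
            raise ValueError("only surface pressure (0 dbar) is supported")


@dataclass(frozen=True)
class CarbonateState:
    """Solved CO2 system: total-scale pH, [CO3²⁻] in μmol kg⁻¹, Ω values."""

    pH_total: float
    CO3: float
    omega_ara: float
    omega_cal: float


@dataclass(frozen=True)
class EquilibriumConstants:
    """Stoichiometric constants (mol/kg-sw; K products on the total pH scale)."""

    K1: float
    K2: float
    KB: float
    KW: float
    Ksp_ara: float
    Ksp_cal: float
    BT: float  # total boron, mol/kg
    Ca: float  # calcium, mol/kg


def equilibrium_constants(T: float, S: float) -> EquilibriumConstants:
    TK = T + 273.15
    lnTK = math.log(TK)
    sqS = math.sqrt(S)

    # Lueker et al. (2000): pK1, pK2 on the total scale
    pK1 = 3633.86 / TK - 61.2172 + 9.6777 * lnTK - 0.011555 * S + 0.0001152 * S * S
    pK2 = 471.78 / TK + 25.929 - 3.16967 * lnTK - 0.01781 * S + 0.0001122 * S * S
    K1 = 10.0**-pK1
    K2 = 10.0**-pK2

    # Dickson (1990): boric acid, total scale
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S * sqS - 0.0996 * S * S) / TK
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        - (24.4344 + 25.085 * sqS + 0.2474 * S) * lnTK
        + 0.053105 * sqS * TK
    )
    KB = math.exp(lnKB)

    # ionic strength and the minor-ion totals used for pH-scale conversion
    ion_str = 19.924 * S / (1000.0 - 1.005 * S)
    sqI = math.sqrt(ion_str)
    TS = (0.14 / 96.062) * (S / 1.80655)  # total sulfate (Morris & Riley)
    TF = (0.000067 / 18.998) * (S / 1.80655)  # total fluoride (Riley)

    # Dickson (1990): bisulfate, free scale
    lnKS = (
        -4276.1 / TK
        + 141.328
        - 23.093 * lnTK
        + (-13856.0 / TK + 324.57 - 47.986 * lnTK) * sqI
        + (35474.0 / TK - 771.54 + 114.723 * lnTK) * ion_str
        - 2698.0 / TK * ion_str * sqI
        + 1776.0 / TK * ion_str * ion_str
        + math.log(1.0 - 0.001005 * S)
    )
    KS = math.exp(lnKS)

    # Dickson & Riley (1979): hydrogen fluoride, free scale
    lnKF = 1590.2 / TK - 12.641 + 1.525 * sqI + math.log(1.0 - 0.001005 * S)
    KF = math.exp(lnKF)

    # Millero (1995): water, seawater scale; convert to total scale
    lnKW_sws = (
        148.9802
        - 13847.26 / TK
        - 23.6521 * lnTK
        + (-5.977 + 118.67 / TK + 1.0495 * lnTK) * sqS
        - 0.01615 * S
    )
    sws_to_tot = (1.0 + TS / KS) / (1.0 + TS / KS + TF / KF)
    KW = math.exp(lnKW_sws) * sws_to_tot

    # Mucci (1983): stoichiometric solubility products, mol²/kg²
    log10TK = math.log10(TK)
    logK_cal = (
        -171.9065
        - 0.077993 * TK
        + 2839.319 / TK
        + 71.595 * log10TK
        + (-0.77712 + 0.0028426 * TK + 178.34 / TK) * sqS
        - 0.07711 * S
        + 0.0041249 * S * sqS
    )
    logK_ara = (
        -171.945
        - 0.077993 * TK
        + 2903.293 / TK
        + 71.595 * log10TK
        + (-0.068393 + 0.0017276 * TK + 88.135 / TK) * sqS
        - 0.10018 * S
        + 0.0059415 * S * sqS
    )
    Ksp_cal = 10.0**logK_cal
    Ksp_ara = 10.0**logK_ara

    BT = 0.000232 / 10.811 * (S / 1.80655)  # Uppström (1974)
    Ca = 0.02128 / 40.087 * (S / 1.80655)  # Riley & Tongudai (1967)

    return EquilibriumConstants(K1, K2, KB, KW, Ksp_ara, Ksp_cal, BT, Ca)


def modeled_alkalinity(pH_total: float, DIC: float, T: float, S: float) -> float:
    """Total alkalinity (μmol kg⁻¹) implied by a total-scale pH and DIC.

    Carbonate + borate + water terms minus total-scale [H+]; the inverse of
    the solver's balance condition, exposed for closure checks.
    """
    k = equilibrium_constants(T, S)
    H = 10.0**-pH_total
    dic = DIC * 1e-6
    den = H * H + k.K1 * H + k.K1 * k.K2
    carb_alk = dic * (k.K1 * H + 2.0 * k.K1 * k.K2) / den
    borate = k.BT * k.KB / (k.KB + H)
    return (carb_alk + borate + k.KW / H - H) * 1e6


def solve_carbonate_system(inp: CarbonateInput) -> CarbonateState:
    """Solve TA/DIC for the full carbonate state at the surface.

    Brent's method brackets the total-scale pH on [2, 12]; the returned
    state reproduces the input TA to better than 1e-10 relative.
    """
    k = equilibrium_constants(inp.T, inp.S)
    ta = inp.TA * 1e-6
    dic = inp.DIC * 1e-6

    def residual(pH: float) -> float:
        H = 10.0**-pH
        den = H * H + k.K1 * H + k.K1 * k.K2
        carb_alk = dic * (k.K1 * H + 2.0 * k.K1 * k.K2) / den
        return carb_alk + k.BT * k.KB / (k.KB + H) + k.KW / H - H - ta

    lo, hi = _PH_BRACKET
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"no pH root in [{lo}, {hi}] for TA={inp.TA}, DIC={inp.DIC}, "
            f"T={inp.T}, S={inp.S}"
        )
    pH = brentq(residual, lo, hi, xtol=1e-13, rtol=4 * np.finfo(float).eps)

    H = 10.0**-pH
    den = H * H + k.K1 * H + k.K1 * k.K2
    CO3 = dic * k.K1 * k.K2 / den
    omega_ara = k.Ca * CO3 / k.Ksp_ara
    omega_cal = k.Ca * CO3 / k.Ksp_cal
    return CarbonateState(pH, CO3 * 1e6, omega_ara, omega_cal)


def omega_field(TA: Raster, DIC: Raster, T: Raster, S: Raster) -> Raster:
    """Cellwise Ω_ara on a shared grid; any missing input makes a missing cell."""
    spec = TA.spec
    for r in (DIC, T, S):
        if r.spec != spec:
            raise ValueError("TA, DIC, T, S rasters must share one grid")
    out = np.full(spec.shape, np.nan)
    ok = TA.valid & DIC.valid & T.valid & S.valid
    for i, j in zip(*np.nonzero(ok)):
        state = solve_carbonate_system(
            CarbonateInput(
                TA=float(TA.values[i, j]),
                DIC=float(DIC.values[i, j]),
                T=float(T.values[i, j]),
                S=float(S.values[i, j]),
            )
        )
        out[i, j] = state.omega_ara
    return Raster(spec, out)


def alkalinity_for_omega(
    omega_target: float, DIC: float, T: float, S: float, bracket: tuple[float, float] = (1500.0, 3500.0)
) -> float:
    """TA (μmol kg⁻¹) at which Ω_ara equals ``omega_target`` for fixed DIC, T, S.

    Ω_ara is strictly increasing in TA at fixed DIC, so the root is unique
    within any bracket that straddles the target.
    """

    def f(ta: float) -> float:
        return solve_carbonate_system(CarbonateInput(ta, DIC, T, S)).omega_ara - omega_target

    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"omega target {omega_target} not bracketed by TA in {bracket} "
            f"at DIC={DIC}, T={T}, S={S}"
        )
    return brentq(f, lo, hi, xtol=1e-8)
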