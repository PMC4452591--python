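"""Independent oracles used by the test suite.

Each oracle re-derives a quantity through a deliberately different route
from the library implementation: the habitat oracle loops over every 30"
cell applying the decision flow literally with scalar comparisons; the
confusion oracle tallies cell by cell; the carbonate oracle solves the
alkalinity balance by a two-stage dense pH-grid scan (no root finder)
with the speciation written out term by term.  None of them import the
code paths they check beyond the data containers.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# carbonate chemistry: dense-grid scan solver


def _constants(T_C: float, S: float) -> dict[str, float]:
    """Equilibrium constants, transcribed from the primary sources.

    K1/K2: Lueker, Dickson & Keeling (2000), total scale.
    KB: Dickson (1990).  KW: Millero (1995), seawater scale, converted.
    Ksp: Mucci (1983).  Totals: Uppström (1974) boron, Morris & Riley
    sulfate, Riley fluoride, Riley & Tongudai calcium.
    """
    T = T_C + 273.15
    pK1 = 3633.86 / T - 61.2172 + 9.6777 * math.log(T) - 0.011555 * S + 0.0001152 * S**2
    pK2 = 471.78 / T + 25.929 - 3.16967 * math.log(T) - 0.01781 * S + 0.0001122 * S**2
    KB = math.exp(
        (-8966.90 - 2890.53 * S**0.5 - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2) / T
        + 148.0248
        + 137.1942 * S**0.5
        + 1.62142 * S
        + (-24.4344 - 25.085 * S**0.5 - 0.2474 * S) * math.log(T)
        + 0.053105 * S**0.5 * T
    )
    ion = 19.924 * S / (1000.0 - 1.005 * S)
    TS = 0.14 / 96.062 * S / 1.80655
    TF = 0.000067 / 18.998 * S / 1.80655
    KS = math.exp(
        -4276.1 / T
        + 141.328
        - 23.093 * math.log(T)
        + (-13856.0 / T + 324.57 - 47.986 * math.log(T)) * ion**0.5
        + (35474.0 / T - 771.54 + 114.723 * math.log(T)) * ion
        - 2698.0 / T * ion**1.5
        + 1776.0 / T * ion**2
        + math.log(1.0 - 0.001005 * S)
    )
    KF = math.exp(1590.2 / T - 12.641 + 1.525 * ion**0.5 + math.log(1.0 - 0.001005 * S))
    KW_sws = math.exp(
        148.9802
        - 13847.26 / T
        - 23.6521 * math.log(T)
        + (-5.977 + 118.67 / T + 1.0495 * math.log(T)) * S**0.5
        - 0.01615 * S
    )
    KW = KW_sws * (1.0 + TS / KS) / (1.0 + TS / KS + TF / KF)
    logKspC = (
        -171.9065
        - 0.077993 * T
        + 2839.319 / T
        + 71.595 * math.log10(T)
        + (-0.77712 + 0.0028426 * T + 178.34 / T) * S**0.5
        - 0.07711 * S
        + 0.0041249 * S**1.5
    )
    logKspA = (
        -171.945
        - 0.077993 * T
        + 2903.293 / T
        + 71.595 * math.log10(T)
        + (-0.068393 + 0.0017276 * T + 88.135 / T) * S**0.5
        - 0.10018 * S
        + 0.0059415 * S**1.5
    )
    return {
        "K1": 10.0**-pK1,
        "K2": 10.0**-pK2,
        "KB": KB,
        "KW": KW,
        "KspA": 10.0**logKspA,
        "KspC": 10.0**logKspC,
        "BT": 0.000232 / 10.811 * S / 1.80655,
        "Ca": 0.02128 / 40.087 * S / 1.80655,
    }


def oracle_carbonate(TA_umol: float, DIC_umol: float, T: float, S: float) -> dict[str, float]:
    """Solve TA+DIC by scanning pH grids; returns pH, CO3 (μmol/kg), omegas."""
    c = _constants(T, S)
    TA = TA_umol * 1e-6
    DIC = DIC_umol * 1e-6

    def residual(pH: np.ndarray) -> np.ndarray:
        H = 10.0 ** (-pH)
        alpha = 1.0 / (1.0 + c["K1"] / H + c["K1"] * c["K2"] / H**2)  # CO2* fraction
        co2 = DIC * alpha
        hco3 = co2 * c["K1"] / H
        co3 = hco3 * c["K2"] / H
        boh4 = c["BT"] / (1.0 + H / c["KB"])
        oh = c["KW"] / H
        return hco3 + 2.0 * co3 + boh4 + oh - H - TA

    lo, hi = 2.0, 12.0
    for _ in range(3):  # three grid refinements: final spacing ~1e-8 pH
        grid = np.linspace(lo, hi, 20001)
        k = int(np.argmin(np.abs(residual(grid))))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
    pH = 0.5 * (lo + hi)
    H = 10.0**-pH
    co3 = DIC / (1.0 + H / c["K2"] + H**2 / (c["K1"] * c["K2"]))
    return {
        "pH": pH,
        "CO3": co3 * 1e6,
        "omega_ara": c["Ca"] * co3 / c["KspA"],
        "omega_cal": c["Ca"] * co3 / c["KspC"],
    }


# ---------------------------------------------------------------------------
# habitat: literal cell-by-cell decision flow


def brute_force_habitat(env, limits, omega_mask=None) -> np.ndarray:
    """Boolean 30" suitability by looping over every fine cell."""
    fine = env.fine_spec
    coarse = env.coarse_spec
    mid = env.mid_spec
    fc = round(coarse.resolution / fine.resolution)
    fm = round(mid.resolution / fine.resolution)
    masked = omega_mask.to_array(coarse) if omega_mask is not None else np.zeros(coarse.shape, bool)
    out = np.zeros(fine.shape, dtype=bool)
    for i in range(fine.n_lat):
        ci, mi = i // fc, i // fm
        for j in range(fine.n_lon):
            cj, mj = j // fc, j // fm
            t = env.T.values[ci, cj]
            s = env.S.values[ci, cj]
            no3 = env.NO3.values[ci, cj]
            po4 = env.PO4.values[ci, cj]
            if math.isnan(t) or not (limits.t_min <= t <= limits.t_max):
                continue
            if math.isnan(s) or not (limits.s_min <= s <= limits.s_max):
                continue
            if math.isnan(no3) or no3 > limits.no3_max:
                continue
            if math.isnan(po4) or po4 > limits.po4_max:
                continue
            if env.omega is not None and not masked[ci, cj]:
                om = env.omega.values[ci, cj]
                if not math.isnan(om) and om < limits.omega_min:
                    continue
            par = env.PAR.values[mi, mj]
            k490 = env.K490.values[mi, mj]
            if math.isnan(par) or math.isnan(k490) or par <= limits.i_min:
                continue
            zmax = math.log(par / limits.i_min) / k490
            z = env.Z.values[i, j]
            if math.isnan(z) or not (0.0 < z <= zmax):
                continue
            out[i, j] = True
    return out


def brute_force_confusion(observed: np.ndarray, predicted: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) tallied cell by cell."""
    tp = fp = fn = tn = 0
    for o, p in zip(np.asarray(observed).ravel(), np.asarray(predicted).ravel()):
        if o == 1 and p == 1:
            tp += 1
        elif o == 0 and p == 1:
            fp += 1
        elif o == 1 and p == 0:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn
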