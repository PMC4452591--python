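"""Synthetic study worlds with planted, exactly recoverable ground truth.

The generator emulates the input stack the habitat analysis consumes —
1° climatologies (T, S, nitrate, phosphate, TA, DIC), 5′ ocean-color
fields (PAR, K490), 30″ bathymetry, monthly/weekly series, and charted
reef polygons — on a small equal-angle domain, with two guarantees that
real data cannot give:

* every planted tolerance bound is attained *exactly* at one designated
  reef cell (explicit insertion, not distribution-tail luck), so
  inverse-mode derivation recovers the planted envelope bit-for-bit;
* shelf depths are calibrated against the light equation so that the set
  of predicted-present cells changes at known I_min values: "deep-edge"
  reef cells drop out one refinement step above the planted I_min and
  "marginal" non-reef cells drop out below it, making the planted I_min
  the unique ROC-distance argmin of the sweep.

Coarse cells are assigned roles — land, abyssal ocean, and shelf cells
subdivided into bound-carrying, deep-edge, marginal and ordinary reef
candidates.  ``omission_rate`` leaves suitable cells reef-free (baseline
false positives); ``commission_rate`` drops reef polygons into deep water
(irreducible false negatives, emulating bathymetry/charting mismatches in
real reef data).  All randomness derives from one integer seed; the same
seed reproduces the world bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from . import carbonate
from .grids import GridSpec, Raster, RES_1DEG, RES_5MIN, RES_30SEC, expand, nesting
from .habitat import DEFAULT_LIMITS, EnvStack, ToleranceLimits, max_reef_depth, predict_habitat

_SHELF_FINE = 50  # shelf width in 30" cells (an integer number of 5' cells)
_SUITABLE_THROUGH = 600.0  # ordinary shelves stay suitable up to this I_min


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions for a synthetic world.

    The default extent (10° × 20°, 200 coarse cells, 2.88 M 30″ cells) is
    sized for sub-minute full-pipeline runs.  ``planted_limits`` carries
    the envelope *and* the planted optimal I_min.
    """

    lat_min: float = -5.0
    lat_max: float = 5.0
    lon_min: float = 0.0
    lon_max: float = 20.0
    seed: int = 0
    planted_limits: ToleranceLimits = DEFAULT_LIMITS
    omission_rate: float = 0.10
    commission_rate: float = 0.05
    land_fraction: float = 0.12
    abyss_fraction: float = 0.30
    n_marginal: int = 12
    n_edge: int = 4
    min_vertices_per_cell: int = 4
    max_vertices_per_cell: int = 12
    # field centers and noise amplitudes (smooth harmonic mixing)
    t_base: float = 25.65
    t_amp: float = 4.6
    s_base: float = 34.55
    s_amp: float = 6.5
    no3_base: float = 2.5
    no3_amp: float = 2.5
    po4_base: float = 0.35
    po4_amp: float = 0.35
    ta_base: float = 2300.0
    ta_amp: float = 90.0
    dic_base: float = 2000.0
    dic_amp: float = 110.0
    par_base: float = 1700.0
    par_amp: float = 250.0
    k490_base: float = 0.05
    k490_amp: float = 0.02
    k490_coastal: float = 0.03

    def __post_init__(self) -> None:
        for name in ("omission_rate", "commission_rate", "land_fraction", "abyss_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic world."""

    limits: ToleranceLimits
    i_min: float
    fine_mask: Raster  # suitable 30" cells at the planted limits and I_min
    reef_cells: np.ndarray  # 1deg bool: cells given reef polygons (excl. commissions)
    commission_cells: np.ndarray  # 1deg bool: deep cells given spurious polygons
    omitted_cells: np.ndarray  # 1deg bool: suitable cells left reef-free


@dataclass
class SyntheticWorld:
    env: EnvStack
    ta: Raster
    dic: Raster
    monthly: dict[str, list[Raster]]
    weekly_t: list[Raster]
    reefs: pd.DataFrame
    truth: PlantedTruth
    config: WorldConfig


def _smooth_field(rng: np.random.Generator, spec: GridSpec, n_modes: int = 5) -> np.ndarray:
    """Seeded low-order harmonic mixture normalized to [-1, 1]."""
    latn = (spec.lat_centers - spec.lat_min) / (spec.lat_max - spec.lat_min)
    lonn = (spec.lon_centers - spec.lon_min) / (spec.lon_max - spec.lon_min)
    LA, LO = np.meshgrid(latn, lonn, indexing="ij")
    f = np.zeros(spec.shape)
    for _ in range(n_modes):
        p = rng.integers(1, 4)
        q = rng.integers(1, 4)
        amp = rng.uniform(0.4, 1.0)
        ph = rng.uniform(0.0, 2.0 * math.pi)
        f += amp * np.cos(2.0 * math.pi * (p * LA + q * LO) + ph)
    return f / np.max(np.abs(f))


def _allocate_roles(rng: np.random.Generator, n_cells: int, cfg: WorldConfig):
    order = rng.permutation(n_cells)
    n_land = round(cfg.land_fraction * n_cells)
    n_abyss = max(1, round(cfg.abyss_fraction * n_cells))
    land = order[:n_land]
    abyss = order[n_land : n_land + n_abyss]
    shelf = order[n_land + n_abyss :]
    if len(shelf) < 3:
        raise ValueError(
            f"extent too small: only {len(shelf)} shelf cells after land/abyss allocation"
        )
    n_bound = min(7, max(2, len(shelf) - 2))
    bound = shelf[:n_bound]
    rest = shelf[n_bound:]
    n_edge = min(cfg.n_edge, max(1, len(rest) // 3)) if len(rest) else 0
    edge = rest[:n_edge]
    rest = rest[n_edge:]
    n_marg = min(cfg.n_marginal, len(rest) // 2)
    marginal = rest[:n_marg]
    normal = rest[n_marg:]
    return land, abyss, bound, edge, marginal, normal


def _marginal_targets(i_min: float, n: int) -> list[float]:
    """Drop-out I_min values for marginal false-positive cells.

    The four cells nearest the planted value drop out at successive
    refinement steps below it; the rest spread across the coarse sweep so
    false positives decline steadily, as in the real optimization.
    """
    fine = [i_min - 40.0, i_min - 30.0, i_min - 20.0, i_min - 10.0]
    coarse = [v for v in np.arange(100.0, i_min - 49.0, 50.0)]
    pool = fine + coarse[::-1]
    out = []
    k = 0
    while len(out) < n:
        out.append(pool[k % len(pool)])
        k += 1
    return out[:n]


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build a :class:`SyntheticWorld`; deterministic under ``config.seed``."""
    cfg = config
    lim = cfg.planted_limits
    rng = np.random.default_rng(cfg.seed)

    coarse = GridSpec(cfg.lat_min, cfg.lat_max, cfg.lon_min, cfg.lon_max, RES_1DEG)
    mid = GridSpec(cfg.lat_min, cfg.lat_max, cfg.lon_min, cfg.lon_max, RES_5MIN)
    fine = GridSpec(cfg.lat_min, cfg.lat_max, cfg.lon_min, cfg.lon_max, RES_30SEC)
    n_cells = coarse.n_lat * coarse.n_lon

    # --- 1 deg environmental fields: latitudinal structure + smooth noise
    lat_struct = np.cos(math.pi * coarse.lat_centers / 90.0)[:, None] * np.ones(coarse.shape)
    t = cfg.t_base + cfg.t_amp * (0.75 * _smooth_field(rng, coarse) + 0.25 * (lat_struct - lat_struct.mean()))
    s = cfg.s_base + cfg.s_amp * _smooth_field(rng, coarse)
    no3 = np.clip(cfg.no3_base + cfg.no3_amp * _smooth_field(rng, coarse), 0.01, None)
    po4 = np.clip(cfg.po4_base + cfg.po4_amp * _smooth_field(rng, coarse), 0.005, None)
    ta = cfg.ta_base + cfg.ta_amp * _smooth_field(rng, coarse)
    dic = cfg.dic_base + cfg.dic_amp * _smooth_field(rng, coarse)

    # --- roles
    land, abyss, bound, edge, marginal, normal = _allocate_roles(rng, n_cells, cfg)
    unravel = lambda flat: np.unravel_index(flat, coarse.shape)  # noqa: E731

    # commissions: spurious reef polygons over deep, env-suitable water
    n_reef_planned = len(bound) + len(edge) + len(normal)
    n_comm = min(round(cfg.commission_rate * n_reef_planned), len(abyss))
    commission = abyss[:n_comm]
    # a gridded-carbon coverage gap (missing TA/DIC) over abyssal cells
    gap = abyss[n_comm : n_comm + min(6, max(0, len(abyss) - n_comm))]
    fail_pool = abyss[n_comm + len(gap) :]

    # --- clip every must-pass cell strictly inside the planted envelope
    must_pass = np.concatenate([bound, edge, marginal, normal, commission])
    mp = unravel(must_pass)
    t_pad = 0.02 * (lim.t_max - lim.t_min)
    s_pad = 0.02 * (lim.s_max - lim.s_min)
    t[mp] = np.clip(t[mp], lim.t_min + t_pad, lim.t_max - t_pad)
    s[mp] = np.clip(s[mp], lim.s_min + s_pad, lim.s_max - s_pad)
    no3[mp] = np.clip(no3[mp], 0.01, 0.98 * lim.no3_max)
    po4[mp] = np.clip(po4[mp], 0.005, 0.98 * lim.po4_max)

    # --- plant exact envelope bounds on designated reef cells (round-robin)
    bound_assign = {}
    for k, name in enumerate(("t_min", "t_max", "s_min", "s_max", "no3_max", "po4_max", "omega")):
        bound_assign[name] = bound[k % len(bound)]
    t[unravel(bound_assign["t_min"])] = lim.t_min
    t[unravel(bound_assign["t_max"])] = lim.t_max
    s[unravel(bound_assign["s_min"])] = lim.s_min
    s[unravel(bound_assign["s_max"])] = lim.s_max
    no3[unravel(bound_assign["no3_max"])] = lim.no3_max
    po4[unravel(bound_assign["po4_max"])] = lim.po4_max

    # --- plant out-of-range showcase values on spare deep cells so every
    # bound binds somewhere in the domain
    fail_values = [
        (t, lim.t_min - 2.5),
        (t, lim.t_max + 2.5),
        (s, lim.s_min - 2.5),
        (s, min(lim.s_max + 1.5, 49.0)),
        (no3, 1.5 * lim.no3_max),
        (po4, 1.5 * lim.po4_max),
    ]
    for k, (arr, value) in enumerate(fail_values):
        if k < len(fail_pool):
            arr[unravel(fail_pool[k])] = value

    # --- aragonite saturation: solve the carbonate system cellwise, after
    # adjusting TA where a target omega must hold exactly
    omega_targets: dict[int, float] = {}
    omega_targets[int(bound_assign["omega"])] = lim.omega_min
    if len(fail_pool) > 6:
        omega_targets[int(fail_pool[6])] = max(lim.omega_min - 0.4, 0.3)

    ta_missing = np.zeros(coarse.shape, dtype=bool)
    ta_missing[unravel(gap)] = True

    omega = np.full(coarse.shape, np.nan)
    for flat in range(n_cells):
        ij = np.unravel_index(flat, coarse.shape)
        if ta_missing[ij]:
            continue
        if flat in omega_targets:
            target = omega_targets[flat]
            ta[ij] = carbonate.alkalinity_for_omega(target, float(dic[ij]), float(t[ij]), float(s[ij]))
            omega[ij] = target
            continue
        state = carbonate.solve_carbonate_system(
            carbonate.CarbonateInput(float(ta[ij]), float(dic[ij]), float(t[ij]), float(s[ij]))
        )
        omega[ij] = state.omega_ara
    # must-pass cells whose omega falls below the envelope get their TA
    # raised to a comfortable saturation state
    for flat in must_pass:
        ij = np.unravel_index(int(flat), coarse.shape)
        if ta_missing[ij] or int(flat) in omega_targets:
            continue
        if omega[ij] < lim.omega_min + 0.1:
            target = lim.omega_min + rng.uniform(0.2, 0.8)
            ta[ij] = carbonate.alkalinity_for_omega(target, float(dic[ij]), float(t[ij]), float(s[ij]))
            omega[ij] = target

    ta_r = Raster(coarse, np.where(ta_missing, np.nan, ta))
    dic_r = Raster(coarse, np.where(ta_missing, np.nan, dic))
    omega_r = Raster(coarse, omega)

    # --- 5' ocean color
    par = cfg.par_base + cfg.par_amp * _smooth_field(rng, mid)
    k490 = cfg.k490_base + cfg.k490_amp * _smooth_field(rng, mid)
    land_flat = np.zeros(n_cells, dtype=bool)
    land_flat[land] = True
    land_coarse = land_flat.reshape(coarse.shape)
    land5 = expand(land_coarse, nesting(coarse, mid).factor)
    coastal = binary_dilation(land5, iterations=1) & ~land5
    k490 = k490 + np.where(coastal, cfg.k490_coastal, 0.0)

    # --- bathymetry: per-coarse-block structure with calibrated shelves
    role = np.full(n_cells, "abyss", dtype=object)
    role[land] = "land"
    role[bound] = "shelf"
    role[normal] = "shelf"
    role[edge] = "edge"
    role[marginal] = "marginal"
    marg_t = dict(zip((int(c) for c in marginal), _marginal_targets(lim.i_min, len(marginal))))

    fc = nesting(coarse, fine).factor  # 120
    fm = nesting(mid, fine).factor  # 10
    cm = nesting(coarse, mid).factor  # 12
    z = np.empty(fine.shape)
    sides = rng.integers(0, 4, size=n_cells)  # shelf side per cell: W/E/S/N
    u_fine = rng.random(fine.shape)

    def shelf_slices(side: int, r0: int, c0: int):
        """(fine rows, fine cols) of the shelf region inside one block."""
        if side == 0:
            return slice(r0, r0 + fc), slice(c0, c0 + _SHELF_FINE)
        if side == 1:
            return slice(r0, r0 + fc), slice(c0 + fc - _SHELF_FINE, c0 + fc)
        if side == 2:
            return slice(r0, r0 + _SHELF_FINE), slice(c0, c0 + fc)
        return slice(r0 + fc - _SHELF_FINE, r0 + fc), slice(c0, c0 + fc)

    for flat in range(n_cells):
        i, j = np.unravel_index(flat, coarse.shape)
        r0, c0 = i * fc, j * fc
        blk = (slice(r0, r0 + fc), slice(c0, c0 + fc))
        kind = role[flat]
        if kind == "land":
            z[blk] = -(5.0 + 45.0 * u_fine[blk])
            continue
        if kind == "abyss":
            z[blk] = 3500.0 + 1500.0 * u_fine[blk]
            continue
        # shelf-bearing cells: start from deep water, then carve the shelf
        z[blk] = 3500.0 + 1500.0 * u_fine[blk]
        sl = shelf_slices(int(sides[flat]), r0, c0)
        # 5' cells overlapping the shelf region
        m_rows = slice(sl[0].start // fm, (sl[0].stop + fm - 1) // fm)
        m_cols = slice(sl[1].start // fm, (sl[1].stop + fm - 1) // fm)
        par_blk = par[m_rows, m_cols]
        k_blk = k490[m_rows, m_cols]
        if kind == "shelf":
            zc = float(np.min(max_reef_depth(par_blk, k_blk, _SUITABLE_THROUGH)))
            d = zc * (0.30 + 0.45 * rng.random())
            z[sl] = d + 0.05 * zc * (u_fine[sl] - 0.5)
        else:
            t_drop = lim.i_min if kind == "edge" else marg_t[flat]
            z[sl] = float(np.max(max_reef_depth(par_blk, k_blk, t_drop)))

    env = EnvStack(
        T=Raster(coarse, t),
        S=Raster(coarse, s),
        NO3=Raster(coarse, no3),
        PO4=Raster(coarse, po4),
        PAR=Raster(mid, par),
        K490=Raster(mid, k490),
        Z=Raster(fine, z),
        omega=omega_r,
    )

    # --- ground truth suitability at the planted limits
    truth_result = predict_habitat(env, lim, omega_mask=None)
    fine_mask = truth_result.fine_mask

    # --- reef polygons: one per reef cell, >= 1 vertex per chosen suitable cell
    omit_flags = rng.random(len(normal)) < cfg.omission_rate
    omitted = normal[omit_flags]
    reef_cells_flat = np.concatenate([bound, edge, normal[~omit_flags]])
    rows = []
    pid = 0
    for flat in sorted(int(x) for x in reef_cells_flat):
        i, j = np.unravel_index(flat, coarse.shape)
        blk_mask = fine_mask.values[i * fc : (i + 1) * fc, j * fc : (j + 1) * fc]
        cand = np.argwhere(blk_mask)
        if cand.size == 0:  # pragma: no cover - construction guarantees non-empty
            raise RuntimeError(f"reef cell {(i, j)} has no suitable 30-arcsec cell")
        k = int(rng.integers(cfg.min_vertices_per_cell, cfg.max_vertices_per_cell + 1))
        pick = cand[rng.choice(len(cand), size=min(k, len(cand)), replace=False)]
        for (fi, fj) in pick:
            lat = fine.lat_centers[i * fc + fi] + 0.6 * RES_30SEC * (rng.random() - 0.5)
            lon = fine.lon_centers[j * fc + fj] + 0.6 * RES_30SEC * (rng.random() - 0.5)
            rows.append((pid, lat, lon))
        pid += 1
    for flat in sorted(int(x) for x in commission):
        i, j = np.unravel_index(flat, coarse.shape)
        for _ in range(4):
            fi = int(rng.integers(0, fc))
            fj = int(rng.integers(0, fc))
            lat = fine.lat_centers[i * fc + fi] + 0.6 * RES_30SEC * (rng.random() - 0.5)
            lon = fine.lon_centers[j * fc + fj] + 0.6 * RES_30SEC * (rng.random() - 0.5)
            rows.append((pid, lat, lon))
        pid += 1
    reefs = pd.DataFrame(rows, columns=["polygon_id", "lat", "lon"])

    def flag_grid(flat_idx) -> np.ndarray:
        g = np.zeros(n_cells, dtype=bool)
        g[np.asarray(flat_idx, dtype=int)] = True
        return g.reshape(coarse.shape)

    truth = PlantedTruth(
        limits=lim,
        i_min=lim.i_min,
        fine_mask=fine_mask,
        reef_cells=flag_grid(reef_cells_flat),
        commission_cells=flag_grid(commission),
        omitted_cells=flag_grid(omitted),
    )

    # --- monthly and weekly series: annual value +/- a seasonal cycle
    amps = {"T": 2.4, "S": 1.2, "NO3": 0.6, "PO4": 0.08}
    floors = {"T": None, "S": None, "NO3": 0.0, "PO4": 0.0}
    annual = {"T": t, "S": s, "NO3": no3, "PO4": po4}
    monthly: dict[str, list[Raster]] = {}
    phases = {v: rng.uniform(0.0, 2.0 * math.pi) for v in amps}
    for var, amp in amps.items():
        series = []
        for m in range(12):
            cyc = amp * math.cos(2.0 * math.pi * (m + 0.5) / 12.0 + phases[var])
            vals = annual[var] + cyc
            if floors[var] is not None:
                vals = np.clip(vals, floors[var], None)
            series.append(Raster(coarse, vals))
        monthly[var] = series
    phase_w = rng.uniform(0.0, 2.0 * math.pi)
    weekly_t = [
        Raster(coarse, t + 3.2 * math.cos(2.0 * math.pi * (w + 0.5) / 52.0 + phase_w))
        for w in range(52)
    ]

    return SyntheticWorld(env, ta_r, dic_r, monthly, weekly_t, reefs, truth, cfg)


# ---------------------------------------------------------------------------
# fixture round-trip

_UNITS = {
    "T": "degC",
    "S": "psu",
    "NO3": "umol L-1",
    "PO4": "umol L-1",
    "TA": "umol kg-1",
    "DIC": "umol kg-1",
    "omega": "1",
    "PAR": "umol photons m-2 s-1",
    "K490": "m-1",
    "Z": "m",
}


def write_fixture(world: SyntheticWorld, directory) -> dict[str, str]:
    """Write a world in the pipeline's file dialects; returns the path map."""
    from pathlib import Path

    from . import io as rio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    env = world.env
    layers = {
        "T": env.T,
        "S": env.S,
        "NO3": env.NO3,
        "PO4": env.PO4,
        "TA": world.ta,
        "DIC": world.dic,
        "omega": env.omega,
        "PAR": env.PAR,
        "K490": env.K490,
        "Z": env.Z,
    }
    paths: dict[str, str] = {}
    for name, raster in layers.items():
        p = d / f"{name}.nc"
        rio.write_raster(raster, p, name, _UNITS.get(name))
        paths[name] = str(p)
    for var, series in world.monthly.items():
        p = d / f"monthly_{var}.nc"
        rio.write_raster_series(series, p, var, _UNITS.get(var))
        paths[f"monthly_{var}"] = str(p)
    p = d / "weekly_T.nc"
    rio.write_raster_series(world.weekly_t, p, "T", _UNITS["T"])
    paths["weekly_T"] = str(p)
    p = d / "reefs.csv"
    rio.write_polygons(world.reefs, p)
    paths["reefs"] = str(p)
    truth = dict(world.truth.limits.to_dict(), seed=world.config.seed)
    p = d / "truth.toml"
    rio.write_flat_toml(truth, p)
    paths["truth"] = str(p)
    return paths


def read_fixture(directory):
    """Reload a written fixture: (EnvStack, reefs, planted ToleranceLimits)."""
    from pathlib import Path

    from . import io as rio

    d = Path(directory)
    env = rio.load_env({k: str(d / f"{k}.nc") for k in ("T", "S", "NO3", "PO4", "PAR", "K490", "Z", "omega")})
    reefs = rio.read_polygons(d / "reefs.csv")
    truth = rio.read_toml(d / "truth.toml")
    limits = ToleranceLimits.from_dict(truth)
    return env, reefs, limits
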