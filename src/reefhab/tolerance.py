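"""Inverse mode: tolerance limits from observed reef locations.

Charted reef polygons are rasterized onto the 30″ grid by vertex
membership — every 30″ cell containing at least one polygon vertex is
marked as observed reef habitat (interior fill is deliberately not
applied, matching how the observation grid is defined).  A 1° cell counts
as a reef cell when its observed-habitat fraction is above zero.  The
derived envelope is then the global extreme of each environmental
variable over reef cells: two-sided ranges for temperature and salinity,
upper thresholds for the nutrients, a lower threshold for Ω_ara.  The
minimum light intensity I_min is *not* derived here — depth/reef-charting
inconsistencies make direct inversion of the light equation unreliable,
so I_min comes from the ROC sweep in :mod:`reefhab.evaluation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import GridSpec, Raster, aggregate_fraction
from .habitat import EnvStack, RegionMask, ToleranceLimits

logger = logging.getLogger(__name__)

TimeScale = str  # "annual" | "monthly" | "weekly"
_SCALES = ("annual", "monthly", "weekly")


@dataclass
class ReefObservations:
    """Rasterized reef presence: 30″ mask plus 1° observed-habitat fraction."""

    fine_mask: Raster
    coarse_fraction: Raster
    n_vertices_used: int
    n_vertices_dropped: int

    @property
    def presence(self) -> np.ndarray:
        """Binary 1° observed presence (fraction strictly above zero)."""
        return (self.coarse_fraction.values > 0).astype(np.int8)


@dataclass(frozen=True)
class DerivedLimits:
    """Envelope extremes over reef cells at a given temporal scale.

    ``omega_min`` is None when no reef cell carries a checked Ω value.
    """

    t_min: float
    t_max: float
    s_min: float
    s_max: float
    no3_max: float
    po4_max: float
    omega_min: float | None
    time_scale: TimeScale

    def to_tolerance_limits(self, i_min: float, omega_fallback: float = 1e-9) -> ToleranceLimits:
        return ToleranceLimits(
            t_min=self.t_min,
            t_max=self.t_max,
            s_min=self.s_min,
            s_max=self.s_max,
            no3_max=self.no3_max,
            po4_max=self.po4_max,
            omega_min=self.omega_min if self.omega_min is not None else omega_fallback,
            i_min=i_min,
        )


def _iter_vertices(polygons) -> Iterable[tuple[float, float]]:
    if isinstance(polygons, pd.DataFrame):
        yield from zip(polygons["lat"].to_numpy(), polygons["lon"].to_numpy())
    else:
        for poly in polygons:
            for lat, lon in poly:
                yield lat, lon


def rasterize_reefs(
    polygons, spec: GridSpec, coarse_spec: GridSpec | None = None
) -> ReefObservations:
    """Mark every 30″ cell holding at least one polygon vertex.

    ``polygons`` is either an iterable of ``[(lat, lon), ...]`` vertex
    sequences or a DataFrame with ``polygon_id``/``lat``/``lon`` columns.
    Vertices outside the grid are dropped (their count is logged and
    reported).  Cells are half-open, so a vertex on a shared edge belongs
    to exactly one cell.
    """
    mask = np.zeros(spec.shape, dtype=bool)
    used = dropped = 0
    for lat, lon in _iter_vertices(polygons):
        loc = spec.locate(float(lat), float(lon))
        if loc is None:
            dropped += 1
            continue
        mask[loc] = True
        used += 1
    if dropped:
        logger.info("rasterize_reefs: dropped %d out-of-domain vertices", dropped)
    fine = Raster(spec, mask)
    if coarse_spec is None:
        coarse_spec = GridSpec(spec.lat_min, spec.lat_max, spec.lon_min, spec.lon_max, 1.0)
    frac = aggregate_fraction(fine, coarse_spec)
    return ReefObservations(fine, frac, used, dropped)


def _extreme(
    values: list[np.ndarray], reef: np.ndarray, name: str, mode: str, trim: float | None
) -> float:
    """Extreme of a variable over reef cells across time slices; NaNs ignored."""
    pool = np.concatenate([np.asarray(v)[reef].ravel() for v in values])
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        raise ValueError(f"variable {name} has no valid values over reef cells")
    if trim is not None:
        lo, hi = np.quantile(pool, [trim, 1.0 - trim])
        return float(lo if mode == "min" else hi)
    return float(pool.min() if mode == "min" else pool.max())


def derive_limits(
    obs: ReefObservations,
    env: EnvStack,
    time_scale: TimeScale = "annual",
    monthly: Mapping[str, Sequence[Raster]] | None = None,
    weekly_t: Sequence[Raster] | None = None,
    omega_mask: RegionMask | None = None,
    quantile_trim: float | None = None,
) -> DerivedLimits:
    """Global min/max of each environmental variable over 1° reef cells.

    For ``monthly``/``weekly`` scales the extremes run across all time
    slices available for a variable (weekly series exist for temperature
    only; other variables fall back to monthly, then annual).  Ω_ara is
    always taken from the annual field, restricted to reef cells outside
    ``omega_mask`` with non-missing Ω.  ``quantile_trim`` optionally
    replaces raw extremes with (q, 1−q) quantiles for sensitivity
    analysis; by default raw global extremes are used.
    """
    if time_scale not in _SCALES:
        raise ValueError(f"time_scale must be one of {_SCALES}")
    if obs.coarse_fraction.spec != env.coarse_spec:
        raise ValueError("observation fraction grid differs from environment grid")
    reef = obs.coarse_fraction.values > 0
    if not reef.any():
        raise ValueError("reef mask is empty; cannot derive limits")

    def slices(var: str) -> list[np.ndarray]:
        annual = [getattr(env, var).values]
        if time_scale == "annual":
            return annual
        series: list[np.ndarray] = []
        if time_scale == "weekly" and var == "T" and weekly_t is not None:
            series = [r.values for r in weekly_t]
        elif monthly is not None and var in monthly:
            series = [r.values for r in monthly[var]]
        return series if series else annual

    t_min = _extreme(slices("T"), reef, "T", "min", quantile_trim)
    t_max = _extreme(slices("T"), reef, "T", "max", quantile_trim)
    s_min = _extreme(slices("S"), reef, "S", "min", quantile_trim)
    s_max = _extreme(slices("S"), reef, "S", "max", quantile_trim)
    no3_max = _extreme(slices("NO3"), reef, "NO3", "max", quantile_trim)
    po4_max = _extreme(slices("PO4"), reef, "PO4", "max", quantile_trim)

    omega_min: float | None = None
    if env.omega is not None:
        checked = reef & env.omega.valid
        if omega_mask is not None:
            checked &= ~omega_mask.to_array(env.coarse_spec)
        if checked.any():
            omega_min = _extreme([env.omega.values], checked, "omega", "min", quantile_trim)

    return DerivedLimits(
        t_min, t_max, s_min, s_max, no3_max, po4_max, omega_min, time_scale
    )
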