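"""The diagnostic habitat engine: threshold envelope plus light/depth check.

A 30″ cell is potential reef habitat when (a) the enclosing 1° cell passes
the environmental envelope — temperature and salinity inside two-sided
ranges, nitrate and phosphate below upper thresholds, aragonite saturation
above a lower threshold — and (b) the sea floor lies between the surface
and the maximum depth of reef growth,

    Z_max = ln(PAR / I_min) / K490,

evaluated on the enclosing 5′ cell (depth positive downward; zero when
surface irradiance is already below I_min).  The Ω_ara check is skipped
inside configurable regional boxes and wherever Ω is missing, mirroring
gaps in the gridded carbon climatology.  Results are reported as the 30″
suitability mask, the per-1°-cell habitat percentage, and the total
spherical area of suitable cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .grids import GridSpec, Raster, aggregate_fraction, expand, nesting

logger = logging.getLogger(__name__)

ENV_VARS = ("T", "S", "NO3", "PO4", "omega")


@dataclass(frozen=True)
class ToleranceLimits:
    """Environmental envelope for reef habitat.

    Units: temperature °C, salinity psu, nutrients μmol L⁻¹, Ω_ara
    dimensionless, I_min μmol photons m⁻² s⁻¹.  All comparisons against the
    limits are inclusive.
    """

    t_min: float
    t_max: float
    s_min: float
    s_max: float
    no3_max: float
    po4_max: float
    omega_min: float
    i_min: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(f"need t_min < t_max, got {self.t_min} >= {self.t_max}")
        if not self.s_min < self.s_max:
            raise ValueError(f"need s_min < s_max, got {self.s_min} >= {self.s_max}")
        for name in ("no3_max", "po4_max", "omega_min", "i_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def with_i_min(self, i_min: float) -> "ToleranceLimits":
        return replace(self, i_min=i_min)

    def to_dict(self) -> dict[str, float]:
        return {
            "t_min": self.t_min,
            "t_max": self.t_max,
            "s_min": self.s_min,
            "s_max": self.s_max,
            "no3_max": self.no3_max,
            "po4_max": self.po4_max,
            "omega_min": self.omega_min,
            "i_min": self.i_min,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ToleranceLimits":
        return cls(**{k: float(d[k]) for k in cls.__dataclass_fields__ if k in d})


#: Annually averaged limits derived by this analysis (inverse mode on the
#: global climatologies), used as the package default envelope.
DEFAULT_LIMITS = ToleranceLimits(
    t_min=21.7,
    t_max=29.6,
    s_min=28.7,
    s_max=40.4,
    no3_max=4.51,
    po4_max=0.63,
    omega_min=2.82,
    i_min=450.0,
)

#: Tolerance limits of Kleypas (1997), for comparison runs (no Ω check in
#: the original; an effectively unbounded omega_min stands in for "not
#: checked" when a full limit set is required).
K97_LIMITS = ToleranceLimits(
    t_min=18.1,
    t_max=31.5,
    s_min=30.0,
    s_max=39.0,
    no3_max=2.0,
    po4_max=0.2,
    omega_min=1e-9,
    i_min=300.0,
)


@dataclass(frozen=True)
class Box:
    """Named rectangular lat/lon region."""

    name: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def contains(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )


@dataclass(frozen=True)
class RegionMask:
    """Regions where the Ω_ara criterion is not applied."""

    boxes: tuple[Box, ...] = ()

    def to_array(self, spec: GridSpec) -> np.ndarray:
        lat = spec.lat_centers[:, None]
        lon = spec.lon_centers[None, :]
        out = np.zeros(spec.shape, dtype=bool)
        for box in self.boxes:
            out |= box.contains(lat, lon)
        return out


#: Default Ω-exempt regions: rectangles approximating the Indonesian Sea
#: and the wider Caribbean, where the gridded carbon climatology has no
#: TA/DIC coverage.  The source analysis gives no coordinates; these boxes
#: are configuration, not science.
DEFAULT_OMEGA_MASK = RegionMask(
    (
        Box("indonesian_sea", -11.0, 10.0, 95.0, 135.0),
        Box("caribbean", 8.0, 28.0, -90.0, -58.0),
    )
)


@dataclass
class EnvStack:
    """Co-registered environmental layers at the three resolutions.

    T/S/NO3/PO4 (and optionally Ω_ara) at 1°; PAR and K490 at 5′;
    bathymetry Z at 30″ with depth in metres positive below sea level.
    """

    T: Raster
    S: Raster
    NO3: Raster
    PO4: Raster
    PAR: Raster
    K490: Raster
    Z: Raster
    omega: Raster | None = None

    def __post_init__(self) -> None:
        coarse = self.T.spec
        for name in ("S", "NO3", "PO4"):
            if getattr(self, name).spec != coarse:
                raise ValueError(f"{name} grid differs from T grid")
        if self.omega is not None and self.omega.spec != coarse:
            raise ValueError("omega grid differs from T grid")
        if self.K490.spec != self.PAR.spec:
            raise ValueError("K490 grid differs from PAR grid")
        # validates exact nesting 1 deg > 5' > 30"
        nesting(coarse, self.PAR.spec)
        nesting(self.PAR.spec, self.Z.spec)
        nesting(coarse, self.Z.spec)

    @property
    def coarse_spec(self) -> GridSpec:
        return self.T.spec

    @property
    def mid_spec(self) -> GridSpec:
        return self.PAR.spec

    @property
    def fine_spec(self) -> GridSpec:
        return self.Z.spec


@dataclass
class HabitatResult:
    """30″ suitability mask, 1° habitat fraction, and total area (km²)."""

    fine_mask: Raster
    coarse_fraction: Raster
    total_area_km2: float
    rejection_counts: dict[str, int] | None = None


def max_reef_depth(PAR, K490, i_min: float):
    """Maximum depth of reef growth (m, positive downward).

    ``ln(PAR / I_min) / K490`` where surface irradiance exceeds I_min, else
    0 (the light criterion can never be met).  Accepts scalars or arrays.
    """
    PAR = np.asarray(PAR, dtype=float)
    K490 = np.asarray(K490, dtype=float)
    if not i_min > 0:
        raise ValueError("i_min must be positive")
    if np.any(K490[~np.isnan(K490)] <= 0):
        raise ValueError("K490 must be positive")
    if np.any(PAR[~np.isnan(PAR)] < 0):
        raise ValueError("PAR must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(PAR / i_min) / K490
    z = np.where(np.isnan(z), np.nan, np.maximum(z, 0.0))
    z = np.where(PAR <= i_min, 0.0, z)
    z = np.where(np.isnan(PAR) | np.isnan(K490), np.nan, z)
    if z.ndim == 0:
        return float(z)
    return z


def check_env_cell(
    T: float,
    S: float,
    NO3: float,
    PO4: float,
    omega: float | None,
    limits: ToleranceLimits,
) -> bool:
    """Envelope check for a single 1° cell.

    Missing (NaN) T/S/NO3/PO4 fail conservatively; ``omega=None`` or NaN
    means the Ω criterion is not applied for this cell.
    """
    for v, lo, hi in (
        (T, limits.t_min, limits.t_max),
        (S, limits.s_min, limits.s_max),
        (NO3, None, limits.no3_max),
        (PO4, None, limits.po4_max),
    ):
        if v is None or math.isnan(v):
            return False
        if lo is not None and v < lo:
            return False
        if v > hi:
            return False
    if omega is not None and not math.isnan(omega) and omega < limits.omega_min:
        return False
    return True


def check_env_grid(
    env: EnvStack, limits: ToleranceLimits, omega_mask: RegionMask | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Vectorized envelope check over the 1° grid.

    Returns the boolean pass array and per-variable rejection tallies
    (number of 1° cells failing each criterion; a cell can fail several).
    """
    spec = env.coarse_spec
    t, s = env.T.values, env.S.values
    no3, po4 = env.NO3.values, env.PO4.values

    with np.errstate(invalid="ignore"):
        fail = {
            "T": ~((t >= limits.t_min) & (t <= limits.t_max)),
            "S": ~((s >= limits.s_min) & (s <= limits.s_max)),
            "NO3": ~(no3 <= limits.no3_max),
            "PO4": ~(po4 <= limits.po4_max),
        }
        if env.omega is None:
            fail["omega"] = np.zeros(spec.shape, dtype=bool)
        else:
            checked = env.omega.valid
            if omega_mask is not None:
                checked &= ~omega_mask.to_array(spec)
            fail["omega"] = checked & ~(env.omega.values >= limits.omega_min)

    ok = ~(fail["T"] | fail["S"] | fail["NO3"] | fail["PO4"] | fail["omega"])
    counts = {k: int(v.sum()) for k, v in fail.items()}
    return ok, counts


def predict_habitat(
    env: EnvStack,
    limits: ToleranceLimits,
    omega_mask: RegionMask | None = None,
) -> HabitatResult:
    """Run the full decision flow and aggregate to the 1° habitat fraction."""
    ev = HabitatEvaluator(env, limits, omega_mask)
    return ev.result(limits.i_min)


class HabitatEvaluator:
    """Precomputed decision-flow state, reusable across I_min values.

    The envelope check and the bathymetry screen do not depend on I_min;
    only Z_max does.  The I_min sweep exploits this by re-evaluating just
    the light criterion per candidate value.
    """

    def __init__(
        self,
        env: EnvStack,
        limits: ToleranceLimits,
        omega_mask: RegionMask | None = None,
    ) -> None:
        self.env = env
        self.limits = limits
        self.coarse_ok, self.rejections = check_env_grid(env, limits, omega_mask)
        nest_cf = nesting(env.coarse_spec, env.fine_spec)
        nest_mf = nesting(env.mid_spec, env.fine_spec)
        self._f_coarse = nest_cf.factor
        self._f_mid = nest_mf.factor
        z = env.Z.values
        self._depth = np.where(env.Z.missing, np.nan, z)
        self._static_ok = expand(self.coarse_ok, self._f_coarse) & (self._depth > 0)
        self._row_areas = env.fine_spec.row_areas_km2()
        logger.debug("envelope rejections per variable: %s", self.rejections)

    def fine_mask(self, i_min: float) -> np.ndarray:
        zmax = max_reef_depth(self.env.PAR.values, self.env.K490.values, i_min)
        zmax = np.where(np.isnan(zmax), 0.0, zmax)  # missing PAR/K490: light fails
        return self._static_ok & (self._depth <= expand(zmax, self._f_mid))

    def result(self, i_min: float) -> HabitatResult:
        mask = self.fine_mask(i_min)
        fine = Raster(self.env.fine_spec, mask)
        frac = aggregate_fraction(fine, self.env.coarse_spec)
        area = float((mask.sum(axis=1) * self._row_areas).sum())
        return HabitatResult(fine, frac, area, dict(self.rejections))


def habitat_area(result: HabitatResult) -> float:
    """Total spherical area (km²) of suitable 30″ cells, recomputed from the mask."""
    mask = result.fine_mask.values.astype(bool) & ~result.fine_mask.missing
    row_areas = result.fine_mask.spec.row_areas_km2()
    return float((mask.sum(axis=1) * row_areas).sum())
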