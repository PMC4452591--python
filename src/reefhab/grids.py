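"""Equal-angle geographic rasters and their multi-resolution nesting.

The habitat analysis runs on three co-registered cell-centered lat/lon
grids: 1° (climatological fields), 5′ (ocean-color fields) and 30″
(bathymetry and the suitability mask).  A 1° cell encloses a 12 × 12 block
of 5′ cells and a 120 × 120 block of 30″ cells; a 5′ cell encloses a
10 × 10 block of 30″ cells.  All grids here share a bounding box within
the 40° N–40° S study band, cells are half-open intervals ``[lo, hi)`` in
both axes, and areas are computed on a sphere of radius 6371 km.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: degrees per cell for the three canonical resolutions
RES_1DEG = 1.0
RES_5MIN = 1.0 / 12.0
RES_30SEC = 1.0 / 120.0

_LAT_BAND = (-40.0, 40.0)


def _cells(extent: float, resolution: float) -> int:
    n = extent / resolution
    n_round = round(n)
    if n_round <= 0 or abs(n - n_round) > 1e-6:
        raise ValueError(
            f"extent {extent} deg is not a positive integer multiple of "
            f"resolution {resolution} deg"
        )
    return n_round


@dataclass(frozen=True)
class GridSpec:
    """Cell-centered equal-angle grid over ``[lat_min, lat_max] × [lon_min, lon_max]``.

    ``resolution`` is in degrees per cell (1, 1/12 or 1/120 in the standard
    pipeline, but any resolution whose extents divide exactly is accepted).
    Longitudes follow the [-180, 180) convention; latitude must stay within
    the 40° N–40° S band the model is defined on.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float

    n_lat: int = field(init=False, repr=False, compare=False)
    n_lon: int = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (_LAT_BAND[0] <= self.lat_min < self.lat_max <= _LAT_BAND[1]):
            raise ValueError(
                f"latitude range [{self.lat_min}, {self.lat_max}] must lie "
                f"within [{_LAT_BAND[0]}, {_LAT_BAND[1]}]"
            )
        if not (-180.0 <= self.lon_min < self.lon_max <= 180.0):
            raise ValueError(
                f"longitude range [{self.lon_min}, {self.lon_max}] must lie "
                "within [-180, 180]"
            )
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        object.__setattr__(self, "n_lat", _cells(self.lat_max - self.lat_min, self.resolution))
        object.__setattr__(self, "n_lon", _cells(self.lon_max - self.lon_min, self.resolution))

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat_min + np.arange(self.n_lat + 1) * (
            (self.lat_max - self.lat_min) / self.n_lat
        )

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_min + np.arange(self.n_lon + 1) * (
            (self.lon_max - self.lon_min) / self.n_lon
        )

    @property
    def lat_centers(self) -> np.ndarray:
        e = self.lat_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        e = self.lon_edges
        return 0.5 * (e[:-1] + e[1:])

    def same_extent(self, other: "GridSpec") -> bool:
        return (
            math.isclose(self.lat_min, other.lat_min, abs_tol=1e-9)
            and math.isclose(self.lat_max, other.lat_max, abs_tol=1e-9)
            and math.isclose(self.lon_min, other.lon_min, abs_tol=1e-9)
            and math.isclose(self.lon_max, other.lon_max, abs_tol=1e-9)
        )

    def locate(self, lat: float, lon: float) -> tuple[int, int] | None:
        """Cell index of a point, or ``None`` when outside the domain.

        Cells are half-open ``[lo, hi)``; a point on the outer lat/lon_max
        edge belongs to no cell.
        """
        if not (self.lat_min <= lat < self.lat_max):
            return None
        if not (self.lon_min <= lon < self.lon_max):
            return None
        i = int((lat - self.lat_min) / self.resolution)
        j = int((lon - self.lon_min) / self.resolution)
        # guard against float round-down at exact interior edges
        i = min(max(i, 0), self.n_lat - 1)
        j = min(max(j, 0), self.n_lon - 1)
        if lat < self.lat_edges[i]:
            i -= 1
        elif lat >= self.lat_edges[i + 1]:
            i += 1
        if lon < self.lon_edges[j]:
            j -= 1
        elif lon >= self.lon_edges[j + 1]:
            j += 1
        return i, j

    def row_areas_km2(self) -> np.ndarray:
        """Spherical area (km²) of one cell in each latitude row.

        Computed from shared edge sines so the sum over a column telescopes
        to the analytic band area.
        """
        sin_e = np.sin(np.radians(self.lat_edges))
        dlam = math.radians(self.resolution)
        return EARTH_RADIUS_KM**2 * dlam * np.diff(sin_e)

    def band_area_km2(self) -> float:
        """Analytic area of the full domain."""
        return (
            EARTH_RADIUS_KM**2
            * math.radians(self.lon_max - self.lon_min)
            * (math.sin(math.radians(self.lat_max)) - math.sin(math.radians(self.lat_min)))
        )


@dataclass
class Raster:
    """Values on a :class:`GridSpec` with an explicit missing-data mask.

    ``values`` is indexed ``[lat, lon]`` with row 0 at ``lat_min`` (both
    axes ascending, CF-style).  ``missing`` marks cells that carry no
    numeric meaning; under the mask ``values`` holds NaN.
    """

    spec: GridSpec
    values: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.spec.shape}"
            )
        if self.missing is None:
            if self.values.dtype.kind == "f":
                self.missing = np.isnan(self.values)
            else:
                self.missing = np.zeros(self.spec.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.spec.shape:
                raise ValueError("missing mask shape does not match grid")
            if self.values.dtype.kind == "f":
                self.values = self.values.copy()
                self.values[self.missing] = np.nan

    @classmethod
    def full(cls, spec: GridSpec, value: float, dtype=float) -> "Raster":
        return cls(spec, np.full(spec.shape, value, dtype=dtype))

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy(), self.missing.copy())

    @property
    def valid(self) -> np.ndarray:
        return ~self.missing


# ---------------------------------------------------------------------------
# operations


def cell_area(lat_lo: float, lat_hi: float, dlon: float) -> float:
    """Spherical area (km²) of a lat band slice ``[lat_lo, lat_hi] × dlon``.

    Uses the exact zone formula R²·Δλ·(sin φ_hi − sin φ_lo).
    """
    if not (-90.0 <= lat_lo < lat_hi <= 90.0):
        raise ValueError(f"need -90 <= lat_lo < lat_hi <= 90, got [{lat_lo}, {lat_hi}]")
    if dlon < 0:
        raise ValueError("dlon must be non-negative")
    return (
        EARTH_RADIUS_KM**2
        * math.radians(dlon)
        * (math.sin(math.radians(lat_hi)) - math.sin(math.radians(lat_lo)))
    )


@dataclass(frozen=True)
class Nesting:
    """Exact nesting of a fine grid inside a coarse grid (shared extent).

    Each coarse cell ``(i, j)`` maps to the ``factor × factor`` block of
    fine cells ``[i·f, (i+1)·f) × [j·f, (j+1)·f)``; blocks partition the
    fine grid with no overlap and no gap.
    """

    coarse: GridSpec
    fine: GridSpec
    factor: int

    @property
    def cells_per_block(self) -> int:
        return self.factor * self.factor

    def block(self, i: int, j: int) -> tuple[slice, slice]:
        f = self.factor
        return slice(i * f, (i + 1) * f), slice(j * f, (j + 1) * f)

    def coarse_index(self, i_fine: int, j_fine: int) -> tuple[int, int]:
        return i_fine // self.factor, j_fine // self.factor


def subdivide(coarse: GridSpec, fine_resolution: float) -> Nesting:
    """Nest a finer resolution inside ``coarse`` over the same extent."""
    ratio = coarse.resolution / fine_resolution
    factor = round(ratio)
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"fine resolution {fine_resolution} does not divide coarse "
            f"resolution {coarse.resolution} exactly"
        )
    fine = GridSpec(
        coarse.lat_min, coarse.lat_max, coarse.lon_min, coarse.lon_max, fine_resolution
    )
    return Nesting(coarse, fine, factor)


def nesting(coarse: GridSpec, fine: GridSpec) -> Nesting:
    """Validate that ``fine`` nests exactly in ``coarse`` and return the map."""
    if not coarse.same_extent(fine):
        raise ValueError("grids do not share an extent; exact nesting required")
    nest = subdivide(coarse, fine.resolution)
    if nest.fine.shape != fine.shape:
        raise ValueError("fine grid shape inconsistent with nesting")
    return Nesting(coarse, fine, nest.factor)


def aggregate_fraction(fine: Raster, coarse: GridSpec) -> Raster:
    """Fraction of true fine cells per coarse block.

    The denominator is the full block — land and ocean cells alike — so
    predicted and observed presence percentages are directly comparable.
    Missing fine cells count as false.
    """
    nest = nesting(coarse, fine.spec)
    f = nest.factor
    vals = fine.values.astype(bool) & ~fine.missing
    frac = vals.reshape(coarse.n_lat, f, coarse.n_lon, f).mean(axis=(1, 3))
    return Raster(coarse, frac)


def expand(coarse_values: np.ndarray, factor: int) -> np.ndarray:
    """Repeat each coarse cell value over its factor × factor fine block."""
    return np.repeat(np.repeat(coarse_values, factor, axis=0), factor, axis=1)


def lookup_coarse(fine_spec: GridSpec, i_fine: int, j_fine: int, coarse: Raster) -> float:
    """Value of the coarse cell enclosing a fine cell, with gap filling.

    If the enclosing coarse cell is missing, the nearest non-missing
    neighbor within a 1-cell radius (3 × 3 neighborhood, center-to-center
    distance from the fine cell, row-major tie-break) is used; if that
    neighborhood is entirely missing the value is reported missing (NaN).
    """
    lat = fine_spec.lat_centers[i_fine]
    lon = fine_spec.lon_centers[j_fine]
    loc = coarse.spec.locate(lat, lon)
    if loc is None:
        raise ValueError("fine cell lies outside the coarse domain")
    ic, jc = loc
    if not coarse.missing[ic, jc]:
        return float(coarse.values[ic, jc])
    best = math.inf
    best_val = math.nan
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            ii, jj = ic + di, jc + dj
            if di == dj == 0 or not (0 <= ii < coarse.spec.n_lat and 0 <= jj < coarse.spec.n_lon):
                continue
            if coarse.missing[ii, jj]:
                continue
            d = math.hypot(
                coarse.spec.lat_centers[ii] - lat, coarse.spec.lon_centers[jj] - lon
            )
            if d < best:
                best = d
                best_val = float(coarse.values[ii, jj])
    return best_val
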