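"""File dialects and the end-to-end pipeline driver.

Rasters travel as CF-style netCDF (``lat``/``lon`` coordinate variables,
ascending axes, ``_FillValue`` for missing data; written through xarray's
scipy backend as netCDF-3 classic).  Files arriving with [0, 360)
longitudes or descending axes are normalized on read.  Reef polygons are
a minimal vertex table (CSV with ``polygon_id``, ``lat``, ``lon``);
tolerance limits, region masks and run settings are flat TOML.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec, Raster
from .habitat import (
    Box,
    EnvStack,
    RegionMask,
    ToleranceLimits,
    predict_habitat,
)
from . import carbonate, evaluation, tolerance

logger = logging.getLogger(__name__)

_FILL = 9.969209968386869e36  # netCDF default float fill


# ---------------------------------------------------------------------------
# rasters


def _spec_from_coords(lat: np.ndarray, lon: np.ndarray, path) -> GridSpec:
    def step(c, name):
        if c.size < 2:
            return None
        d = np.diff(c)
        if not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError(f"{path}: coordinate {name} is not equally spaced")
        return float(d[0])

    dlat = step(lat, "lat")
    dlon = step(lon, "lon")
    if dlat is None and dlon is None:
        raise ValueError(f"{path}: cannot infer resolution from 1x1 grid")
    dlat = dlat if dlat is not None else dlon
    dlon = dlon if dlon is not None else dlat
    if not np.isclose(dlat, dlon, rtol=1e-9):
        raise ValueError(f"{path}: lat and lon resolutions differ ({dlat} vs {dlon})")
    return GridSpec(
        lat_min=float(lat[0] - dlat / 2),
        lat_max=float(lat[-1] + dlat / 2),
        lon_min=float(lon[0] - dlon / 2),
        lon_max=float(lon[-1] + dlon / 2),
        resolution=dlat,
    )


def _normalize(da: xr.DataArray, path) -> xr.DataArray:
    if "lat" not in da.coords or "lon" not in da.coords:
        raise ValueError(f"{path}: missing 'lat'/'lon' coordinate variables")
    lat = da["lat"].values
    if lat.size >= 2 and lat[0] > lat[-1]:
        da = da.isel(lat=slice(None, None, -1))
    lon = da["lon"].values
    if np.any(lon >= 180.0):
        wrapped = ((lon + 180.0) % 360.0) - 180.0
        da = da.assign_coords(lon=wrapped).sortby("lon")
    return da.transpose("lat", "lon", ...)


def read_raster(path, var: str | None = None, expected_units: str | None = None) -> Raster:
    """Read one 2-D raster; normalizes longitudes to [-180, 180) and axis order."""
    path = Path(path)
    try:
        ds = xr.open_dataset(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"{path}: cannot parse netCDF ({exc})") from exc
    with ds:
        names = [n for n in ds.data_vars if ds[n].ndim >= 2]
        if var is None:
            if len(names) != 1:
                raise ValueError(f"{path}: expected one data variable, found {names}")
            var = names[0]
        if var not in ds:
            raise ValueError(f"{path}: variable {var!r} not present (has {list(ds.data_vars)})")
        da = _normalize(ds[var], path)
        units = da.attrs.get("units")
        if expected_units is not None and units is not None and units != expected_units:
            logger.warning("%s: units %r differ from expected %r", path, units, expected_units)
        spec = _spec_from_coords(da["lat"].values, da["lon"].values, path)
        return Raster(spec, np.asarray(da.values, dtype=float))


def read_raster_series(path, var: str | None = None) -> list[Raster]:
    """Read a (time, lat, lon) raster stack as a list of time slices."""
    path = Path(path)
    with xr.open_dataset(path) as ds:
        if var is None:
            names = [n for n in ds.data_vars if ds[n].ndim == 3]
            if len(names) != 1:
                raise ValueError(f"{path}: expected one 3-D variable, found {names}")
            var = names[0]
        da = _normalize(ds[var], path)
        spec = _spec_from_coords(da["lat"].values, da["lon"].values, path)
        tdim = [d for d in da.dims if d not in ("lat", "lon")]
        if len(tdim) != 1:
            raise ValueError(f"{path}: variable {var!r} is not (time, lat, lon)")
        return [
            Raster(spec, np.asarray(da.isel({tdim[0]: k}).values, dtype=float))
            for k in range(da.sizes[tdim[0]])
        ]


def _to_dataarray(raster: Raster, name: str, units: str | None) -> xr.DataArray:
    da = xr.DataArray(
        raster.values.astype(float),
        coords={"lat": raster.spec.lat_centers, "lon": raster.spec.lon_centers},
        dims=("lat", "lon"),
        name=name,
    )
    if units:
        da.attrs["units"] = units
    da["lat"].attrs["units"] = "degrees_north"
    da["lon"].attrs["units"] = "degrees_east"
    return da


def write_raster(raster: Raster, path, name: str = "value", units: str | None = None) -> None:
    da = _to_dataarray(raster, name, units)
    da.to_dataset().to_netcdf(path, engine="scipy", encoding={name: {"_FillValue": _FILL}})


def write_raster_series(rasters: Sequence[Raster], path, name: str, units: str | None = None) -> None:
    spec = rasters[0].spec
    stack = np.stack([r.values for r in rasters])
    da = xr.DataArray(
        stack,
        coords={"time": np.arange(len(rasters)), "lat": spec.lat_centers, "lon": spec.lon_centers},
        dims=("time", "lat", "lon"),
        name=name,
    )
    if units:
        da.attrs["units"] = units
    da.to_dataset().to_netcdf(path, engine="scipy", encoding={name: {"_FillValue": _FILL}})


# ---------------------------------------------------------------------------
# polygons and configs


def read_polygons(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"polygon_id", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: polygon table lacks columns {sorted(missing)}")
    return df


def write_polygons(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_flat_toml(mapping: Mapping, path) -> None:
    """Write a flat (or one-level-nested) mapping as TOML."""
    lines = []
    tables = []
    for k, v in mapping.items():
        if isinstance(v, Mapping):
            tables.append((k, v))
        else:
            lines.append(f"{k} = {_toml_scalar(v)}")
    for name, tbl in tables:
        lines.append("")
        lines.append(f"[{name}]")
        for k, v in tbl.items():
            lines.append(f"{k} = {_toml_scalar(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def read_limits(path) -> ToleranceLimits:
    return ToleranceLimits.from_dict(read_toml(path))


def write_limits(limits: ToleranceLimits, path) -> None:
    write_flat_toml(limits.to_dict(), path)


def read_region_mask(path) -> RegionMask:
    data = read_toml(path)
    boxes = tuple(
        Box(name, float(b["lat_min"]), float(b["lat_max"]), float(b["lon_min"]), float(b["lon_max"]))
        for name, b in data.items()
    )
    return RegionMask(boxes)


def write_region_mask(mask: RegionMask, path) -> None:
    write_flat_toml(
        {
            b.name: {
                "lat_min": b.lat_min,
                "lat_max": b.lat_max,
                "lon_min": b.lon_min,
                "lon_max": b.lon_max,
            }
            for b in mask.boxes
        },
        path,
    )


# ---------------------------------------------------------------------------
# pipeline


_ENV_KEYS = ("T", "S", "NO3", "PO4", "PAR", "K490", "Z")


@dataclass
class RunConfig:
    """One reproducible end-to-end run.

    ``env`` maps layer names (T, S, NO3, PO4, PAR, K490, Z, and optionally
    omega or TA+DIC) to netCDF paths.  Exactly one of ``i_min`` / ``sweep``
    selects a fixed light threshold or the ROC optimization; limits come
    from a file or, with ``derive=True``, from inverse mode on the reef
    observations.
    """

    env: dict[str, str]
    out_dir: str
    reefs: str | None = None
    limits_file: str | None = None
    derive: bool = False
    i_min: float | None = None
    sweep: bool = False
    omega_mask_file: str | None = None
    use_default_omega_mask: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.sweep == (self.i_min is not None):
            raise ValueError("choose exactly one of a fixed i_min or sweep mode")
        if self.derive and self.limits_file:
            raise ValueError("limits come either from a file or from derivation, not both")
        if (self.derive or self.sweep) and not self.reefs:
            raise ValueError("derivation and sweep modes need reef observations")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        data = read_toml(path)
        run = data.get("run", {})
        return cls(
            env={k: str(v) for k, v in data.get("env", {}).items()},
            out_dir=str(run.get("out_dir", ".")),
            reefs=run.get("reefs"),
            limits_file=run.get("limits_file"),
            derive=bool(run.get("derive", False)),
            i_min=float(run["i_min"]) if "i_min" in run else None,
            sweep=bool(run.get("sweep", False)),
            omega_mask_file=run.get("omega_mask_file"),
            use_default_omega_mask=bool(run.get("use_default_omega_mask", False)),
            log_level=str(run.get("log_level", "INFO")),
        )


def load_env(paths: Mapping[str, str]) -> EnvStack:
    """Assemble an :class:`EnvStack`, computing Ω from TA+DIC when needed."""
    missing = [k for k in _ENV_KEYS if k not in paths]
    if missing:
        raise ValueError(f"environment layers missing: {missing}")
    layers = {k: read_raster(paths[k]) for k in _ENV_KEYS}
    omega = None
    if "omega" in paths:
        omega = read_raster(paths["omega"])
    elif "TA" in paths and "DIC" in paths:
        logger.info("computing omega_ara from TA and DIC")
        omega = carbonate.omega_field(
            read_raster(paths["TA"]), read_raster(paths["DIC"]), layers["T"], layers["S"]
        )
    return EnvStack(omega=omega, **layers)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the staged analysis and write its products.

    Stages: Ω from TA/DIC if not supplied → optional inverse-mode limit
    derivation → habitat prediction (fixed I_min or I_min sweep) →
    confusion evaluation against observed reefs.  Writes the 1° habitat
    fraction, the signed FP/FN map, the sweep table, and a JSON run
    report; returns the report.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        env = load_env(config.env)
    except Exception as exc:
        raise RuntimeError(f"stage load_env failed: {exc}") from exc

    omega_mask = None
    if config.omega_mask_file:
        omega_mask = read_region_mask(config.omega_mask_file)
    elif config.use_default_omega_mask:
        from .habitat import DEFAULT_OMEGA_MASK

        omega_mask = DEFAULT_OMEGA_MASK

    obs = None
    if config.reefs:
        reefs = read_polygons(config.reefs)
        obs = tolerance.rasterize_reefs(reefs, env.fine_spec, env.coarse_spec)

    if config.derive:
        try:
            derived = tolerance.derive_limits(obs, env, omega_mask=omega_mask)
        except Exception as exc:
            raise RuntimeError(f"stage derive_limits failed: {exc}") from exc
        limits = derived.to_tolerance_limits(i_min=config.i_min if config.i_min else 450.0)
    elif config.limits_file:
        limits = read_limits(config.limits_file)
        if config.i_min is not None:
            limits = limits.with_i_min(config.i_min)
    else:
        from .habitat import DEFAULT_LIMITS

        limits = DEFAULT_LIMITS if config.i_min is None else DEFAULT_LIMITS.with_i_min(config.i_min)

    report: dict = {"limits": limits.to_dict(), "stages": []}

    sweep_result = None
    if config.sweep:
        observed = evaluation.presence_matrix(obs.coarse_fraction)
        sweep_result = evaluation.sweep_imin(env, limits, observed, omega_mask=omega_mask)
        limits = limits.with_i_min(sweep_result.best_i_min)
        report["best_i_min"] = sweep_result.best_i_min
        report["limits"]["i_min"] = sweep_result.best_i_min
        table = pd.DataFrame(
            [
                {
                    "i_min": p.i_min,
                    "TP": p.counts.TP,
                    "FP": p.counts.FP,
                    "FN": p.counts.FN,
                    "TN": p.counts.TN,
                    "TPR": p.TPR,
                    "FPR": p.FPR,
                    "distance": p.distance,
                    "area_km2": p.area_km2,
                }
                for p in sweep_result.points
            ]
        )
        table.to_csv(out / "sweep.csv", index=False)
        report["stages"].append("sweep_imin")

    try:
        result = predict_habitat(env, limits, omega_mask=omega_mask)
    except Exception as exc:
        raise RuntimeError(f"stage predict_habitat failed: {exc}") from exc
    write_raster(result.coarse_fraction, out / "habitat_fraction.nc", "habitat_fraction", "1")
    report["stages"].append("predict_habitat")
    report["total_area_km2"] = result.total_area_km2
    report["rejection_counts"] = result.rejection_counts

    if obs is not None:
        observed = evaluation.presence_matrix(obs.coarse_fraction)
        predicted = evaluation.presence_matrix(result.coarse_fraction)
        counts, signed = evaluation.confusion(observed, predicted)
        tpr, fpr = evaluation.rates(counts)
        write_raster(signed, out / "signed_fp_fn.nc", "observed_minus_predicted", "1")
        report["confusion"] = {
            "TP": counts.TP,
            "FP": counts.FP,
            "FN": counts.FN,
            "TN": counts.TN,
            "TPR": tpr,
            "FPR": fpr,
            "distance": evaluation.roc_distance(tpr, fpr),
        }
        report["observed_cells"] = int(observed.values.sum())
        report["stages"].append("evaluate")

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
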