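"""Gridded and station monthly climatologies: data model and I/O.

Coordinates are WGS84 longitude/latitude with cell-center registration;
latitudes are stored north→south.  Five variables define a climatology:
monthly-average minimum and maximum temperature (°C), monthly precipitation
total (mm), and relative humidity at 09:00 and 15:00 (%).  Any cell missing
any variable in any month is masked out.

NetCDF files are read and written through xarray (NetCDF3 via the scipy
engine); station tables are plain CSV with one row per month and columns
``tmin, tmax, ptotal, rh0900, rh1500``.  Raster map output is TIFF with an
ESRI world-file sidecar for georeferencing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GridDefinition",
    "MonthlyClimatology",
    "ScenarioSpec",
    "ClimateDataError",
    "read_climatology",
    "write_climatology",
    "read_station_csv",
    "apply_scenario_delta",
    "read_occurrences",
    "write_occurrences",
    "write_raster",
]

VARIABLES = ("tmin", "tmax", "ptotal", "rh0900", "rh1500")


class ClimateDataError(ValueError):
    """Raised for malformed or inconsistent climate inputs."""


@dataclass(frozen=True)
class GridDefinition:
    """A regular lon/lat grid, cell-center registered, latitudes north→south.

    ``lon_origin``/``lat_origin`` are the *center* of the north-west cell.
    """

    lon_origin: float
    lat_origin: float
    cell_size: float = 1.0 / 6.0  # degrees; default 10 arc-minutes
    n_lon: int = 1
    n_lat: int = 1

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ClimateDataError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ClimateDataError("grid must have at least one cell")
        h = self.cell_size / 2.0
        west = self.lon_origin - h
        east = self.lon_origin + (self.n_lon - 1) * self.cell_size + h
        north = self.lat_origin + h
        south = self.lat_origin - (self.n_lat - 1) * self.cell_size - h
        if west < -180.0 - 1e-9 or east > 180.0 + 1e-9:
            raise ClimateDataError(f"grid longitudes [{west}, {east}] exceed [-180, 180]")
        if south < -90.0 - 1e-9 or north > 90.0 + 1e-9:
            raise ClimateDataError(f"grid latitudes [{south}, {north}] exceed [-90, 90]")

    @property
    def lons(self) -> np.ndarray:
        return self.lon_origin + self.cell_size * np.arange(self.n_lon)

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, north→south."""
        return self.lat_origin - self.cell_size * np.arange(self.n_lat)

    def locate(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Nearest-cell-center (row, col), or None if outside the grid."""
        j = round((lon - self.lon_origin) / self.cell_size)
        i = round((self.lat_origin - lat) / self.cell_size)
        if 0 <= i < self.n_lat and 0 <= j < self.n_lon:
            return int(i), int(j)
        return None


@dataclass(frozen=True)
class ScenarioSpec:
    """A labelled climate scenario (e.g. one GCM × emission pathway × year)."""

    label: str
    emissions: str = ""
    year: int = 0
    baseline_end_year: int = 1990

    def __post_init__(self) -> None:
        if not self.label:
            raise ClimateDataError("scenario label must be non-empty")
        if self.year and self.year < self.baseline_end_year:
            raise ClimateDataError(
                f"scenario year {self.year} precedes baseline end {self.baseline_end_year}"
            )


class MonthlyClimatology:
    """Per-cell 12-month values of the five climate variables plus a mask.

    Arrays have shape ``(12, n_lat, n_lon)``; ``mask`` is True on valid
    (land) cells.  Use :func:`read_climatology` / :func:`read_station_csv`
    to construct from files, or the ``synthetic`` module for test data.
    """

    def __init__(
        self,
        grid: GridDefinition,
        tmin: np.ndarray,
        tmax: np.ndarray,
        ptotal: np.ndarray,
        rh0900: np.ndarray,
        rh1500: np.ndarray,
        mask: np.ndarray | None = None,
    ):
        self.grid = grid
        shape = (12, grid.n_lat, grid.n_lon)
        arrays = {}
        for name, arr in zip(VARIABLES, (tmin, tmax, ptotal, rh0900, rh1500)):
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != shape:
                raise ClimateDataError(f"{name} has shape {arr.shape}, expected {shape}")
            arrays[name] = arr
        self.tmin = arrays["tmin"]
        self.tmax = arrays["tmax"]
        self.ptotal = arrays["ptotal"]
        self.rh0900 = arrays["rh0900"]
        self.rh1500 = arrays["rh1500"]
        valid = np.ones(shape[1:], dtype=bool)
        for arr in arrays.values():
            valid &= np.all(np.isfinite(arr), axis=0)
        if mask is None:
            mask = valid
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape[1:]:
                raise ClimateDataError(f"mask has shape {mask.shape}, expected {shape[1:]}")
            mask = mask & valid
        self.mask = mask
        self._validate()

    def _validate(self) -> None:
        m = self.mask
        if not m.any():
            return
        if np.any(self.tmin[:, m] > self.tmax[:, m] + 1e-9):
            raise ClimateDataError("tmin exceeds tmax on some valid cell-months")
        if np.any(self.ptotal[:, m] < 0):
            raise ClimateDataError("negative monthly precipitation on valid cells")
        for name in ("rh0900", "rh1500"):
            rh = getattr(self, name)[:, m]
            if np.any(rh < 0) or np.any(rh > 100):
                raise ClimateDataError(f"{name} outside [0, 100] on valid cells")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid.n_lat, self.grid.n_lon)

    def to_dataset(self) -> xr.Dataset:
        coords = {
            "month": np.arange(1, 13, dtype=np.int32),
            "lat": ("lat", self.grid.lats),
            "lon": ("lon", self.grid.lons),
        }
        data = {
            name: (("month", "lat", "lon"), getattr(self, name))
            for name in VARIABLES
        }
        data["mask"] = (("lat", "lon"), self.mask.astype(np.int8))
        ds = xr.Dataset(data, coords=coords)
        ds["tmin"].attrs["units"] = "degC"
        ds["tmax"].attrs["units"] = "degC"
        ds["ptotal"].attrs["units"] = "mm month-1"
        ds["rh0900"].attrs["units"] = "percent"
        ds["rh1500"].attrs["units"] = "percent"
        ds.attrs["cell_size"] = self.grid.cell_size
        ds.attrs["registration"] = "cell-center"
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "MonthlyClimatology":
        missing = [v for v in VARIABLES if v not in ds]
        if missing:
            raise ClimateDataError(f"dataset missing variables: {', '.join(missing)}")
        if ds.sizes.get("month") != 12:
            raise ClimateDataError(f"expected 12 months, got {ds.sizes.get('month')}")
        lats = np.asarray(ds["lat"].values, dtype=float)
        lons = np.asarray(ds["lon"].values, dtype=float)
        if lats.size > 1:
            steps = np.diff(lats)
            if np.any(steps >= 0) or not np.allclose(steps, steps[0], atol=1e-9):
                raise ClimateDataError("latitudes must be regular and north->south")
            cell = -float(steps[0])
        elif lons.size > 1:
            cell = float(lons[1] - lons[0])
        else:
            cell = float(ds.attrs.get("cell_size", 1.0 / 6.0))
        if lons.size > 1 and not np.allclose(np.diff(lons), cell, atol=1e-9):
            raise ClimateDataError("longitude spacing differs from latitude spacing")
        grid = GridDefinition(float(lons[0]), float(lats[0]), cell, lons.size, lats.size)
        mask = None
        if "mask" in ds:
            mask = np.asarray(ds["mask"].values).astype(bool)
        return cls(grid, *(np.asarray(ds[v].values, dtype=np.float64) for v in VARIABLES), mask=mask)


def write_climatology(clim: MonthlyClimatology, path: str | Path) -> None:
    """Write a climatology to NetCDF (classic format via the scipy engine)."""
    clim.to_dataset().to_netcdf(str(path), engine="scipy")


def read_climatology(source: str | Path | dict[str, str | Path]) -> MonthlyClimatology:
    """Read a monthly climatology.

    *source* is either a single multi-variable NetCDF path, a mapping of
    variable name → single-variable NetCDF path (all on identical grids),
    or a station CSV path (delegates to :func:`read_station_csv`).
    """
    if isinstance(source, dict):
        parts = {}
        for name, p in source.items():
            if name not in VARIABLES:
                raise ClimateDataError(f"unknown variable {name!r}; expected one of {VARIABLES}")
            with xr.open_dataset(str(p), engine="scipy") as ds:
                if name not in ds:
                    raise ClimateDataError(f"{p}: variable {name!r} not found")
                parts[name] = ds[name].load()
        missing = [v for v in VARIABLES if v not in parts]
        if missing:
            raise ClimateDataError(f"missing variables: {', '.join(missing)}")
        first = parts[VARIABLES[0]]
        for name, da in parts.items():
            if da.shape != first.shape or not np.allclose(da["lat"], first["lat"]) \
                    or not np.allclose(da["lon"], first["lon"]):
                raise ClimateDataError(f"grid mismatch between {VARIABLES[0]} and {name}")
        ds = xr.Dataset({k: v for k, v in parts.items()})
        return MonthlyClimatology.from_dataset(ds)
    source = Path(source)
    if source.suffix.lower() == ".csv":
        return read_station_csv(source)
    with xr.open_dataset(str(source), engine="scipy") as ds:
        return MonthlyClimatology.from_dataset(ds.load())


def read_station_csv(path: str | Path, lon: float = 0.0, lat: float = 0.0) -> MonthlyClimatology:
    """Read a single-station monthly table as a 1×1-cell climatology.

    Expects 12 rows and columns ``tmin, tmax, ptotal, rh0900, rh1500``;
    optional ``lon``/``lat`` columns override the coordinate arguments.
    """
    df = pd.read_csv(path)
    missing = [v for v in VARIABLES if v not in df.columns]
    if missing:
        raise ClimateDataError(f"{path}: missing columns: {', '.join(missing)}")
    if len(df) != 12:
        raise ClimateDataError(f"{path}: expected 12 monthly rows, got {len(df)}")
    if "lon" in df.columns:
        lon = float(df["lon"].iloc[0])
    if "lat" in df.columns:
        lat = float(df["lat"].iloc[0])
    grid = GridDefinition(lon, lat, n_lon=1, n_lat=1)
    arrs = [df[v].to_numpy(dtype=np.float64).reshape(12, 1, 1) for v in VARIABLES]
    return MonthlyClimatology(grid, *arrs)


def _broadcast(field, shape, name: str) -> np.ndarray:
    arr = np.asarray(field, dtype=np.float64)
    if arr.ndim == 0:
        return np.broadcast_to(arr, shape)
    if arr.shape == shape[1:]:
        return np.broadcast_to(arr[None, :, :], shape)
    if arr.shape == shape:
        return arr
    raise ClimateDataError(f"{name} has shape {arr.shape}; expected scalar, {shape[1:]} or {shape}")


def apply_scenario_delta(
    base: MonthlyClimatology,
    dT: float | np.ndarray = 0.0,
    P_scale: float | np.ndarray = 1.0,
    dRH: float | np.ndarray = 0.0,
) -> MonthlyClimatology:
    """Perturb a baseline climatology into a scenario climatology.

    Temperatures are shifted by ``dT`` (°C), precipitation scaled by
    ``P_scale`` (must be positive), relative humidity shifted by ``dRH``
    (percentage points) and clamped to [0, 100].  Each perturbation may be
    a scalar, a per-cell field, or a per-month-per-cell field.  The land
    mask is preserved.
    """
    shape = (12,) + base.shape
    dT = _broadcast(dT, shape, "dT")
    P_scale = _broadcast(P_scale, shape, "P_scale")
    dRH = _broadcast(dRH, shape, "dRH")
    if np.any(P_scale <= 0):
        raise ClimateDataError("P_scale must be positive everywhere")
    return MonthlyClimatology(
        base.grid,
        base.tmin + dT,
        base.tmax + dT,
        base.ptotal * P_scale,
        np.clip(base.rh0900 + dRH, 0.0, 100.0),
        np.clip(base.rh1500 + dRH, 0.0, 100.0),
        mask=base.mask,
    )


def read_occurrences(path: str | Path) -> np.ndarray:
    """Read occurrence points as an ``(n, 2)`` array of (lon, lat).

    Accepts CSV with ``lon``/``lat`` columns or GeoJSON Point features.
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        obj = json.loads(path.read_text(encoding="utf-8"))
        feats = obj.get("features", [])
        pts = []
        for f in feats:
            geom = f.get("geometry", {})
            if geom.get("type") == "Point":
                pts.append(geom["coordinates"][:2])
        return np.asarray(pts, dtype=float).reshape(-1, 2)
    df = pd.read_csv(path)
    if "lon" not in df.columns or "lat" not in df.columns:
        raise ClimateDataError(f"{path}: occurrence CSV needs 'lon' and 'lat' columns")
    return df[["lon", "lat"]].to_numpy(dtype=float)


def write_occurrences(points: np.ndarray, path: str | Path) -> None:
    """Write (lon, lat) points as GeoJSON."""
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {},
        }
        for x, y in np.asarray(points, dtype=float).reshape(-1, 2)
    ]
    obj = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(obj, indent=1), encoding="utf-8")


def write_raster(
    array: np.ndarray,
    grid: GridDefinition,
    path: str | Path,
    colormap: np.ndarray | None = None,
    nodata: float = np.nan,
) -> None:
    """Write a 2-D field as TIFF with an ESRI world-file sidecar.

    Float arrays are written as float32; integer arrays as uint8 (optionally
    with a 256-entry RGB ``colormap``, values scaled to 16-bit as TIFF
    palettes require).
    """
    import tifffile

    arr = np.asarray(array)
    if arr.shape != (grid.n_lat, grid.n_lon):
        raise ClimateDataError(f"array shape {arr.shape} does not match grid {(grid.n_lat, grid.n_lon)}")
    path = Path(path)
    if np.issubdtype(arr.dtype, np.floating):
        tifffile.imwrite(str(path), arr.astype(np.float32))
    else:
        data = arr.astype(np.uint8)
        if colormap is not None:
            cmap = (np.asarray(colormap, dtype=np.uint16) * 257).T  # (3, 256), 16-bit
            tifffile.imwrite(str(path), data, colormap=cmap)
        else:
            tifffile.imwrite(str(path), data)
    # world file: pixel size, rotation terms, center of upper-left pixel
    world = path.with_suffix(path.suffix + "w") if path.suffix else path.with_suffix(".tfw")
    world.write_text(
        "\n".join(
            f"{v:.10f}"
            for v in (grid.cell_size, 0.0, 0.0, -grid.cell_size, grid.lon_origin, grid.lat_origin)
        )
        + "\n",
        encoding="utf-8",
    )
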