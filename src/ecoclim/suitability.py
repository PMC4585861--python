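"""Classification, area accounting, scenario comparison, and overlays.

EI grids are classified into the four standard suitability classes
(unsuitable < 1, marginal 1–10, suitable 10–20, highly suitable > 20),
class areas are accumulated in km² with a spherical-zone cell-area formula,
and pairs of runs are compared through per-cell stress differences and a
4×4 class-transition matrix.  Occurrence points are validated by
nearest-cell-center lookup on the categorical map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .climate_io import GridDefinition, write_raster
from .indices import AnnualResult, SuitabilityClass, classify

__all__ = [
    "SuitabilityClass",
    "classify",
    "cell_area",
    "grid_cell_areas",
    "area_table",
    "combined_area_table",
    "ChangeMap",
    "stress_change",
    "class_transitions",
    "overlay_occurrences",
    "write_ei_raster",
    "write_class_raster",
    "CLASS_NAMES",
    "CLASS_COLORS",
]

EARTH_RADIUS_KM = 6371.0088

CLASS_NAMES = ("unsuitable", "marginal", "suitable", "highly_suitable")

#: Map legend: white / blue / yellow / red for classes 0..3.
CLASS_COLORS = np.array(
    [[255, 255, 255], [0, 90, 200], [255, 220, 0], [200, 20, 20]], dtype=np.uint8
)


def cell_area(lat_center, cell_size: float):
    """Area in km² of a cell_size×cell_size cell centred at *lat_center*.

    Spherical zone formula: A = R²·Δλ·(sin φ_top − sin φ_bottom).
    """
    lat = np.asarray(lat_center, dtype=np.float64)
    half = cell_size / 2.0
    if np.any(np.abs(lat) + half > 90.0 + 1e-9):
        raise ValueError("cell extends beyond the poles")
    dlam = np.deg2rad(cell_size)
    top = np.deg2rad(lat + half)
    bot = np.deg2rad(lat - half)
    return EARTH_RADIUS_KM**2 * dlam * (np.sin(top) - np.sin(bot))


def grid_cell_areas(grid: GridDefinition) -> np.ndarray:
    """Per-cell areas (km²) as an (n_lat, n_lon) array."""
    per_row = cell_area(grid.lats, grid.cell_size)
    return np.repeat(per_row[:, None], grid.n_lon, axis=1)


def area_table(result: AnnualResult) -> pd.Series:
    """km² in each suitability class over the valid mask, plus the total."""
    areas = grid_cell_areas(result.grid)
    vals = {}
    for code, name in enumerate(CLASS_NAMES):
        sel = result.mask & (result.cls == code)
        vals[name] = float(areas[sel].sum())
    vals["total"] = float(sum(vals[n] for n in CLASS_NAMES))
    return pd.Series(vals, name="area_km2")


def combined_area_table(results: dict[str, AnnualResult]) -> pd.DataFrame:
    """Scenario × class area table (one row per scenario label)."""
    rows = {label: area_table(res) for label, res in results.items()}
    df = pd.DataFrame(rows).T
    df.index.name = "scenario"
    return df


@dataclass
class ChangeMap:
    """Per-cell difference of one stress between two runs (b − a)."""

    grid: GridDefinition
    mask: np.ndarray
    which: str
    delta: np.ndarray


def _check_same_grid(a: AnnualResult, b: AnnualResult) -> np.ndarray:
    if a.grid != b.grid:
        raise ValueError("runs are on different grids")
    return a.mask & b.mask


def stress_change(a: AnnualResult, b: AnnualResult, which: str) -> ChangeMap:
    """Per-cell arithmetic difference of the named stress (CS/HS/DS/WS)."""
    mask = _check_same_grid(a, b)
    delta = np.where(mask, b.stress(which) - a.stress(which), np.nan)
    return ChangeMap(grid=a.grid, mask=mask, which=which.lower(), delta=delta)


def class_transitions(a: AnnualResult, b: AnnualResult, by_area: bool = True) -> pd.DataFrame:
    """4×4 class-transition matrix between two runs (rows: from, cols: to).

    Entries are km² when *by_area* (default), otherwise cell counts.
    """
    mask = _check_same_grid(a, b)
    weights = grid_cell_areas(a.grid) if by_area else np.ones(mask.shape)
    mat = np.zeros((4, 4), dtype=np.float64)
    fa = a.cls[mask]
    fb = b.cls[mask]
    w = weights[mask]
    np.add.at(mat, (fa, fb), w)
    return pd.DataFrame(mat, index=list(CLASS_NAMES), columns=list(CLASS_NAMES))


def overlay_occurrences(points: np.ndarray, result: AnnualResult) -> tuple[pd.DataFrame, pd.Series]:
    """Look up each (lon, lat) point on the classified grid.

    Returns a per-point table (lon, lat, row, col, ei, class name; off-grid
    or masked points flagged ``off_grid``) and a summary with per-class
    counts, the off-grid count, and the fraction of on-grid points with
    EI > 0.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    records = []
    for lon, lat in pts:
        loc = result.grid.locate(lon, lat)
        if loc is None or not result.mask[loc]:
            records.append({"lon": lon, "lat": lat, "row": -1, "col": -1,
                            "ei": np.nan, "class": "off_grid"})
            continue
        i, j = loc
        records.append({
            "lon": lon, "lat": lat, "row": i, "col": j,
            "ei": float(result.ei[i, j]),
            "class": CLASS_NAMES[int(result.cls[i, j])],
        })
    table = pd.DataFrame.from_records(
        records, columns=["lon", "lat", "row", "col", "ei", "class"]
    )
    counts = {name: int((table["class"] == name).sum()) for name in CLASS_NAMES}
    counts["off_grid"] = int((table["class"] == "off_grid").sum())
    on_grid = table[table["class"] != "off_grid"]
    counts["fraction_ei_positive"] = (
        float((on_grid["ei"] > 0).mean()) if len(on_grid) else np.nan
    )
    # object dtype keeps the class counts integral beside the fraction
    return table, pd.Series(counts, name="occurrences", dtype=object)


def write_ei_raster(result: AnnualResult, path: str | Path) -> None:
    """EI as a float raster (NaN outside the mask), with world file."""
    write_raster(np.where(result.mask, result.ei, np.nan), result.grid, path)


def write_class_raster(result: AnnualResult, path: str | Path) -> None:
    """Class codes 0–3 as a palette raster (legend white/blue/yellow/red)."""
    cmap = np.zeros((256, 3), dtype=np.uint8)
    cmap[:4] = CLASS_COLORS
    write_raster(result.cls.astype(np.uint8), result.grid, path, colormap=cmap)
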