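"""The ecoclimatic model core: growth indices, stresses, and the annual EI.

Weekly growth is the product of two trapezoidal responses: the temperature
index TI (zero at or beyond DV0/DV3, one on [DV1, DV2]) and the moisture
index MI (analogous on SM0..SM3).  The annual growth index GIA is 100×
the mean weekly growth index.

Four stresses accumulate weekly threshold exceedances linearly at their
tabulated per-week rates and are clamped at 100:

* cold stress — two mechanisms, combined by ``max``: weekly minimum
  temperature below TTCS, and weekly degree-days falling short of DTCS;
* heat stress — weekly maximum temperature above TTHS;
* dry stress — soil moisture below SMDS;
* wet stress — soil moisture above SMWS.

The Ecoclimatic Index is ``EI = GIA·(1−CS/100)(1−HS/100)(1−DS/100)(1−WS/100)``,
set to zero when the annual degree-day sum above DV0 falls short of PDD
(the growing-season gate), and clamped to [0, 100].

All reductions over the 52 weeks use an explicit fixed-order weekly loop so
results are bit-identical between gridded runs and a literal per-cell loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .climate_io import GridDefinition, MonthlyClimatology
from .params import ParameterSet
from .phenoclim import WEEK_DAYS, SoilMoistureSeries, WeeklyClimate, soil_moisture_balance, to_weekly

__all__ = [
    "SuitabilityClass",
    "AnnualResult",
    "temperature_index",
    "moisture_index",
    "growth_index",
    "annual_growth_index",
    "degree_days",
    "cold_stress",
    "heat_stress",
    "dry_stress",
    "wet_stress",
    "ecoclimatic_index",
    "run_grid",
    "run_cell",
]


class SuitabilityClass(IntEnum):
    """EI classes, ordered by increasing favourability."""

    UNSUITABLE = 0  # EI < 1
    MARGINAL = 1  # 1 <= EI < 10
    SUITABLE = 2  # 10 <= EI <= 20
    HIGHLY_SUITABLE = 3  # EI > 20


def _trapezoid(x: np.ndarray, lo: float, opt_lo: float, opt_hi: float, hi: float) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return np.interp(x, [lo, opt_lo, opt_hi, hi], [0.0, 1.0, 1.0, 0.0])


def temperature_index(t_avg, p: ParameterSet) -> np.ndarray:
    """Weekly temperature growth response in [0, 1]."""
    return _trapezoid(t_avg, p.DV0, p.DV1, p.DV2, p.DV3)


def moisture_index(sm, p: ParameterSet) -> np.ndarray:
    """Weekly soil-moisture growth response in [0, 1]."""
    return _trapezoid(sm, p.SM0, p.SM1, p.SM2, p.SM3)


def growth_index(t_avg, sm, p: ParameterSet) -> np.ndarray:
    """GI = TI × MI."""
    return temperature_index(t_avg, p) * moisture_index(sm, p)


def _weekly_sum(values: np.ndarray) -> np.ndarray:
    """Fixed-order sum over the leading (week) axis."""
    acc = np.zeros(values.shape[1:], dtype=np.float64)
    for w in range(values.shape[0]):
        acc = acc + values[w]
    return acc


def annual_growth_index(gi: np.ndarray) -> np.ndarray:
    """GIA = 100 × (Σ_w GI_w) / 52 for a (52, ...) GI array."""
    return 100.0 * _weekly_sum(np.asarray(gi, dtype=np.float64)) / 52.0


def degree_days(t_avg: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Weekly degree-days above DV0: max(0, t_avg − DV0) × days in week."""
    days = WEEK_DAYS.reshape((-1,) + (1,) * (np.ndim(t_avg) - 1))
    return np.maximum(0.0, np.asarray(t_avg, dtype=np.float64) - p.DV0) * days


def cold_stress(t_min: np.ndarray, dd: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Annual cold stress: max of the temperature and degree-day mechanisms.

    Both measure the same limiting process, so they combine by ``max``
    rather than sum (summing would double-count cold exposure).
    """
    cs1 = 100.0 * abs(p.THCS) * _weekly_sum(np.maximum(0.0, p.TTCS - np.asarray(t_min)))
    cs2 = 100.0 * abs(p.DHCS) * _weekly_sum(np.maximum(0.0, p.DTCS - np.asarray(dd)))
    return np.minimum(100.0, np.maximum(np.minimum(100.0, cs1), np.minimum(100.0, cs2)))


def heat_stress(t_max: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Annual heat stress from weekly t_max exceedance above TTHS."""
    hs = 100.0 * p.THHS * _weekly_sum(np.maximum(0.0, np.asarray(t_max) - p.TTHS))
    return np.minimum(100.0, hs)


def dry_stress(sm: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Annual dry stress from weekly soil-moisture deficit below SMDS."""
    ds = 100.0 * abs(p.HDS) * _weekly_sum(np.maximum(0.0, p.SMDS - np.asarray(sm)))
    return np.minimum(100.0, ds)


def wet_stress(sm: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Annual wet stress from weekly soil-moisture surplus above SMWS."""
    ws = 100.0 * p.HWS * _weekly_sum(np.maximum(0.0, np.asarray(sm) - p.SMWS))
    return np.minimum(100.0, ws)


def ecoclimatic_index(gia, cs, hs, ds, ws, annual_dd, p: ParameterSet) -> np.ndarray:
    """Combine growth and stresses into the annual EI in [0, 100]."""
    ei = (
        np.asarray(gia, dtype=np.float64)
        * (1.0 - np.asarray(cs) / 100.0)
        * (1.0 - np.asarray(hs) / 100.0)
        * (1.0 - np.asarray(ds) / 100.0)
        * (1.0 - np.asarray(ws) / 100.0)
    )
    ei = np.where(np.asarray(annual_dd) < p.PDD, 0.0, ei)
    return np.clip(ei, 0.0, 100.0)


def classify(ei) -> np.ndarray:
    """Map EI values to suitability class codes (0–3).

    Boundary policy: EI < 1 unsuitable; 1 ≤ EI < 10 marginal;
    10 ≤ EI ≤ 20 suitable; EI > 20 highly suitable.
    """
    ei = np.asarray(ei, dtype=np.float64)
    if np.any((ei < 0) | (ei > 100)):
        raise ValueError("EI outside [0, 100]")
    cls = np.zeros(ei.shape, dtype=np.int8)
    cls[ei >= 1.0] = SuitabilityClass.MARGINAL
    cls[ei >= 10.0] = SuitabilityClass.SUITABLE
    cls[ei > 20.0] = SuitabilityClass.HIGHLY_SUITABLE
    return cls


@dataclass
class AnnualResult:
    """Per-cell annual model outputs on a grid."""

    grid: GridDefinition
    mask: np.ndarray
    gia: np.ndarray
    cs: np.ndarray
    hs: np.ndarray
    ds: np.ndarray
    ws: np.ndarray
    annual_dd: np.ndarray
    ei: np.ndarray
    cls: np.ndarray  # SuitabilityClass codes, int8

    STRESSES = ("cs", "hs", "ds", "ws")

    def stress(self, name: str) -> np.ndarray:
        name = name.lower()
        if name not in self.STRESSES:
            raise KeyError(f"unknown stress {name!r}; expected one of {self.STRESSES}")
        return getattr(self, name)

    def to_dataset(self):
        import xarray as xr

        coords = {"lat": self.grid.lats, "lon": self.grid.lons}
        data = {
            k: (("lat", "lon"), getattr(self, k))
            for k in ("gia", "cs", "hs", "ds", "ws", "annual_dd", "ei")
        }
        data["cls"] = (("lat", "lon"), self.cls)
        data["mask"] = (("lat", "lon"), self.mask.astype(np.int8))
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["cell_size"] = self.grid.cell_size
        return ds

    def save(self, path) -> None:
        self.to_dataset().to_netcdf(str(path), engine="scipy")

    @classmethod
    def load(cls, path) -> "AnnualResult":
        import xarray as xr

        with xr.open_dataset(str(path), engine="scipy") as ds:
            ds = ds.load()
        lats = np.asarray(ds["lat"].values, dtype=float)
        lons = np.asarray(ds["lon"].values, dtype=float)
        if lats.size > 1:
            cell = float(lats[0] - lats[1])
        elif lons.size > 1:
            cell = float(lons[1] - lons[0])
        else:
            cell = float(ds.attrs.get("cell_size", 1.0 / 6.0))
        grid = GridDefinition(float(lons[0]), float(lats[0]), cell, lons.size, lats.size)
        return cls(
            grid=grid,
            mask=np.asarray(ds["mask"].values).astype(bool),
            gia=np.asarray(ds["gia"].values, dtype=np.float64),
            cs=np.asarray(ds["cs"].values, dtype=np.float64),
            hs=np.asarray(ds["hs"].values, dtype=np.float64),
            ds=np.asarray(ds["ds"].values, dtype=np.float64),
            ws=np.asarray(ds["ws"].values, dtype=np.float64),
            annual_dd=np.asarray(ds["annual_dd"].values, dtype=np.float64),
            ei=np.asarray(ds["ei"].values, dtype=np.float64),
            cls=np.asarray(ds["cls"].values).astype(np.int8),
        )


def run_weekly(wk: WeeklyClimate, sm: SoilMoistureSeries, p: ParameterSet) -> dict[str, np.ndarray]:
    """Compute all annual quantities from prepared weekly series."""
    gi = growth_index(wk.t_avg, sm.sm, p)
    gia = annual_growth_index(gi)
    dd = degree_days(wk.t_avg, p)
    annual_dd = _weekly_sum(dd)
    cs = cold_stress(wk.t_min, dd, p)
    hs = heat_stress(wk.t_max, p)
    ds = dry_stress(sm.sm, p)
    ws = wet_stress(sm.sm, p)
    ei = ecoclimatic_index(gia, cs, hs, ds, ws, annual_dd, p)
    return {
        "gia": gia, "cs": cs, "hs": hs, "ds": ds, "ws": ws,
        "annual_dd": annual_dd, "ei": ei,
    }


def run_grid(clim: MonthlyClimatology, p: ParameterSet) -> AnnualResult:
    """Full pipeline on a gridded climatology; masked cells stay masked."""
    wk = to_weekly(clim)
    sm = soil_moisture_balance(wk, p)
    out = run_weekly(wk, sm, p)
    mask = clim.mask
    for key in ("gia", "cs", "hs", "ds", "ws", "annual_dd", "ei"):
        out[key] = np.where(mask, out[key], np.nan)
    cls = np.zeros(mask.shape, dtype=np.int8)
    cls[mask] = classify(out["ei"][mask])
    return AnnualResult(grid=clim.grid, mask=mask, cls=cls, **out)


def run_cell(clim: MonthlyClimatology, p: ParameterSet) -> AnnualResult:
    """Run the pipeline on a single-cell climatology (e.g. a station)."""
    if clim.shape != (1, 1):
        raise ValueError(f"run_cell expects a 1x1-cell climatology, got {clim.shape}")
    return run_grid(clim, p)
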