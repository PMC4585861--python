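"""Synthetic tropical climatologies, scenario testbeds, and occurrences.

All randomness in the package lives here, behind an integer seed on
``numpy.random.default_rng``; the model core is fully deterministic.

The generator emulates the gross structure of tropical monthly
climatologies: temperature falling off with latitude at a fixed lapse,
a seasonal cycle whose amplitude grows with latitude (continentality) and
flips phase across the equator, monsoonal rainfall shaped by a von-Mises
annual profile normalised to the annual total, and fixed morning/afternoon
humidity baselines.  Per-cell noise adds spatial heterogeneity.  Defaults
describe a SE-Asia-like humid tropical domain: equatorial means within the
crop's ideal ranges (minimum 23 °C, maximum 32 °C), 2250 mm yr⁻¹ rain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .climate_io import GridDefinition, MonthlyClimatology
from .indices import AnnualResult, SuitabilityClass
from .phenoclim import MONTH_MIDS, YEAR_DAYS

__all__ = ["SyntheticSpec", "make_climatology", "make_gradient_testbed", "sample_occurrences"]

#: Latitude (degrees) at which the nominal seasonal amplitude applies.
AMPLITUDE_REF_LAT = 35.0
#: Day of year of the northern-hemisphere temperature maximum.
SUMMER_PEAK_DOY = 196.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic monthly climatology grid."""

    n_lat: int = 40
    n_lon: int = 40
    lat_origin: float = 9.75  # north-most cell-center latitude
    lon_origin: float = 95.0
    cell_size: float = 0.5  # coarse default keeps tests fast
    tmin_eq: float = 23.0  # equatorial monthly-mean minimum, °C
    tmax_eq: float = 32.0  # equatorial monthly-mean maximum, °C
    lapse: float = 0.15  # °C decline per degree of latitude
    amplitude: float = 6.0  # seasonal half-range at 35° latitude, °C
    annual_rain: float = 2250.0  # mm yr⁻¹
    monsoon_kappa: float = 1.0  # von-Mises concentration; 0 = uniform
    rain_peak_doy: float = 15.0
    rh0900: float = 90.0
    rh1500: float = 70.0
    noise_t: float = 1.5  # per-cell temperature anomaly sd, °C
    noise_rh: float = 3.0  # per-cell humidity anomaly sd, %
    noise_p: float = 0.15  # per-cell-month log-scale rain jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annual_rain < 0:
            raise ValueError("annual_rain must be non-negative")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if min(self.noise_t, self.noise_rh, self.noise_p) < 0:
            raise ValueError("noise levels must be non-negative")


def make_climatology(spec: SyntheticSpec) -> MonthlyClimatology:
    """Generate a deterministic (per seed) synthetic climatology."""
    rng = np.random.default_rng(spec.seed)
    grid = GridDefinition(
        spec.lon_origin, spec.lat_origin, spec.cell_size, spec.n_lon, spec.n_lat
    )
    lat = grid.lats[:, None] * np.ones((1, grid.n_lon))  # (nlat, nlon)

    phase = np.cos(2.0 * np.pi * (MONTH_MIDS - SUMMER_PEAK_DOY) / YEAR_DAYS)
    seasonal = (
        spec.amplitude * (lat / AMPLITUDE_REF_LAT)[None] * phase[:, None, None]
    )
    t_anom = rng.normal(0.0, spec.noise_t, lat.shape) if spec.noise_t else np.zeros(lat.shape)
    base_min = spec.tmin_eq - spec.lapse * np.abs(lat) + t_anom
    base_max = spec.tmax_eq - spec.lapse * np.abs(lat) + t_anom
    tmin = base_min[None] + seasonal
    tmax = base_max[None] + seasonal

    w = np.exp(
        spec.monsoon_kappa * np.cos(2.0 * np.pi * (MONTH_MIDS - spec.rain_peak_doy) / YEAR_DAYS)
    )
    w = w / w.sum()
    monthly = w[:, None, None] * np.ones((1,) + lat.shape)
    if spec.noise_p:
        jitter = np.exp(rng.normal(0.0, spec.noise_p, (12,) + lat.shape))
        monthly = monthly * jitter
        monthly = monthly / monthly.sum(axis=0, keepdims=True)
    ptotal = spec.annual_rain * monthly

    def rh_field(base: float) -> np.ndarray:
        anom = rng.normal(0.0, spec.noise_rh, lat.shape) if spec.noise_rh else 0.0
        return np.clip(np.broadcast_to(base + anom, (12,) + lat.shape), 0.0, 100.0).copy()

    return MonthlyClimatology(grid, tmin, tmax, ptotal, rh_field(spec.rh0900), rh_field(spec.rh1500))


#: Gradient-testbed recipe: an equator→35° strip with continental
#: seasonality so cold stress erodes suitability gradually poleward.
GRADIENT_SPEC = SyntheticSpec(
    n_lat=71,
    n_lon=4,
    lat_origin=35.0,
    lon_origin=100.0,
    cell_size=0.5,
    tmin_eq=23.0,
    tmax_eq=31.0,
    lapse=0.26,
    amplitude=16.0,
    annual_rain=2250.0,
    monsoon_kappa=0.0,
    noise_t=0.0,
    noise_rh=0.0,
    noise_p=0.0,
    seed=0,
)

#: Annual rainfall of the testbed's arid column (mm yr⁻¹).
ARID_RAIN = 200.0


def make_gradient_testbed() -> tuple[MonthlyClimatology, dict]:
    """A strip from the equator to 35° with a known class pattern.

    Under the oil-palm preset the humid columns run monotonically from
    highly suitable at the equator through suitable and marginal to
    unsuitable poleward (cold-stress/degree-day limited); the last column
    is arid (200 mm yr⁻¹) and dry-stress limited.  Returns the climatology
    and a dict describing the expected pattern.
    """
    clim = make_climatology(GRADIENT_SPEC)
    arid_col = GRADIENT_SPEC.n_lon - 1
    ptotal = clim.ptotal.copy()
    ptotal[:, :, arid_col] *= ARID_RAIN / GRADIENT_SPEC.annual_rain
    clim = MonthlyClimatology(
        clim.grid, clim.tmin, clim.tmax, ptotal, clim.rh0900, clim.rh1500, mask=clim.mask
    )
    expected = {
        "equator_row": GRADIENT_SPEC.n_lat - 1,  # lats run north→south
        "polar_row": 0,
        "humid_cols": list(range(arid_col)),
        "arid_col": arid_col,
        "equator_class": SuitabilityClass.HIGHLY_SUITABLE,
        "polar_class": SuitabilityClass.UNSUITABLE,
        "class_monotone_equatorward": True,
    }
    return clim, expected


def sample_occurrences(
    result: AnnualResult,
    n: int,
    class_filter: SuitabilityClass | int = SuitabilityClass.HIGHLY_SUITABLE,
    seed: int = 0,
) -> np.ndarray:
    """Sample *n* points uniformly over centers of cells in one class.

    Sampling is with replacement, so *n* may exceed the number of matching
    cells.  Raises ValueError if the class is empty on the valid mask.
    """
    sel = result.mask & (result.cls == int(class_filter))
    rows, cols = np.nonzero(sel)
    if rows.size == 0:
        raise ValueError(f"no valid cells in class {SuitabilityClass(int(class_filter)).name}")
    if n == 0:
        return np.empty((0, 2), dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rows.size, size=n)
    lons = result.grid.lons[cols[idx]]
    lats = result.grid.lats[rows[idx]]
    return np.column_stack([lons, lats])
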