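"""Monthly → weekly climate disaggregation and the soil-moisture bucket.

The model year has 365.25 days split into 52 weeks: weeks 1–51 are 7 days
and week 52 is 8.25 days, so annual totals close exactly without a stub
53rd week.  Months are equal twelfths of the year.

Temperatures and humidity are interpolated linearly (and periodically)
between month midpoints and sampled at week midpoints.  Monthly
precipitation is spread uniformly within each month and integrated over
each week's day span, which conserves the annual total by construction.

Soil moisture follows a single-bucket weekly water balance expressed as a
fraction ``sm`` of the soil water-holding capacity (default 100 mm).
Actual evapotranspiration is supply-limited — potential ET scaled by the
current moisture fraction::

    aet_w = k_et * max(0, t_avg_w) * (1 - rh_mean_w/100) * days_w * sm_{w-1}
    sm_w  = clip(sm_{w-1} + (precip_w - aet_w) / soil_capacity, 0, sm_cap)

With ``k_et = 1.0`` mm·°C⁻¹·day⁻¹ an ideal humid-tropical cell (26 °C,
RH 80 %, 2250 mm yr⁻¹ evenly spread) equilibrates at sm* ≈ 1.18, inside
the optimal moisture band, and potential ET at sm = 1 is ≈ 5.2 mm day⁻¹ —
a realistic tropical rate.  The supply limitation gives the balance a
unique attracting annual cycle, so the spin-up is insensitive to its
initial state.  The bucket may exceed nominal capacity up to ``sm_cap``
(default 2.5) so sustained surplus can drive wet stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate_io import MonthlyClimatology
from .params import ParameterSet

__all__ = [
    "WEEK_DAYS",
    "YEAR_DAYS",
    "WeeklyClimate",
    "SoilMoistureSeries",
    "to_weekly",
    "soil_moisture_balance",
]

YEAR_DAYS = 365.25
MONTH_DAYS = YEAR_DAYS / 12.0
#: Days in each of the 52 model weeks (week 52 absorbs the remainder).
WEEK_DAYS = np.array([7.0] * 51 + [YEAR_DAYS - 51 * 7.0])
_WEEK_EDGES = np.concatenate([[0.0], np.cumsum(WEEK_DAYS)])
WEEK_MIDS = 0.5 * (_WEEK_EDGES[:-1] + _WEEK_EDGES[1:])
MONTH_MIDS = (np.arange(12) + 0.5) * MONTH_DAYS
_MONTH_EDGES = np.arange(13) * MONTH_DAYS


@dataclass
class WeeklyClimate:
    """52-week series per cell; arrays shaped ``(52, ...)``."""

    t_min: np.ndarray
    t_max: np.ndarray
    t_avg: np.ndarray
    precip: np.ndarray  # mm per week
    rh_mean: np.ndarray  # %
    mask: np.ndarray | None = None


@dataclass
class SoilMoistureSeries:
    """Converged annual soil-moisture cycle (fraction of capacity)."""

    sm: np.ndarray  # (52, ...) moisture fraction
    cycles: int  # spin-up cycles used
    converged: np.ndarray  # per-cell flag


def _interp_periodic(monthly: np.ndarray) -> np.ndarray:
    """Sample a periodic piecewise-linear curve through month midpoints at
    week midpoints.  ``monthly`` is (12, ...); returns (52, ...)."""
    # wrap one month on each side for periodicity
    knots_t = np.concatenate([[MONTH_MIDS[-1] - YEAR_DAYS], MONTH_MIDS, [MONTH_MIDS[0] + YEAR_DAYS]])
    knots_v = np.concatenate([monthly[-1:], monthly, monthly[:1]], axis=0)
    idx = np.searchsorted(knots_t, WEEK_MIDS, side="right") - 1
    t0, t1 = knots_t[idx], knots_t[idx + 1]
    frac = ((WEEK_MIDS - t0) / (t1 - t0)).reshape((-1,) + (1,) * (monthly.ndim - 1))
    return knots_v[idx] * (1.0 - frac) + knots_v[idx + 1] * frac


def _apportion_precip(monthly: np.ndarray) -> np.ndarray:
    """Split monthly totals into weekly totals by day overlap (conservative)."""
    rate = monthly / MONTH_DAYS  # mm/day within each month
    cum = np.concatenate([np.zeros((1,) + monthly.shape[1:]), np.cumsum(monthly, axis=0)], axis=0)

    def cum_at(t: np.ndarray) -> np.ndarray:
        m = np.minimum((t / MONTH_DAYS).astype(int), 11)
        return cum[m] + rate[m] * (t - _MONTH_EDGES[m]).reshape((-1,) + (1,) * (monthly.ndim - 1))

    c = cum_at(_WEEK_EDGES[:-1])
    c_next = np.concatenate([c[1:], cum[-1:]], axis=0)
    return c_next - c


def to_weekly(clim: MonthlyClimatology) -> WeeklyClimate:
    """Disaggregate a monthly climatology to the 52-week model year."""
    t_min = _interp_periodic(clim.tmin)
    t_max = _interp_periodic(clim.tmax)
    rh = _interp_periodic(0.5 * (clim.rh0900 + clim.rh1500))
    precip = _apportion_precip(clim.ptotal)
    return WeeklyClimate(
        t_min=t_min,
        t_max=t_max,
        t_avg=0.5 * (t_min + t_max),
        precip=precip,
        rh_mean=rh,
        mask=clim.mask,
    )


def weekly_pet(wk: WeeklyClimate, p: ParameterSet) -> np.ndarray:
    """Potential evapotranspiration per week at unit soil moisture, mm."""
    days = WEEK_DAYS.reshape((-1,) + (1,) * (wk.t_avg.ndim - 1))
    return p.k_et * np.maximum(0.0, wk.t_avg) * (1.0 - wk.rh_mean / 100.0) * days


def soil_moisture_balance(
    wk: WeeklyClimate,
    p: ParameterSet,
    initial: float | None = None,
    tol: float = 1e-6,
    max_cycles: int = 100,
) -> SoilMoistureSeries:
    """Iterate the annual bucket cycle to a periodic steady state.

    Starts at ``initial`` (default ``SM1``) and repeats the 52-week year
    until the series changes by less than *tol* between cycles, up to
    *max_cycles*.  Non-convergence is flagged, not fatal.
    """
    pet1 = weekly_pet(wk, p)  # PET at sm = 1
    shape = wk.t_avg.shape[1:]
    sm0 = p.SM1 if initial is None else float(initial)
    sm = np.full(shape, sm0, dtype=np.float64)
    series = np.full((52,) + shape, sm0, dtype=np.float64)
    prev = np.full((52,) + shape, np.inf)
    cycles = 0
    # Each cell freezes at its own convergence cycle, so a cell's converged
    # series is identical whether it is run alone or inside a grid.
    active = np.ones(shape, dtype=bool)
    for cycles in range(1, max_cycles + 1):
        for w in range(52):
            new = np.clip(sm + (wk.precip[w] - pet1[w] * sm) / p.soil_capacity, 0.0, p.sm_cap)
            upd = np.where(active, new, series[w])
            series[w] = upd
            sm = upd
        diff = np.max(np.abs(series - prev), axis=0)
        active &= ~(diff < tol)
        if not active.any():
            break
        prev[...] = series
    return SoilMoistureSeries(sm=series, cycles=cycles, converged=~active)
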