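# Model description and design notes

## The ecoclimatic index

`ecoclim` implements a process-oriented (CLIMEX-style) annual suitability
model.  The premise is that a perennial species experiences, at every
location, a favourable season in which the population can grow and an
unfavourable season it must survive.  Both are scored from weekly climate:

* **Growth.** Each week carries a temperature index `TI` and a moisture
  index `MI`, both trapezoidal responses in [0, 1]: zero at or beyond the
  limiting thresholds (`DV0`/`DV3` for temperature, `SM0`/`SM3` for soil
  moisture), one across the optimal range (`DV1–DV2`, `SM1–SM2`), linear in
  between.  `TI` is evaluated on the weekly mean temperature, `MI` on the
  weekly soil-moisture fraction.  The weekly growth index is `GI = TI·MI`
  and the annual growth index is `GIA = 100·mean(GI)`.

* **Survival.** Four stresses accumulate weekly threshold exceedances
  linearly at a tabulated per-week rate, each clamped at 100:
  cold stress has two mechanisms combined by `max` — weekly minimum
  temperature below `TTCS` (rate `|THCS|`) and weekly degree-days short of
  `DTCS` (rate `|DHCS|`) — because both measure the same limiting process
  and summing would double-count; heat stress is weekly maximum temperature
  above `TTHS` at rate `THHS`; dry and wet stress are soil-moisture
  excursions below `SMDS` / above `SMWS` at rates `|HDS|` / `HWS`.

* **Combination.**
  `EI = GIA · (1−CS/100)(1−HS/100)(1−DS/100)(1−WS/100)`, forced to 0 when
  the annual degree-day sum above `DV0` falls short of `PDD` (a hard
  growing-season gate, which is how the degree-day requirement acts as a
  range limiter), then clamped to [0, 100].  Classification:
  EI < 1 unsuitable, 1–10 marginal, 10–20 suitable, > 20 highly suitable;
  the EI = 20 boundary belongs to "suitable" because "highly" is strictly
  above 20.  EI is classified at full double precision; nothing is rounded.

The bundled oil-palm preset (`src/ecoclim/data/oil_palm.toml`) carries the
published *Elaeis guineensis* parameterisation: growth optimal at 24–28 °C
between moisture fractions 0.6–1.6, cold stress below 15 °C, heat stress
above 36 °C, dry stress below 0.4, wet stress above 2, and a 1500 °C·day
annual heat requirement.  Rates are stored signed as conventionally printed
(cold/dry rates negative); kernels take magnitudes, so the table can be
transcribed verbatim.

## The model year

365.25 days in 52 weeks: weeks 1–51 have 7 days and week 52 has 8.25, so
annual totals close exactly without a 53rd stub week.  Months are equal
twelfths of the year.  Temperatures and humidity are interpolated linearly
and periodically between month midpoints and sampled at week midpoints —
monotone, overshoot-free, and reproducible.  Monthly precipitation is
treated as a uniform daily rate within the month and integrated over each
week's span, which conserves the annual total by construction.  Degree-days
and evapotranspiration use the per-week day counts, including week 52's
8.25 days.

## Soil-moisture bucket

Soil moisture is a single bucket expressed as a fraction `sm` of the soil
water-holding capacity (default 100 mm).  Actual evapotranspiration is
supply-limited: potential ET scaled by the current moisture fraction,

```
aet_w = k_et · max(0, t_avg_w) · (1 − rh_mean_w/100) · days_w · sm_{w−1}
sm_w  = clip(sm_{w−1} + (precip_w − aet_w)/capacity, 0, sm_cap)
```

Choices that matter:

* `k_et = 1.0 mm·°C⁻¹·day⁻¹` was calibrated once against the crop's ideal
  water regime: an ideal humid-tropical cell (26 °C, RH 80 %, 2250 mm yr⁻¹
  evenly spread — the middle of the reported ideal 2000–2500 mm range)
  must equilibrate inside the optimal moisture band `[SM1, SM2]`.  The
  supply-limited rule has the closed-form equilibrium
  `sm* = P / (k_et·T·(1−RH/100)·days)`, giving `sm* ≈ 1.18` for that cell,
  and a potential ET at `sm = 1` of ≈ 5.2 mm day⁻¹, a realistic humid-
  tropics rate.  `k_et` is exposed in the parameter file.
* Scaling ET with `sm` (rather than subtracting a moisture-independent
  PET) gives the balance a unique, strongly attracting annual cycle: the
  spin-up provably forgets its initial state, wet climates settle at an
  interior equilibrium instead of pinning at the bucket ceiling, and dry
  climates decay exponentially to an empty bucket.
* `sm_cap = 2.5` exceeds `SM3 = 2` so sustained surplus can push the bucket
  above the wet-stress threshold; fractions above 1 represent surplus
  beyond nominal capacity, which is meaningful on the `SM` scale
  (`SM2 = 1.6`, `SM3 = 2`).
* Spin-up starts at `SM1`, iterates annual cycles until the series changes
  by < 1e-6 (at most 100 cycles; non-convergence is flagged, not fatal),
  and freezes each cell at its own convergence cycle so a cell's converged
  series is bit-identical whether it is run alone or inside a grid.

## Numerical choices

* All arithmetic in double precision.  Weekly reductions (stresses, GIA,
  annual degree-days) use an explicit fixed-order 52-step loop, vectorized
  across cells, so gridded results are bit-identical to a literal per-cell
  loop; tests exploit this for exact oracle comparisons.
* Trapezoids are evaluated with `np.interp` on the four thresholds; values
  at the limiting thresholds are exactly 0, on the plateau exactly 1.
* Grid geometry is WGS84 lon/lat, cell-center registered, latitudes stored
  north→south.  Cell areas use the spherical-zone formula
  `A = R²·Δλ·(sin φ_top − sin φ_bottom)` with R = 6371.0088 km; summed over
  a global grid this reproduces the sphere area to 1e-6 relative.
* Scenario deltas shift both temperatures equally (preserving
  `t_min ≤ t_max`), scale precipitation multiplicatively, and clamp
  perturbed humidity to [0, 100].

## Synthetic data: what it emulates, and what it does not

All randomness lives in `ecoclim.synthetic` behind an integer seed; the
model core is deterministic.  The generator produces tropical-like monthly
climatologies: temperature declining with latitude at a fixed lapse, a
seasonal cycle whose amplitude grows with latitude and flips phase across
the equator, von-Mises-shaped monsoonal rainfall normalised to the annual
total, fixed morning/afternoon humidity levels, and per-cell Gaussian
noise.  Two fixed configurations serve as study conditions:

* **Tropical grid** (default `SyntheticSpec`): a 40×40, 0.5° SE-Asia-like
  domain spanning ±10° latitude, equatorial monthly means 23/32 °C
  (within the crop's reported ideal ranges), 2250 mm yr⁻¹, RH 90/70 %,
  noise 1.5 °C.  Used for scenario-direction experiments (e.g. +4 °C).
* **Gradient testbed**: a noise-free 0–35° strip (0.5°, four columns) with
  continental seasonality — amplitude growing to 16 °C at 35° over a
  0.26 °C/degree lapse — so cold stress erodes suitability gradually and
  the humid columns traverse all four classes monotonically with latitude;
  the fourth column receives 200 mm yr⁻¹ and is dry-stress limited.  The
  continentality is deliberate: with the hard 1500 °C·day gate, a
  low-seasonality maritime profile would jump from suitable straight to
  unsuitable at the gate latitude, leaving no marginal band to test.

The generator does **not** emulate real gridded climatologies: no
topography, coastlines, land-sea contrast, interannual variability, or GCM
spatial change patterns.  Passing tests on synthetic data therefore
demonstrate the correctness and qualitative behaviour of the model kernels
and pipeline — not agreement with any published map, which would require
the original 10-arcmin climatology and occurrence records as inputs.  When
those are supplied (NetCDF grids or station CSVs), the same pipeline runs
unchanged.

## Problem sizes

Default experiment sizes — 40×40 scenario grids, a 71×4 gradient strip,
10,000-series fuzz ensembles, 1,000-series oracle comparisons — were chosen
so that each question (directionality, class structure, bound-probing,
exactness) is answered with comfortable margin while a full run of the
suite and the acceptance script completes in seconds.

## Known limitations

* The hydrology is a one-layer bucket: no runoff, soil texture, snow, or
  irrigation; humid cells never water-log realistically, so wet stress is
  conservative.
* Interaction stresses (hot-dry, cold-wet, …), irradiance, and diapause
  terms of the full commercial formulation are not modelled; no published
  parameter values exist for this species.
* Stress accumulation is linear in exceedance and week-additive; any
  compounding behaviour of the original closed-source implementation is
  not reproduced.  Results are expected to match published maps in class
  pattern, not bit-for-bit.
* The degree-day gate is hard; a tapered alternative would smooth class
  boundaries at the cold margin.
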