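# ecoclim

Mechanistic, CLIMEX-style ecoclimatic suitability modelling for perennial
crops on gridded monthly climatologies, with a published oil-palm
(*Elaeis guineensis*) parameter preset.  Built for crop/biogeography
researchers who want an open, tested pipeline to ask how climate — and
climate change scenarios — bound where a species can establish and thrive.

## The model

For every grid cell, monthly climate (T_min, T_max, precipitation,
RH at 09:00 and 15:00) is disaggregated to a 52-week year, a soil-moisture
bucket is spun up to its periodic steady state, and each week is scored by
trapezoidal growth responses: a temperature index TI (0 outside
[DV0, DV3], 1 on [DV1, DV2]) and a moisture index MI (analogous on
SM0..SM3).  The annual growth index is

    GIA = 100 · mean_w( TI_w · MI_w )

Four survival stresses accumulate weekly threshold exceedances linearly at
per-week rates and clamp at 100: cold (t_min below TTCS, or weekly
degree-days short of DTCS — the larger of the two mechanisms), heat (t_max
above TTHS), dry and wet (soil moisture beyond SMDS / SMWS).  The annual
Ecoclimatic Index combines them,

    EI = GIA · (1−CS/100)(1−HS/100)(1−DS/100)(1−WS/100),   EI := 0 if DD_annual < PDD

where DD_annual is the heat sum above DV0 and PDD the minimum annual
requirement.  EI ∈ [0, 100] classifies as unsuitable (< 1), marginal
(1–10), suitable (10–20) or highly suitable (> 20).  See
`docs/methods.md` for the full formulation, the bucket hydrology, and
every default.

## Worked example

A synthetic equator→35° gradient strip (three humid columns, one arid)
run under the bundled oil-palm preset, then a +2 °C scenario:

```python
import numpy as np
import ecoclim as ec

p = ec.oil_palm_preset()                      # DV0=19, SM1=0.6, PDD=1500, ...
clim, expected = ec.make_gradient_testbed()
res = ec.run_grid(clim, p)

print(ec.area_table(res).round(1))
warm = ec.run_grid(ec.apply_scenario_delta(clim, dT=2.0), p)
print(ec.combined_area_table({"current": res, "plus2C": warm}).round(1))
print("total change in cold stress:",
      round(float(np.nansum(ec.stress_change(res, warm, "cs").delta)), 1))
```

prints

```
unsuitable         308156.9
marginal            57828.8
suitable            59519.7
highly_suitable    398404.8
total              823910.1
          unsuitable  marginal  suitable  highly_suitable     total
scenario
current     308156.9   57828.8   59519.7         398404.8  823910.1
plus2C      260099.0   64395.2   58334.2         441081.8  823910.1
total change in cold stress: -2721.0
```

Reading this: the equatorial end of the strip is highly suitable
(EI = 100 there); suitability degrades poleward through all four classes
as cold stress grows and the degree-day requirement bites.  Areas are km²
from the spherical cell-area formula, and the `total` column is identical
across scenarios — the land mask is fixed, only classes move.  Warming
this cold-limited strip by 2 °C relieves cold stress (negative total
change) and moves area out of `unsuitable` into the suitable classes; on a
hot tropical domain the same operation lowers EI instead (see the scenario
tests).  Occurrence validation works the same way:

```python
pts = ec.sample_occurrences(res, 23, seed=1)   # 23 points from highly suitable cells
table, summary = ec.overlay_occurrences(pts, res)
print(summary)                                  # highly_suitable 23, fraction_ei_positive 1.0
```

## Command line

```sh
ecoclim synth --out base.nc --seed 1              # synthetic tropical climatology
ecoclim run --climate base.nc --out runs \
    --scenario 2100_A2:2100:4.0:0.9               # label:year:dT:Pscale[:dRH]
ecoclim compare runs/result_current.nc runs/result_2100_A2.nc --out cmp --stress hs
ecoclim validate runs/result_current.nc occurrences.geojson
```

`run` writes, per scenario, an EI raster (TIFF + world file), a
colour-tabled class raster, a result NetCDF, a scenario×class area CSV,
and a run log recording parameters, their hash, seed, and version.  Real
gridded climatologies enter as NetCDF (one file or one per variable) or
single-station monthly CSVs; future climates enter either as replacement
climatologies or as delta perturbations.

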