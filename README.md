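# nichetrack

Plankton range shifts versus the velocity of climate change in the
North-East Atlantic and North Sea.

Marine plankton surveys such as the Continuous Plankton Recorder (CPR)
record taxon counts along commercial shipping routes for decades.  A
central question for climate-change biogeography is whether each taxon's
range simply tracks its thermal envelope as isotherms move poleward
(**niche conservatism**) or lags behind it (**niche plasticity**).
`nichetrack` implements the full analysis chain for that question on
tow-sample tables and gridded monthly SST, for the domain 45–64° N,
20° W–8° E over 1954–2013:

1. **Gridding** — samples are pooled into twelve 5-year × calendar-month
   sets, counts are log(n+1)-transformed, vertically migrating genera are
   restricted to 18:00–06:00 local solar time, each monthly set is
   interpolated by ordinary kriging (automatic spherical/exponential/
   gaussian variogram selection by weighted least squares, Cressie-style
   weights N/h²) onto a 0.5° grid, and monthly fields are averaged into
   5-yearly maps.  SST is treated identically.
2. **Isotherm tracking** — for each 0.5° longitude a cubic polynomial of
   SST on latitude locates the 11, 12 and 13 °C isotherms; their mean
   latitude per period measures the velocity of climate change.
3. **Range metrics** — per taxon and period: the percentage of the kriged
   population north of each isotherm (with sub-cell linear splitting), the
   median range latitude, and a population index (grid mean).
4. **Inference** — Pearson correlation of the (z-scored) percent-north
   series with the isotherm's mean latitude, with the effective sample size
   re-estimated for serial autocorrelation (Chelton-style adjustment in the
   Pyper–Peterson form, 1/n_eff = (1/n)·Σ ρₓ(j)ρᵧ(j), J = ⌊n/5⌋).  A
   significant one-sided *negative* correlation at an isotherm indicates
   niche plasticity.  The layer also computes abundance–SST correlation
   signs, range displacements in km (1° latitude = 111 km) and per-decade
   velocities, and the seasonal peak Sₚ = Σ M·x_M / Σ x_M with its shift
   over the warming period.
5. **Synthetic data** — a generator producing HadISST-like SST histories
   (cooling 1959–1984, warming 1984–2008, latitudinal gradient, seasonal
   cycle) and CPR-like tows for taxa with *known* niche behaviour, so the
   entire pipeline can be validated against analytic ground truth: with
   gradient g and trend rate τ, isotherms and conservative ranges move
   north at τ/g degrees per year while plastic ranges stay put.

## Worked example

The bundled demonstration simulates two taxa with opposite niche behaviour
and runs the chain end to end (about a minute on one CPU):

```sh
nichetrack demo --out scratch/demo
```

Report (abridged):

```
               taxon      verdict  n_isotherms_negative  movement_cooling_km  movement_warming_km
conservative_tracker conservative                     0              -155.0                220.8
    plastic_resident plastic_all3                     3                -3.8                  2.0
```

with isotherm movement in the warming window of 219.9/220.7/221.4 km for
the 11/12/13 °C isotherms (≈ 88 km per decade over the 2.5-decade span).
The temperature-anchored taxon shows no negative percent-north correlation
(it moves with the isotherms: 220.8 km ≈ the isotherm shift), while the
latitude-anchored taxon is flagged plastic at all three isotherms
(r ≈ −0.99) and its range median moves only 2 km.

The same pipeline runs on real inputs via a YAML config pointing at a tow
CSV (`taxon,latitude,longitude,datetime_utc,count`) and a long-format SST
table (`time,lat,lon,sst`); see `examples/demo.yaml` for the schema and
the `simulate`, `grid`, `isotherms`, `analyze` and `report` verbs for
stage-wise runs from cached intermediates.

A packaged reference table of published range-shift estimates for 35 taxa
supports fleet-level summaries without the multi-decade survey archives:

```sh
nichetrack report
```

prints, among other statistics, a mean poleward movement of ~54 km per
decade across the 35 taxa in the warming period, 3 taxa moving more than
100 km south versus 18 moving more than 100 km north, and a largest
between-taxon contrast of ~905 km.

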