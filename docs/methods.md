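# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `nichetrack`, and what the synthetic validation does and
does not demonstrate about real survey data.

## Domain and period scheme

All analysis happens on the box 45–64° N, 20° W–8° E with 0.5° cells whose
centres sit at the quarter-degree points (38 × 56 cells); the box edges are
cell boundaries and cells are half-open `[lo, hi)`.  Time is divided into
twelve 5-year periods, 1954–1958 … 2009–2013.  Kriging is applied per
(period, calendar month) because spatial structure cannot be assumed
stable over six decades; the 5-yearly field is the cell-wise mean of the
available monthly fields, with the contributing month count recorded.

Distances are computed on a local equirectangular projection about the
domain centre: 1° latitude = 111.0 km, 1° longitude = 111.0·cos(54.5°) km.
At this extent the distortion is irrelevant next to variogram uncertainty.
The same 111.0 km/degree constant converts range-median displacements to
km (so 10° = 1,110 km); both constants are configurable.

## Gridding and kriging

* Counts are transformed log(n+1) before any spatial statistics.  The base
  (natural by default, base-10 by option) rescales all transformed values
  by one constant, so percent-north, median-latitude and correlation
  results cannot depend on it.
* For the vertically migrating genera (e.g. *Metridia*, *Pleuromamma*)
  only samples taken 18:00–06:00 local solar time (UTC + longitude/15 h)
  are used; near-surface daytime counts of diel migrators are not
  representative of the population.
* A (period, month, taxon) bucket is kriged only when it has at least 30
  samples; sparser buckets are skipped and logged, never silently
  interpolated.  The threshold is a variogram-stability choice.
* The empirical semivariogram uses 15 distance bins to a cutoff of one
  third of the bounding-box diagonal (the common gstat default);
  zero-distance pairs are excluded and duplicate coordinates are averaged
  beforehand (they would make the kriging system singular).
* Three candidate families — spherical, exponential, gaussian, all in the
  practical-range parameterisation — are fitted by weighted least squares
  with Cressie-style weights N_j/h_j², and the family with the smallest
  weighted SSE wins.  Matérn-class models are deliberately omitted.
* The fitted nugget is floored at 0.1% of the sill.  A zero-nugget model
  (the gaussian family especially) makes the ordinary-kriging matrix
  ill-conditioned and can produce order-of-magnitude extrapolation
  artefacts at the grid edges; the floor is far below any realistically
  estimated nugget and does not affect explicitly constructed models, for
  which nugget-0 kriging remains an exact interpolator.
* Ordinary kriging solves the standard augmented system with a Lagrange
  multiplier; the factorised system is reused for all 2,128 cell centres.
  Weights sum to one at every prediction point (checked to 1e-9 in tests),
  predictions are translation-equivariant in the value scale, and a
  spatially constant bucket short-circuits to a constant field.

## Isotherm tracking

Each longitude column of a 5-yearly SST field is fitted with a cubic
polynomial of SST on latitude (a column with fewer than six valid cells
falls back to a lower degree).  The isotherm latitude is a real root of
`poly − temp` inside the column's latitude span at which the fitted SST
decreases northwards — the physically meaningful poleward front; if
several such crossings exist their median is taken, and a column with none
is missing.  Degree 3 captures front curvature without oscillation on ≤ 38
support points; the degree is configurable.  The per-period mean isotherm
latitude averages the non-missing columns.

## Range metrics

* **Percent north** sums cell values column by column, splitting the cell
  containing the isotherm linearly by the fraction of the cell north of
  it (this removes grid-resolution bias); columns with a missing isotherm
  are excluded from numerator and denominator alike.  Implemented as exact
  column sums rather than a smoothed regression of cumulative mass — an
  explicit design choice where the smoothing alternative is ambiguous.
* **Median range latitude** accumulates row totals south→north and
  interpolates linearly inside the crossing row's cell.
* **Population index** is the mean of the kriged values over non-missing
  cells.
* **Per-decade velocity** divides a displacement by the inclusive calendar
  span of the endpoint periods: 1984–1988 → 2004–2008 spans
  (2008 − 1984 + 1)/10 = 2.5 decades.  This is the only convention
  consistent with the published isotherm displacement/velocity pairs the
  package reproduces (e.g. 377.40 km ↦ 150.96 ≈ 151 km per decade).

## Inference

* The percent-north series is z-scored (sample s.d.) per isotherm before
  correlation; this changes nothing about r or p but matches how such
  series are reported.
* The effective sample size for a correlation between two autocorrelated
  series uses the cross-correlation form
  1/n_eff = (1/n)·Σ_{j=−J..J} ρₓ(j)ρᵧ(j) with sample autocorrelations and
  truncation J = ⌊n/5⌋ (the Pyper–Peterson 1998 implementation of the
  Chelton-style adjustment; the alternative integral-timescale variant is
  not used).  n_eff is clipped to (2, n].  For two AR(1) series with
  φ = 0.5 the ratio n_eff/n converges to (1−φ²)/(1+φ²) = 0.6, which the
  tests verify by simulation.
* The plasticity test is one-sided (the hypothesis is directional — the
  proportion north *falls* as the isotherm moves north), using a t
  statistic with n_eff − 2 degrees of freedom; α = 0.05, no
  multiple-testing correction (per-test reporting).  Simulated type-I
  error at n = 12 is ≈ 0.04: the clipping n_eff ≤ n makes the test
  slightly conservative, never anticonservative.
* Abundance–SST correlations are two-sided (both signs are meaningful),
  tested over the full twelve periods and over the five warming-window
  periods, with the adjusted sample size for consistency; the sign of the
  most significant window is reported when either rejects.
* Verdicts: significant negative correlations at all three isotherms →
  `plastic_all3`; at none → `conservative`; otherwise `plastic_partial`.
* The seasonal peak Sₚ = Σ M·x_M / Σ x_M uses monthly mean abundance.
  Profiles with both spring and autumn blooms are reduced to the most
  populous peak by a concrete rule: a second local maximum ≥ 3 months away
  (circularly) reaching ≥ 60% of the global maximum marks the profile
  bimodal, and the weighted mean is then restricted to months within ±3
  (circular) of the global maximum and wrapped back into [1, 12].  The
  thresholds are explicit stand-ins for the qualitative
  "most populous peak" notion.
* The cross-taxon phenology-versus-movement correlation uses ordinary
  degrees of freedom (taxa are exchangeable units, not a time series) and
  requires at least four taxa per group.

## Synthetic generator

The generator defines the validation conditions:

* **SST**: T = 12 °C at 54.5° N minus 0.4 °C per degree latitude, plus a
  piecewise-linear trend (flat 1954–1959, −0.03 °C/yr 1959–1984,
  +0.04 °C/yr 1984–2008, flat after), a seasonal cosine of amplitude
  1 °C peaking in August (N-Atlantic late-summer maximum), and white
  measurement noise of 0.2 °C per monthly cell.  With gradient g and trend
  rate τ every isotherm moves at τ/g degrees per year — here 2.0° ≈ 222 km
  across the warming window, i.e. ≈ 88 km per decade, the same order as
  the observed N-Atlantic isotherm velocities.
* **Tows**: 2,000 per year by default (≈ 830 per 5-year × month bucket),
  uniformly scattered (or along straight simulated transects), with UTC
  times uniform over the day and year, so the night filter removes about
  half the samples of a diel taxon.  Expected log abundance is a baseline
  (3.0 log-units) plus a Gaussian seasonal factor (width 1.5 months) plus
  the niche factor — Gaussian in (SST − optimum)/1.0 °C for conservative
  taxa, Gaussian in (lat − home)/2.5° for plastic taxa; counts are
  round(exp(draw) − 1) clipped at zero with 0.5 log-units of additive
  Gaussian noise (additive on the log scale because the pipeline analyses
  log(n+1) values).  Diel migrators have daytime availability multiplied
  by 0.2.  The niche widths keep each taxon's support inside the domain
  throughout the trend history, so range medians are not truncated.
* The coastal-exclusion flag is a no-op for the open-ocean default box (no
  coastline model); sampling density is chosen for statistical adequacy —
  the generator makes no claim of fidelity to real route networks, ocean
  circulation or species interactions.

Passing the end-to-end recovery test therefore shows that the pipeline
correctly distinguishes temperature-anchored from latitude-anchored ranges
and measures their displacement *under these idealised conditions*:
unbiased spatial sampling, a separable and stationary-in-structure SST
field, and noise that is independent across tows.  It does not validate
behaviour under route-biased sampling, taxon misidentification drift, or
non-thermal drivers, all of which real survey data contain.

## Degenerate inputs and tie-breaks

Constant series raise errors (z-scores, autocorrelations and correlations
are undefined); all-missing columns and zero-mass fields raise; sparse
buckets are skipped and logged; duplicate kriging locations are averaged
with a logged warning; |r| = 1 maps to a zero/one p-value rather than a
division error.  Runs are deterministic given seeds, and the statistical
stage re-run from serialized intermediate grids reproduces the report
byte-for-byte.

## Problem sizes

The bundled demonstration uses 2,000 tows per year × 60 years × 2 taxa and
a 1° synthetic SST grid (≈ 430 variogram fits and kriging solves); the
calibration suites use 200 simulated series pairs (n = 200) for the
effective-sample-size checks and 2,000 replicates (n = 12) for the type-I
rate.  These sizes give Monte-Carlo error comfortably below the tolerances
asserted while keeping a full run in the minutes range on one CPU.

## Known limitations

* No universal or co-kriging, anisotropy, or kriging-variance reporting;
  the variogram family set is fixed at three.
* Percent-north is computed from column sums, not from a fitted smoother
  of cumulative mass; on coarse grids with very patchy fields the two can
  differ slightly.
* The effective-sample-size estimator is itself noisy at n = 12; its
  clipping makes the plasticity test mildly conservative.
* Phenology uses the spatial-mean monthly field as the monthly abundance
  x_M; months skipped for sparse sampling contribute zero mass.
* The equirectangular distance approximation and the fixed 111 km/degree
  constant are adequate for this domain but not for basin-scale or
  high-latitude extensions.
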