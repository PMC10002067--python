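# Methods

## Regression calibration

The four correction forms are ordinary least squares with the *sensor* as
the response and the reference concentration (plus, optionally, temperature
and/or relative humidity) as regressors:

```
slr:       PM_sensor = a·PM_ref + b
mlr_t:     PM_sensor = c·PM_ref + d·T + e
mlr_rh:    PM_sensor = f·PM_ref + g·RH + h
mlr_t_rh:  PM_sensor = i·PM_ref + j·T + k·RH + l
```

Correction is the algebraic inversion of the fitted equation for `PM_ref`
(e.g. `(PM_sensor − j·T − k·RH − l)/i`), not a refit of
reference-on-sensor. The two orientations coincide on noiseless data but
differ under noise; the package implements the orientation the equations
define, because the sensor is the instrument being modelled. A leading
coefficient within `1e-12` of zero makes the equation non-invertible and
raises an error. Negative corrected concentrations are floored at 0
(physical non-negativity); the count of floored samples is logged and, on
the estimator, exposed as `n_floored_`.

Fitting uses `numpy.linalg.lstsq`; on data generated exactly by any of the
four forms, recovery is exact to 1e-8 relative (asserted in tests).
Zero-variance regressors are rejected by name rather than silently
producing a rank-deficient solve.

**Co-averaging.** Series from instruments with different native resolutions
are averaged onto common time bins before fitting: 1-minute bins by default
for sensor/reference co-location, 24-hour bins for the gravimetric chain
(filter weighing integrates over a day). Bins are paired only where both
instruments contribute; each sample falls in the nearest bin, i.e. within
half a bin width.

**Gravimetric chain.** Optical reference instruments are themselves
corrected against filter gravimetry at daily resolution with the identical
SLR machinery; unpaired dates are an error listing the dates, never a
silent inner join.

## κ-Köhler humidity correction

The wet/dry particle-mass ratio is modelled as

```
GF(RH) = 1 + (ρw/ρp) · κ / (1/aw − 1)
```

with water activity `aw = RH/100`. RH enters as a fraction: this is the
standard water-activity convention, and the only reading under which
`aw ≤ 1` holds across the RH domain. Defaults: water density
`ρw = 1 g cm⁻³`; particle density `ρp = 1.65 g cm⁻³` (a typical urban
aerosol assumption, overridable). `aw` is capped at 0.95 so the
`1/aw − 1 → 0` pole near saturation cannot blow up the correction; above
the cap the growth factor is held at its RH = 95 % value. The dry limit
RH → 0 gives exactly GF = 1, and GF is monotone non-decreasing in RH for
any κ ≥ 0 (property-tested).

**Humidogram and κ estimation.** The humidogram is the per-RH-bin mean of
the sensor/reference ratio; defaults are 2 % RH bins with at least 10
samples per retained bin, and at least 3 surviving bins. Since `GF − 1` is
linear in κ, the estimate is the closed-form through-origin OLS slope of
`(ratio − 1)` on the basis `(ρw/ρp)/(1/aw − 1)` evaluated at bin centers.
Fitting on binned means rather than raw points makes the estimate robust to
concentration-dependent noise and weights the RH axis evenly. A negative
unconstrained estimate is floored at 0 and kept in the diagnostics. Note a
small positive discretisation bias is inherent to binning a convex curve
(the bin mean of GF exceeds GF at the bin center); with 2 % bins it is well
under 1 % and far below sampling noise.

**Method selection.** The κ correction is only appropriate when the
humidogram actually rises with RH in the characteristic convex
("exponential") shape. The diagnostic compares the R² of the κ-form fit —
computed about the bin mean, so a flat ratio model scores exactly 0 —
against a margin (default 0.1 in R²) and recommends `kohler` only above it,
otherwise `mlr`. A straight-line fit in RH is reported alongside for
inspection but does not drive the recommendation: a line can track much of
the κ-curve over a moderate RH range, so "beats linear by 0.1" would reject
genuinely hygroscopic humidograms. The recommendation is advisory and never
auto-applied.

## Dose and emission models

Inhaled dose over a trip is `D = PM_out × I/O × t × IR` (µg), exactly
multilinear in its four factors. Two evaluation modes exist: *measured
indoor* (cabin concentration measured directly; used with I/O = 1 to
summarise instrumented bus campaigns) and *derived indoor* (outdoor
concentration × configured I/O ratio; the deployment mode when only
roof-mounted outdoor sensors exist). Default I/O ratios: bus 2.10 (PM2.5)
and 2.50 (PM10), car 0.96/0.93, and 1.0 for motorcycle, bicycle and
walking. Default inhalation rates (m³ h⁻¹): bicycle 1.41, car 0.71, bus
0.76, motorcycle 0.94, walking 1.15. Travel times for modes without
measured times must be supplied explicitly — the table builder never
guesses them.

Per-passenger emission is `E = EF × d / p` (g) over an emission-factor set
keyed (vehicle, fuel, Euro standard), with default occupancy 50 for buses
and 1 for cars and motorcycles; electric vehicles carry EF = 0 by
invariant. The engine stores full precision everywhere; presentation
rounding is half-up at the rendered precision only. When validating against
externally published tables whose inputs were themselves rounded,
cell-level agreement is asserted to within one unit in the last printed
digit — the tightest bound rounded-input propagation supports.

Trips are two-way: stored travel times and distances are round-trip totals.
Records carrying the `excluded` quality flag (and whole excluded periods)
are skipped by every aggregation, with a logged reason, never silently
dropped.

## Mapping and routing

Maps are equal-area metric grids (default 100 m cells) of per-cell
arithmetic means over ok-flagged, geolocated records. The projection is a
local equirectangular mapping centred on the data bounding box; at city
scale the metric error is far below a cell width, and the implementation
needs no external projection machinery. Cell counts are conserved by
construction (asserted as an invariant).

Routing is Dijkstra over non-negative edge costs: `fastest` uses travel
time; `avoid_pollution` uses the edge-wise inhaled dose
(concentration × I/O × time × IR). Clean edges are floored at a cost of
1e-9 so path ordering stays well-defined; the floor is far below any
physically meaningful dose. Ties in total cost break deterministically on
the lexicographically smallest node-id sequence (the search heap orders
`(cost, path)` tuples). Identical origin and destination return an empty
path with zero totals; unreachable destinations raise an error. Edge
concentrations are bound from the grid cell containing the edge midpoint,
with a configurable background for uncovered cells. Correctness is checked
against exhaustive simple-path enumeration on random graphs of up to 8
nodes. Because the dose cost is positively homogeneous in concentration,
uniformly scaling the field never changes the chosen path (tested).

## Synthetic data

The generators emulate the two campaign types the pipeline consumes.

*Ambient field*: concentrations follow a stationary AR(1) process on the
log scale (positivity guaranteed; log-persistence 0.98 per 1-minute step
and stationary log-SD 0.5 by default, giving the right order of short-term
persistence and dynamic range for urban background PM); PM10 is PM2.5 plus
an independent coarse log-AR(1) component, so the fine fraction never
exceeds the total. Temperature and RH are 24-hour sinusoids plus Gaussian
jitter (RH 55 ± 30 %, clipped to [5, 95] %; T 20 ± 5 °C), RH peaking at
night in anti-phase with temperature. Defaults describe a 14-day campaign
at 1-minute resolution with PM2.5/PM10 base levels of 8/20 µg m⁻³.

*Sensor response*: `gain × true × GF(RH; κ, ρp) + offset`, then
multiplicative and/or additive Gaussian noise, truncated at zero. This is
the exact forward model of the correction, so correcting with the
generating κ inverts the confounding to machine precision in the noise-free
limit (tested to 1e-9 relative).

*Trips*: the ambient field is sampled at 1 Hz along a georeferenced
polyline at constant speed; the cabin stream is `io_true × outdoor` plus
resuspension spikes — Poisson-timed events decaying exponentially with a
60 s time constant, mimicking the short-lived peaks passenger movement and
door openings produce.

All generators are pure functions of (scenario, seed). Co-location studies
must use distinct seed streams for the ambient process and the sensor
noise; sharing one seed correlates the noise with the concentration
innovations and biases regression diagnostics.

What the generators do **not** emulate: spatial heterogeneity of the
ambient field along a trip (the field is spatially constant), instrument
drift and temperature dependence of the optics, size-resolved (per-bin)
counting effects, particle composition changes, and traffic microscale
structure. Passing tests therefore demonstrate that the estimators recover
the parameters of this generating model under realistic noise and RH
variation — not that any particular field deployment meets a given
accuracy.

## Problem sizes and tolerances

The synthetic acceptance study runs 100 independent 14-day, 1-minute
co-location campaigns (κ = 0.4, gain 1, 10 % multiplicative noise) and
requires κ recovery within 15 %, corrected slope in [0.95, 1.05], and a
strict R² improvement, each in at least 95 of the 100 seeds. The routing
oracle sweeps 1000 random graphs of up to 8 nodes for both objectives.
Both complete in seconds; the sizes were chosen to give stable pass/fail
statistics, not to stress throughput. Coefficient-recovery tolerances are
1e-8 relative on noiseless data (numerical, not statistical); inversion
identities hold to 1e-9 relative.

## Known limitations

* The κ estimate is a single bulk hygroscopicity for the whole size
  fraction; aerosols with RH-dependent composition violate the model.
* The MLR forms are linear in T and RH; strongly non-linear RH responses
  are only captured through the κ route.
* Routing has no transit schedules, transfers or map-matching; edge travel
  times are inputs.
* Grid cells use arithmetic means; no kriging or temporal decay weighting
  beyond the window/background fallback.
* The dose model stops at the inhalation product — no deposition or uptake
  modelling.
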