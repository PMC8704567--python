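# Methods

## Scope and model

`windborne` reconstructs wind-borne nocturnal moth migration at synoptic
scale. The moth is a passive-plus-airspeed tracer: it is advected by the
horizontal wind at a constant altitude above ground and adds a fixed
self-powered vector of 3.0 m/s *along* the wind (downwind flight, no
deflection angle). The paper-of-record behavior for fall armyworm and
similar noctuids is encoded as explicit, configurable rules rather than
buried in the integrator:

| parameter | default | meaning |
|---|---|---|
| `airspeed` | 3.0 m/s | self-powered vector added along the wind |
| `t_min` | 13.8 degC | flight forbidden strictly below this temperature (equality permits) |
| `takeoff_local` | 19:00 | nominal dusk take-off, local mean solar time |
| `dusk_local`/`dawn_local` | 20:00 / 05:00 | nocturnal window; hourly release times of backward fans |
| `nightly_max_h` | 12 h | over-land nightly cap |
| `max_nights` | 3 | consecutive nights (carried in config; the two-leg reconstruction never needs more) |
| `oversea_max_h` | 36 h | single-flight cap when the over-sea extension applies |
| `max_legs` | 2 | stepping-stone chain length |
| `altitudes_m` | 500, 750, 1000, 1200, 1500, 1750, 2000, 2250 | candidate launch altitudes AGL |
| `step_s` | 300 s | integration step |
| `takeoff_tolerance_h` | 1 h | half-width of the accepted departure-time window |

Local *mean solar* time (UTC + lon/15 h) is used everywhere instead of civil
time zones: trap sites and candidate sources span several zones and the
behavioral clock times are round local values.

### Integration

Midpoint (RK2) stepping at 300 s; position updates use the spherical metric
`dlat = dy/R`, `dlon = dx/(R cos phi)` with R = 6371 km. Backward legs negate
the full ground velocity — the assumption being that the moth also flew
downwind in the past. Altitude is held constant AGL for a whole leg: launch
altitude is a scan parameter, and vertical air motion is diagnostic (the
downdraft analysis) rather than advective. Tests pin the scheme against an
independent explicit-Euler integration at a 1 s step, closed-form
displacements in uniform flow (0.1 % tolerance), forward/backward inversion
on smooth fields (within max(1 km, 0.2 % of path length) at a 60 s step),
and step-halving convergence (< 0.5 km endpoint shift).

### Stop rules

A leg terminates at the first applicable of: cold air at the current
position (`cold`); dawn reached over land, or first landfall after dawn when
over sea (`dawn_landfall`); the 36 h cap (`oversea_cap`); the nightly
over-land budget (`nightly_cap`); leaving the grid (`domain_exit`). The
nightly over-land duration is min(12 h, take-off-to-dawn span): the
dusk-to-dawn window (10 h) binds over land, while the 12 h cap matters only
where dawn rules are suspended; both constants are configurable so either
reading of the behavior is obtainable. Backward legs mirror the forward
rules: integrate back to the most recent local 19:00 (computed at the
release longitude); if over land there, the take-off is found; if over sea,
continue to the first land cell, subject to the same 36 h cap.

### Endpoint validity and chaining

A backward endpoint is a plausible departure when it is (a) terrestrial —
with a two-tier host rule: lenient (any land, the default) or strict (inside
the host-crop raster), applied to the deepest endpoint only, since
intermediate stopovers need only be land; (b) within +-1 h of the local
19:00 take-off *at the endpoint longitude*; and (c) not produced by a cold
stop or grid exit. Valid first-leg endpoints are treated as the previous
flight's landing sites; second backward fans are launched from them across
the preceding night's hourly landing times (one fan per distinct stopover
grid cell and take-off evening — endpoints a few integration steps apart are
the same stopover). A candidate trajectory is identified by its (release
time, altitude) pair and counted once per leg index. Migration naming is
chronological: the deepest backward leg is the "first migration".
`source_region_summary` defaults to the deepest available reconstruction
(two-leg chains dominate one-leg ones when both exist) because the earliest
take-off points are the inferred source; hulls come from shapely, centroids
are unweighted means, and "+-" statistics are sample (n-1) SDs with the
standard error also reported, since a dispersion estimator is a reporting
choice, not a model one.

## Meteorological fields

`MetField` holds (time, level, lat, lon) grids of u, v, temperature (degC)
and omega (Pa/s, positive descending); rain is carried but no quantitative
rain rule is applied. The canonical vertical coordinate is meters AGL;
pressure-level input is converted once at load time with the hypsometric
relation `z = (R_d T / g) ln(p0/p)` (mean column temperature 288 K by
default, configurable) — 850 hPa maps to ~1481 m, consistent with the usual
"approximately 1500 m" shorthand. Sampling is quadrilinear (trilinear in
space, linear in time) with **no extrapolation**: out-of-domain queries raise
a signal the engine records as `domain_exit`, never a silent clamp. The
interpolator is hand-written (vectorised corner weights plus a scalar fast
path, validated against `scipy.interpolate.RegularGridInterpolator` in the
tests) because the trajectory engine needs the explicit domain signal and
low per-step overhead. NetCDF I/O uses xarray with the scipy backend
(NETCDF3_CLASSIC), which round-trips all synthetic fields to 1e-6 relative.

Omega converts to a vertical speed hydrostatically, `w = -omega R_d T /
(p g)` with R_d = 287.05 J/(kg K), g = 9.80665 m/s^2; 0.5 Pa/s at 850 hPa is
about 5 cm/s of sinking air — the quantitative form of the argument that
observed downdrafts cannot overwhelm a 3 m/s airspeed.

## Climatology

Rose samples are monthly mean wind vectors per (site, pressure level,
nocturnal hour, year) stratum; with 3 sites, 5 levels (800-900 hPa), 10
hourly bins (20:00-05:00) and 10 years this yields exactly 1500 samples per
monthly histogram. Monthly means are the default because that stratification
makes the histogram arithmetic exact; raw per-night sampling is available
via `monthly_mean=False`. Directions use the meteorological "from"
convention; sectors are 16 half-open 22.5 degree bins centered on the
compass points (a boundary value belongs to the higher sector). "Westerly"
group statistics are reported both for the single W sector and for a pooled
WSW+W+WNW group, since pooling conventions vary. Downdraft events are
maximal intervals where any profile level reaches the threshold (0.3 Pa/s,
inclusive by default because "above" is ambiguous at the boundary).

## Synthetic weather

The generators produce the structural features the analysis depends on, not
realistic turbulence:

* `make_uniform_field` — the closed-form oracle substrate;
* `make_layered_field` — vertically sheared jets and cold layers aloft (the
  cold transition is compressed into a 10 m layer so "strictly above" holds
  at every standard altitude);
* `make_downdraft_field` — one descending-air episode, boxcar in time, flat
  across mid-levels;
* `make_smooth_field` — low-order random trig modes for inversion and
  convergence tests;
* `make_climatology_field` — ten hourly years with a monsoon seasonal cycle
  (strong westerlies in January/February, trade easterlies April-November);
* `make_monsoon_scenario` — the end-to-end ground truth: a uniform westerly
  jet along a corridor latitude, a one-cell source island, an optional
  one-cell stopover island, and an arrival landmass, with geometry solved
  from the closed-form time-of-flight so a dusk take-off verifiably lands
  within 50 km of the trap during the expected arrival night.

Scenario design choices worth recording: islands are rectangles snapped to
grid cells, so nearest-cell mask lookup has exact land boundaries and the
schedule arithmetic is quantisation-free; the source and stopover are one
cell wide in longitude so that a backward leg released while still over the
island at the nominal take-off hour exits to sea first — otherwise every
island would trivially claim its own arrivals. The jet is uniform in the
vertical and exactly `jet_speed` on the corridor latitude (meridional
curvature vanishes there); a monsoon-onset temporal ramp finishes half a day
before the first flight. The seed jitters temperature and the curvature
coefficient, not the corridor dynamics: scenario timing is a design
constraint, not a random draw. Default geometry mimics a
Sulawesi-to-Torres-Strait corridor scaled to ~2000 km so the whole
reconstruction runs in seconds on one core.

**What passing these tests shows — and does not.** The synthetic fields are
smooth, mass-imbalanced, and free of fronts, cyclone structure, rain and
turbulence. Ground-truth recovery therefore validates the *machinery*
(integration, stop rules, chaining, filtering, counting) and the internal
consistency of the behavioral model; it says nothing about whether real
reanalysis winds resolve the flows that carried a particular immigration, and
nothing about trap efficiency or population sizes. Real-data conclusions
inherit the full uncertainty of the driving meteorology.

## Numerical and degenerate-case conventions

* Calm wind (< 0.1 m/s): the downwind heading is undefined, so the
  self-powered vector is suppressed; calm samples are excluded from roses.
* Temperature gate is inclusive at 13.8 degC ("falls below" prohibits).
* A cold release yields a zero-step trajectory with reason `cold`.
* One valid leg gives SD 0 with a degenerate flag; fewer than three distinct
  endpoints give a degenerate (point/segment) hull, flagged.
* Problem sizes used by the test suite and acceptance script (an 80-member
  fan per night, ~5-day scenario fields at 0.25 degrees and 10 levels, 100
  inversion trials at a 60 s step, a 2-point decade climatology grid) were
  chosen so every closed-form oracle stays exact while the full suite runs
  in about a minute on one core.

## Known limitations

* No vertical trajectory motion, altitude selection behavior, or
  rain-forced landing; omega is diagnostic only.
* Flat surface: AGL equals height above a reference plane (no terrain).
* Local mean solar time ignores the equation of time (minutes-level error).
* The backward take-off search keys on the release longitude's clock; the
  validity filter re-checks the endpoint longitude, so very long zonal legs
  can terminate a few minutes off the exact local dusk (well inside the
  +-1 h tolerance).
* GRIB input and mesoscale-model execution are out of scope; the package
  consumes post-processed NetCDF.
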