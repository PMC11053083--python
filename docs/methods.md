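# Methods

This note documents the models implemented in `heattwin`, the default
parameter choices and why they were made, what the synthetic data
emulate, and the limitations a user should keep in mind.

## Streams and binning

Two streams feed the pipeline per location: meteorological samples
(temperature °F, relative humidity %, nominally every 30 s) and
passersby counts per time bin. Both are placed on a common uniform grid
before any index is computed. Conventions:

* bins are half-open `[start, start + width)`, anchored to the epoch
  grid, timezone-naive local time;
* the base analysis resolution is **1 hour** — the daily seasonal
  period of 24 used by the forecasting presets implies hourly bins —
  with coarser bins (e.g. 4 h) available for reporting via
  `resample_counts`, which sums and conserves totals exactly;
* meteorological bins with no samples are explicit gaps (NaN), never
  zeros. Forecasting refuses gapped input unless interpolation is
  requested, and linear interpolation is limited to runs of ≤ 3 bins —
  beyond that a gap is a data problem, not something to paper over;
* humidity outside [0, 100] and temperatures outside [−80, 150] °F are
  rejected as probable unit errors (the THI formula is
  Fahrenheit-specific, so a Celsius reading slipping in must fail loudly).

## Exposure indices

`THI = t − (0.55 − 0.0055·RH)(t − 58)`. The index is linear in
temperature with slope `0.45 + 0.0055·RH > 0`, and its humidity slope
has the sign of `t − 58`: humid air worsens heat above 58 °F and (in
the formula's terms) softens cold below it.

Band bounds (80, 90, 105, 128 °F) are treated as **strict** lower
bounds: a THI of exactly 105 is still "hot", 105.01 is "very hot". An
explicit floor category below 80 °F ("below very warm") makes the
classifier total. CTHI is the exact product `THI × count` in
person·°F. The bin width of the exposure period is a parameter
(default 1 h) rather than a constant.

CTHI has no established risk thresholds. The package deliberately
ships none; `flag_high_cthi` offers percentile flagging against a
reference window (default: top 25 %) as a clearly-labelled convention,
nothing more.

## Forecasting

THI and counts are forecast **separately** with SARIMA
`(p,d,q)(P,D,Q)_s` models fit by maximum Gaussian likelihood through
the statsmodels state-space machinery, then combined. Choices:

* an intercept is included iff no differencing is applied, so
  `(0,0,0)(0,0,0)_s` degenerates to the sample-mean model;
* stationarity/invertibility are not enforced during optimisation
  (arbitrary user-supplied orders must be fittable); the scale is
  concentrated out of the likelihood; the optimizer iteration cap
  defaults to 50;
* training R² is `1 − SSE/SST` on one-step-ahead residuals after a
  burn-in of the model's full lag depth (`d + D·s + s·max(P,Q) +
  max(p,q)`), because earlier residuals reflect state initialisation,
  not fit;
* count forecasts floor the point and lower bound at zero and stay
  real-valued (run averages and forecast means are not integers);
* the CTHI forecast is the pointwise product of the two point
  forecasts, with interval bounds taken as the products of like bounds
  floored at zero. This is a deliberate, conservative convention: the
  two models are fit independently and no joint distribution is
  estimated, so these are *not* calibrated 95 % bounds on the product;
* confidence level defaults to 95 %;
* four preset orders are shipped under `PRESET_ORDERS` —
  `(2,0,2)(4,0,1)_24` and `(3,1,0)(5,0,0)_24` for THI,
  `(4,1,0)(3,0,1)_24` and `(4,2,3)(2,1,1)_24` for counts — usable
  directly on any hourly series.

`auto_order` is a deterministic stepwise AIC search: ordinary
differencing from repeated augmented Dickey–Fuller tests (5 % level,
max 2), seasonal differencing from a seasonal-strength heuristic
(strength > 0.64 on a seasonal-means decomposition), then greedy
exploration of (p, q, P, Q) neighbourhoods from four standard starting
points, bounded at p,q ≤ 3 and P,Q ≤ 2. It is a starting point meant
for manual adjustment, and the chosen order is always reported. A
guard rejects `d + D > 3` as over-differencing.

## Crowd simulation

The event simulator is one-dimensional along the route's arc length.
This is a deliberate reduction: only checkpoint crossings feed the
pipeline, so modelling the 2-D street fabric, buildings, or collision
avoidance would add parameters without changing the output statistic.

* Arrival times are i.i.d. uniform on the assembly window ("gradual"
  arrival with no further structure assumed); everyone waits at arc 0
  and starts marching simultaneously at the start time.
* Each agent's speed is a single uniform draw from
  `[speed_low, speed_high]` (defaults 0.5–1.0 m/s) held constant, so
  the crowd spreads purely through speed heterogeneity.
* Crossing times are linearly interpolated within the time step, which
  makes binned output exactly independent of the step size (default
  1 s; tests verify bit-equality under halving).
* With the default settings every participant crosses exactly once, so
  each run's total equals the participant count and so does the
  per-bin mean over runs (default 10 runs, seeds `base_seed + i`).
  An optional flag lets the dispersal march back along the route and
  recross the checkpoint, doubling passes; it defaults to off because
  whether a real dispersal recrosses the monitored intersection is
  scenario-specific.
* Routes come from GeoJSON LineStrings. Planar coordinates are used
  as-is (metres); geographic coordinates are projected to a local
  equirectangular plane (adequate below a few kilometres — the error
  against a haversine computation is well under 0.1 % at city scale).
  The checkpoint is given as arc metres or as a coordinate projected
  to the nearest point on the line, and must be strictly interior.

Parking-lot approach and drive-away phases are not simulated; under
the default flag they cannot affect checkpoint counts.

## Black-swan fusion

Run-averaged simulated crossings are **added** to the count point
forecast bin by bin; interval bounds shift by the same amount (after
averaging, the simulation is treated as a deterministic scenario input,
contributing location but not spread). CTHI is then recomputed from
the adjusted counts. Every bin carries a provenance tag
(`baseline` / `baseline+event`) so reports can separate statistical
prediction from scenario adjustment. Fusion is additive and local: an
empty event series is the identity, and changing one event bin touches
only that bin.

## Synthetic data

The generators stand in for the sensor and camera streams the pipeline
was designed around, which are not publicly deposited. They emulate
the *statistical shape* the pipeline assumes, not any particular city's
measurements.

* **Meteorology**: sinusoidal diurnal cycle plus Gaussian noise at a
  30-s cadence; humidity runs in anti-phase with temperature and is
  clipped to [0, 100]. Defaults: mean 86 °F, diurnal amplitude 14 °F
  peaking at 15:00, humidity mean 78 % with amplitude 10 %, noise 1 °F
  / 3 %. This is a humid-subtropical August calibration chosen so the
  afternoon THI peaks near 92–93 °F — reliably inside the "hot" band
  on every generated day — because a calibration with a drier or
  cooler afternoon peak cannot reach THI > 90 at all (the index needs
  heat *and* humidity together). A hotter per-location offset
  (+9 °F / +15 %) in the benchmark bundle pushes one location's peaks
  to ~104 °F, occasionally brushing "very hot" through noise.
* **Counts**: non-homogeneous Poisson draws from separate 24-hour
  weekday and weekend rate profiles (commuter double peak on weekdays,
  broad midday peak on weekends; peak 4-hour rate mass ≈ 250–265
  persons). The calibration keeps every 4-hour sum at or below 400
  with high probability — the normal-conditions regime — with the
  95th percentile of weekly maxima landing near 290. Poisson is an
  assumption of convenience: only totals and bounds are known about
  the regime being emulated, not a distributional family.
* **Benchmark week**: two locations, 7 days starting on a Sunday, a
  500-participant event injected at 11:00 on the final day at one
  location, ground-truth event crossings stored separately. The march
  route is a planar 1200 m polyline with the checkpoint at 600 m, so
  the kinematic crossing window is 600–1200 s after the start — which
  concentrates the event into a single hourly bin. Everything is
  deterministic by seed (derived sub-seeds stay below 2³¹).

What passing tests on these data do **not** show: robustness to sensor
dropout and drift, non-Poisson overdispersion in real pedestrian
counts, weather fronts breaking the diurnal cycle, or events whose
crowds behave unlike the uniform-speed march model.

## Pipeline sizes and determinism

The end-to-end pipeline trains on the first six days (144 hourly bins)
and forecasts the seventh (24 bins), mirroring a short accumulation
window; the default pipeline orders `(1,0,0)(0,1,1)_24` /
`(1,0,1)(0,1,1)_24` are small seasonal models chosen as robust
defaults for week-scale training windows (the shipped presets are
available via configuration). Statistical validation in the test
suite uses 200 replicates for coefficient recovery and interval
coverage and 50 seeds for calibration and fusion-improvement checks.
Estimation is deterministic; all simulation randomness flows from
explicit seeds, and a repeated run with the same config and seed
reproduces every artifact checksum in the manifest.

## Known limitations

* Exposure is location-based, not person-based: no trajectories, no
  exposure duration per individual.
* Crowd-density microclimate feedback (a dense crowd raising local
  heat) is not modelled.
* The THI/CTHI product forecast has no joint uncertainty model; its
  bounds are a labelled convention.
* Daylight-saving and timezone handling are out of scope (naive local
  time throughout).
* The simulator may miss a crossing if the checkpoint lies within one
  step-length of the route's end; keep checkpoints a few metres
  interior at realistic step sizes.
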