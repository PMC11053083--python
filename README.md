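# heattwin

Collective urban heat exposure assessment and forecasting for specific
city locations — a digital-twin style pipeline that combines roadside
weather sensing, pedestrian counting, seasonal time-series forecasting,
and agent-based crowd simulation.

## The problem

Heat-health risk at street level depends on two things at once: how
severe the heat stress is, and how many people are standing in it. A
shaded corner at 95 °F with nobody on it matters less to a city's heat
response than a slightly cooler intersection with a crowd. `heattwin`
is written for the people who operate such a monitoring loop — urban
climate researchers and city analytics teams — and covers the full
cycle: continuous assessment, next-day forecasting, and what-if
correction for scheduled crowd events that no statistical model trained
on ordinary weeks can anticipate.

## The indices

Heat stress is measured by the temperature–humidity index, with
dry-bulb temperature *t* in °F and relative humidity *RH* in percent:

```
THI = t − (0.55 − 0.0055·RH)(t − 58)
```

At saturation (`RH = 100`) the index equals the air temperature; at
58 °F humidity has no effect. THI bands classify risk with strict lower
bounds: **very warm** (> 80 °F), **hot** (> 90), **very hot** (> 105),
**extremely hot** (> 128).

Collective exposure at location *i* in time bin *t* weights heat stress
by the number of people exposed, with `P_{t,i}` the passersby count:

```
CTHI_{t,i} = THI_{t,i} × P_{t,i}      [person·°F]
```

Both THI and counts are forecast with seasonal ARIMA models
`(p,d,q)(P,D,Q)_s` (daily season, `s = 24` on the hourly grid), and the
CTHI forecast is their pointwise product. Scheduled events — a march, a
rally — are handled by a one-dimensional agent-based simulation along
the announced route: participants assemble during an arrival window,
walk at personal speeds drawn uniformly from a stated range, and are
counted as they pass the monitored checkpoint. The run-averaged
simulated crossings are added to the count forecast and the CTHI
forecast is recomputed.

## Worked example

`examples/04_black_swan_fusion.py` builds a synthetic week in which a
500-person march crosses the monitored intersection at 11:00 on the
final day, forecasts that day from the first six days only, then fuses
the simulated event in:

```
11:00 observed CTHI    48731  blind     5231  fused    49684
event-bin MAE: blind 43500 -> fused 953 person-degF
```

The blind seasonal forecast misses the spike by a factor of nine;
adding the simulated crossings to the count forecast before recomputing
CTHI brings the prediction within ~2 % of the observed collective
exposure. The other examples show the assessment table
(`01_exposure_assessment.py`), plain next-day forecasting with interval
bounds (`02_forecast_next_day.py`), and the simulator's conservation
and kinematics (`03_crowd_event.py`).

A thin CLI mirrors the library for file-based composition:

```sh
heattwin gen --seed 1 --out data/
heattwin assess --meteo data/meteo.csv --counts data/counts.csv --out exposure.csv
heattwin simulate-event --scenario data/scenario.yaml --route data/route.geojson \
    --seed 1 --out crossings.csv
heattwin run --config pipeline.yaml     # full pipeline + manifest
```

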