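"""Synthetic sensor and pedestrian streams for a hot-city pilot week.

The pipeline was designed around roadside nodes sampling temperature and
humidity every 30 s and street cameras counting passersby; comparable
public streams are not generally available, so this module generates
statistically similar ones.  The meteorological generator produces a
sinusoidal diurnal cycle plus Gaussian noise, calibrated to a humid
subtropical summer so that daytime THI reliably enters the "hot" band
(> 90 °F) and, at an offset hot location, occasionally brushes "very
hot".  The count generator draws non-homogeneous Poisson counts from
separate weekday and weekend hourly rate profiles, calibrated so that
under normal conditions no 4-hour bin exceeds 400 passersby except with
small probability; simulated crowd events can be injected on top.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crowdsim import EventScenario, Route, simulate_event
from .streams import (
    CountSeries,
    MeteoSample,
    StreamError,
    write_counts_csv,
    write_meteo_csv,
)

__all__ = [
    "MeteoGenConfig",
    "CountGenConfig",
    "gen_meteo",
    "gen_counts",
    "make_benchmark_week",
    "DEFAULT_WEEKDAY_RATES",
    "DEFAULT_WEEKEND_RATES",
]

_MOD = 2**31  # derived seeds stay below 2^31


def _subseed(seed: int, k: int) -> int:
    return (int(seed) * 1_000_003 + 97 * k + 13) % _MOD


@dataclass
class MeteoGenConfig:
    """Diurnal temperature/humidity generator settings.

    Temperature follows mean + amplitude·cos(2π(hour − peak)/24) with
    Gaussian noise; humidity runs in anti-phase (dry afternoons, humid
    nights) and is clipped to [0, 100].  The default calibration — a
    96 °F afternoon peak with ~68 % humidity — places peak THI around
    92–93 °F, inside the "hot" band, on every generated day.
    """

    location_id: str = "loc"
    sample_interval: float = 30.0  # seconds, the sensor cadence
    mean_temperature: float = 86.0  # °F
    diurnal_amplitude: float = 14.0  # °F
    peak_hour: float = 15.0  # local solar-lag afternoon peak
    humidity_mean: float = 78.0  # %
    humidity_amplitude: float = 10.0  # %, anti-phase with temperature
    temp_noise_sd: float = 1.0  # °F
    humidity_noise_sd: float = 3.0  # %
    temp_offset: float = 0.0  # per-location climate offset, °F
    humidity_offset: float = 0.0  # per-location offset, %

    def __post_init__(self):
        if self.diurnal_amplitude < 0 or self.humidity_amplitude < 0:
            raise StreamError("amplitudes must be non-negative")
        if self.sample_interval <= 0:
            raise StreamError("sample interval must be positive")


@dataclass
class CountGenConfig:
    """Hourly pedestrian-rate profiles with Poisson observation noise.

    Separate 24-hour weekday and weekend profiles (persons/hour).  The
    default calibration keeps every 4-hour sum at or below 400 with high
    probability — the stated normal-conditions regime — with commuter
    peaks on weekdays and a broad midday peak on weekends.
    """

    location_id: str = "loc"
    weekday_rates: tuple = None
    weekend_rates: tuple = None
    rate_scale: float = 1.0
    events: list = field(default_factory=list)  # (EventScenario, Route) pairs

    def __post_init__(self):
        if self.weekday_rates is None:
            self.weekday_rates = DEFAULT_WEEKDAY_RATES
        if self.weekend_rates is None:
            self.weekend_rates = DEFAULT_WEEKEND_RATES
        for name in ("weekday_rates", "weekend_rates"):
            rates = tuple(float(r) for r in getattr(self, name))
            if len(rates) != 24:
                raise StreamError(f"{name} must have 24 hourly entries")
            if any(r < 0 for r in rates):
                raise StreamError(f"{name} must be non-negative")
            setattr(self, name, rates)
        if self.rate_scale < 0:
            raise StreamError("rate_scale must be non-negative")


# persons/hour; commuter morning and evening peaks on weekdays
DEFAULT_WEEKDAY_RATES = (
    3, 2, 2, 2, 3, 5, 12, 30, 55, 65, 60, 58,
    62, 68, 60, 52, 55, 68, 72, 55, 35, 20, 10, 5,
)
# broad midday/afternoon peak on weekends
DEFAULT_WEEKEND_RATES = (
    4, 3, 2, 2, 2, 3, 6, 12, 25, 40, 55, 65,
    70, 68, 62, 55, 50, 45, 40, 35, 28, 18, 10, 6,
)


def gen_meteo(
    config: MeteoGenConfig,
    days: int,
    seed: int,
    start: pd.Timestamp = pd.Timestamp("2020-08-16"),
) -> list[MeteoSample]:
    """Generate ``days`` of 30-s-cadence temperature/humidity samples."""
    if days < 1:
        raise StreamError("days must be >= 1")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start)
    n_per_day = int(round(86400 / config.sample_interval))
    n = n_per_day * days
    times = start + pd.to_timedelta(
        np.arange(n) * config.sample_interval, unit="s"
    )
    hours = (times - times.normalize()) / pd.Timedelta(hours=1)
    phase = 2 * np.pi * (np.asarray(hours) - config.peak_hour) / 24.0
    temp = (
        config.mean_temperature
        + config.temp_offset
        + config.diurnal_amplitude * np.cos(phase)
        + rng.normal(0, config.temp_noise_sd, n)
    )
    rh = (
        config.humidity_mean
        + config.humidity_offset
        - config.humidity_amplitude * np.cos(phase)
        + rng.normal(0, config.humidity_noise_sd, n)
    )
    rh = np.clip(rh, 0.0, 100.0)
    temp = np.clip(temp, -79.0, 149.0)
    return [
        MeteoSample(t, config.location_id, float(tv), float(hv))
        for t, tv, hv in zip(times, temp, rh)
    ]


def gen_counts(
    config: CountGenConfig,
    days: int,
    seed: int,
    start: pd.Timestamp = pd.Timestamp("2020-08-16"),
) -> CountSeries:
    """Generate ``days`` of hourly Poisson passersby counts.

    Rates follow the weekday/weekend profiles; any configured (scenario,
    route) event injections are simulated (one run each, seeded from
    ``seed``) and added bin-wise, so the returned stream is what a camera
    would have observed during the event.
    """
    if days < 1:
        raise StreamError("days must be >= 1")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start).normalize()
    idx = pd.date_range(start, periods=days * 24, freq="1h")
    rates = np.array(
        [
            (config.weekend_rates if t.dayofweek >= 5 else config.weekday_rates)[t.hour]
            for t in idx
        ]
    ) * config.rate_scale
    counts = rng.poisson(rates).astype(float)
    series = pd.Series(counts, index=idx)
    series.index.name = "bin_start"
    for k, (scenario, route) in enumerate(config.events):
        if scenario.bin_width != pd.Timedelta(hours=1):
            raise StreamError("injected events must use the hourly bin grid")
        crossings = simulate_event(scenario, route, _subseed(seed, k + 1))
        for t, c in crossings.counts.items():
            if t in series.index:
                series[t] += c
    return CountSeries(config.location_id, pd.Timedelta(hours=1), series)


# ---------------------------------------------------------------------------
# Benchmark bundle
# ---------------------------------------------------------------------------

#: Planar march route used by the benchmark: 1200 m with one bend,
#: checkpoint (the monitored intersection) at arc 600 m.
_BENCH_ROUTE_COORDS = [[0.0, 0.0], [800.0, 0.0], [800.0, 400.0]]
_BENCH_CHECKPOINT_M = 600.0


def _benchmark_event(start_day: pd.Timestamp) -> tuple[EventScenario, Route]:
    scenario = EventScenario(
        n_participants=500,
        assembly_window=pd.Timedelta(hours=1),
        start_time=start_day + pd.Timedelta(days=6, hours=11),
        speed_low=0.5,
        speed_high=1.0,
        n_runs=10,
        location_id="11th",
    )
    route = Route(np.array(_BENCH_ROUTE_COORDS), _BENCH_CHECKPOINT_M)
    return scenario, route


def make_benchmark_week(seed: int, out_dir) -> dict[str, Path]:
    """Write a deterministic one-week, two-location fixture bundle.

    Layout mirrors the pilot study: two neighbouring intersections
    ("10th", hotter; "11th") observed for 7 days starting on a Sunday,
    with a 500-participant event injected at 11:00 on the final day at
    the "11th" location.  The event's own crossings are also written
    separately as ground truth for forecast evaluation.

    Returns a mapping of artifact names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = pd.Timestamp("2020-08-16")  # a Sunday
    scenario, route = _benchmark_event(start)

    meteo_cfgs = {
        "10th": MeteoGenConfig(location_id="10th", temp_offset=9.0,
                               humidity_offset=15.0),
        "11th": MeteoGenConfig(location_id="11th"),
    }
    samples = []
    for k, loc in enumerate(sorted(meteo_cfgs)):
        samples.extend(gen_meteo(meteo_cfgs[loc], 7, _subseed(seed, 100 + k), start))
    meteo_path = out / "meteo.csv"
    write_meteo_csv(samples, meteo_path)

    count_cfgs = {
        "10th": CountGenConfig(location_id="10th"),
        "11th": CountGenConfig(location_id="11th",
                               events=[(scenario, route)]),
    }
    count_series = [
        gen_counts(count_cfgs[loc], 7, _subseed(seed, 200 + k), start)
        for k, loc in enumerate(sorted(count_cfgs))
    ]
    counts_path = out / "counts.csv"
    write_counts_csv(count_series, counts_path)

    # ground-truth event crossings (the same single run injected above)
    truth = simulate_event(scenario, route, _subseed(_subseed(seed, 201), 1))
    truth_path = out / "event_truth.csv"
    write_counts_csv(truth, truth_path)

    route_path = out / "route.geojson"
    route_path.write_text(json.dumps({
        "type": "Feature",
        "properties": {"checkpoint_arc_m": _BENCH_CHECKPOINT_M},
        "geometry": {"type": "LineString", "coordinates": _BENCH_ROUTE_COORDS},
    }, indent=1))

    scenario_path = out / "scenario.yaml"
    scenario_path.write_text(yaml.safe_dump({
        "n_participants": scenario.n_participants,
        "assembly_window_s": int(scenario.assembly_window.total_seconds()),
        "start_time": scenario.start_time.isoformat(),
        "speed_low": scenario.speed_low,
        "speed_high": scenario.speed_high,
        "n_runs": scenario.n_runs,
        "bin_width_s": int(scenario.bin_width.total_seconds()),
        "location_id": scenario.location_id,
        "checkpoint": _BENCH_CHECKPOINT_M,
    }, sort_keys=True))

    return {
        "meteo": meteo_path,
        "counts": counts_path,
        "event_truth": truth_path,
        "route": route_path,
        "scenario": scenario_path,
    }
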