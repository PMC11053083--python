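"""Agent-based simulation of a scheduled crowd event along a route.

Statistical forecasts cannot anticipate one-off "black swan" events — a
march or rally reroutes hundreds of people past a monitored intersection
in a way no historical count stream contains.  This module simulates such
an event from its announced facts (expected participants, start time,
route) and records when each simulated participant crosses a checkpoint
on the route, binned onto the pipeline's count grid.

The model is deliberately one-dimensional: agents move along the route's
arc length at a constant personal speed drawn uniformly from a stated
range, having assembled at the start point during an arrival window.
Only checkpoint crossings feed the downstream pipeline, so the street
network around the route is not modelled.  Crossing times are found by
linear interpolation between simulation steps, which makes the binned
output independent of the step size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString, Point

from .streams import CountSeries, StreamError

__all__ = [
    "Route",
    "EventScenario",
    "AgentState",
    "simulate_event",
    "average_runs",
    "load_scenario",
    "load_route_geojson",
]

_EARTH_RADIUS_M = 6_371_008.8


def _project_local(coords: np.ndarray) -> np.ndarray:
    """Equirectangular projection of lon/lat degrees to local metres."""
    lat0 = math.radians(coords[:, 1].mean())
    x = _EARTH_RADIUS_M * math.cos(lat0) * np.radians(coords[:, 0])
    y = _EARTH_RADIUS_M * np.radians(coords[:, 1])
    return np.column_stack([x, y])


@dataclass
class Route:
    """A polyline march route with one monitored checkpoint on it.

    ``waypoints`` are planar coordinates in metres (lon/lat inputs are
    projected locally on construction); ``checkpoint`` is the arc-length
    position ``d`` of the monitored intersection, strictly interior to
    the route.
    """

    waypoints: np.ndarray = field(repr=False)
    checkpoint: float
    geodesic: bool = False

    def __post_init__(self):
        pts = np.asarray(self.waypoints, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise StreamError("route needs at least two 2-D waypoints")
        if self.geodesic:
            pts = _project_local(pts)
        seglens = np.hypot(*np.diff(pts, axis=0).T)
        cumlen = np.concatenate([[0.0], np.cumsum(seglens)])
        if cumlen[-1] <= 0:
            raise StreamError("degenerate route of zero length")
        if (np.diff(cumlen) <= 0).any():
            raise StreamError("route contains repeated consecutive waypoints")
        self.waypoints = pts
        self.cumlen = cumlen
        if not 0.0 < self.checkpoint < cumlen[-1]:
            raise StreamError(
                f"checkpoint at {self.checkpoint} m must lie strictly inside "
                f"(0, {cumlen[-1]:.1f})"
            )

    @property
    def length(self) -> float:
        """Total arc length L in metres."""
        return float(self.cumlen[-1])

    @classmethod
    def from_coords(cls, coords, checkpoint_coord=None, checkpoint_arc=None,
                    geodesic: bool = False) -> "Route":
        """Build a route, locating the checkpoint by arc metres or by the
        nearest point on the line to a coordinate."""
        if (checkpoint_coord is None) == (checkpoint_arc is None):
            raise StreamError(
                "give exactly one of checkpoint_coord or checkpoint_arc"
            )
        pts = np.asarray(coords, dtype=float)
        if checkpoint_arc is not None:
            return cls(pts, float(checkpoint_arc), geodesic)
        if geodesic:
            merged = np.vstack([pts, np.asarray(checkpoint_coord, float)])
            proj = _project_local(merged)
            line = LineString(proj[:-1])
            d = line.project(Point(proj[-1]))
            route = cls(pts, float(d), geodesic=True)
            return route
        line = LineString(pts)
        d = line.project(Point(checkpoint_coord))
        return cls(pts, float(d), geodesic=False)


@dataclass
class EventScenario:
    """Everything announced about the event, plus simulation knobs.

    Defaults mirror a 500-person march assembling over one hour and
    walking at 0.5–1.0 m/s, with output averaged over 10 runs.
    """

    n_participants: int = 500
    assembly_window: pd.Timedelta = pd.Timedelta(hours=1)
    start_time: pd.Timestamp = pd.Timestamp("2020-08-22 11:00")
    speed_low: float = 0.5   # m/s
    speed_high: float = 1.0  # m/s
    n_runs: int = 10
    time_step: float = 1.0   # s
    return_crosses_checkpoint: bool = False
    bin_width: pd.Timedelta = pd.Timedelta(hours=1)
    location_id: str = "event"

    def __post_init__(self):
        self.assembly_window = pd.Timedelta(self.assembly_window)
        self.bin_width = pd.Timedelta(self.bin_width)
        self.start_time = pd.Timestamp(self.start_time)
        if self.n_participants < 0:
            raise StreamError("n_participants must be non-negative")
        if not 0 < self.speed_low <= self.speed_high:
            raise StreamError(
                f"speeds must satisfy 0 < low <= high, got "
                f"({self.speed_low}, {self.speed_high})"
            )
        if self.assembly_window < pd.Timedelta(0):
            raise StreamError("assembly window must be non-negative")
        if self.n_runs < 1:
            raise StreamError("n_runs must be >= 1")
        if self.time_step <= 0:
            raise StreamError("time step must be positive")


@dataclass(frozen=True)
class AgentState:
    """Final per-agent record from a single simulation run."""

    id: int
    arrival_time: pd.Timestamp
    speed: float
    crossing_times: tuple  # seconds after start_time, one per directional pass
    phase: str  # terminal phase: "dispersed"


def _march(scenario: EventScenario, route: Route, rng: np.random.Generator):
    """Run one realisation; returns (crossing seconds array, agents).

    Agents arrive uniformly at random in the assembly window, wait at arc
    position 0, and all start marching at ``start_time``.  Positions are
    advanced in fixed time steps; a crossing is detected when the position
    passes the checkpoint between steps and its time is linearly
    interpolated within the step.
    """
    n = scenario.n_participants
    arrivals = scenario.start_time - scenario.assembly_window * (1 - rng.random(n))
    speeds = rng.uniform(scenario.speed_low, scenario.speed_high, size=n)
    d, L, dt = route.checkpoint, route.length, scenario.time_step
    crossings: list[list[float]] = [[] for _ in range(n)]
    if n:
        pos = np.zeros(n)
        direction = np.ones(n)
        active = np.ones(n, dtype=bool)
        t = 0.0
        while active.any():
            step = speeds * dt * direction
            new_pos = pos + np.where(active, step, 0.0)
            # outbound crossing: position passes d going up
            out = active & (pos < d) & (new_pos >= d) & (direction > 0)
            # return crossing: position passes d going down
            back = active & (pos > d) & (new_pos <= d) & (direction < 0)
            for i in np.nonzero(out)[0]:
                crossings[i].append(t + (d - pos[i]) / speeds[i])
            for i in np.nonzero(back)[0]:
                crossings[i].append(t + (pos[i] - d) / speeds[i])
            # reached the end of the route
            done = active & (new_pos >= L) & (direction > 0)
            if scenario.return_crosses_checkpoint:
                new_pos[done] = 2 * L - new_pos[done]  # reflect and walk back
                direction[done] = -1
                home = active & (new_pos <= 0) & (direction < 0)
                active[home] = False
            else:
                active[done] = False
            pos = new_pos
            t += dt
    agents = [
        AgentState(
            id=i,
            arrival_time=arrivals[i],
            speed=float(speeds[i]),
            crossing_times=tuple(crossings[i]),
            phase="dispersed",
        )
        for i in range(n)
    ]
    all_crossings = np.array(
        [c for agent in crossings for c in agent], dtype=float
    )
    return all_crossings, agents


def _bin_crossings(seconds: np.ndarray, scenario: EventScenario) -> CountSeries:
    width = scenario.bin_width
    empty = pd.Series(dtype=float, index=pd.DatetimeIndex([], name="bin_start"))
    if len(seconds) == 0:
        return CountSeries(scenario.location_id, width, empty)
    times = scenario.start_time + pd.to_timedelta(seconds, unit="s")
    bins = times.floor(width)
    counts = pd.Series(1.0, index=bins).groupby(level=0).sum()
    full = pd.date_range(counts.index[0], counts.index[-1], freq=width)
    counts = counts.reindex(full, fill_value=0.0)
    counts.index.name = "bin_start"
    return CountSeries(scenario.location_id, width, counts)


def simulate_event(
    scenario: EventScenario,
    route: Route,
    seed: int,
    return_agents: bool = False,
):
    """One simulation run: binned checkpoint-crossing counts.

    With the return-pass flag off, every agent crosses the checkpoint
    exactly once, so the series total equals ``n_participants`` for any
    seed.  Crossing times are bounded by the kinematics:
    ``start + d/speed_high <= crossing <= start + d/speed_low``.
    """
    rng = np.random.default_rng(seed)
    seconds, agents = _march(scenario, route, rng)
    series = _bin_crossings(seconds, scenario)
    if return_agents:
        return series, agents
    return series


def average_runs(scenario: EventScenario, route: Route, base_seed: int) -> CountSeries:
    """Per-bin mean of ``n_runs`` independent runs (seeds base_seed + i).

    Each run conserves the participant total, so the averaged series'
    total is exactly ``n_participants`` when the return flag is off.
    """
    runs = [
        simulate_event(scenario, route, base_seed + i).counts
        for i in range(scenario.n_runs)
    ]
    nonempty = [r for r in runs if not r.empty]
    if not nonempty:
        return CountSeries(
            scenario.location_id,
            scenario.bin_width,
            pd.Series(dtype=float, index=pd.DatetimeIndex([], name="bin_start")),
        )
    lo = min(r.index[0] for r in nonempty)
    hi = max(r.index[-1] for r in nonempty)
    grid = pd.date_range(lo, hi, freq=scenario.bin_width)
    stacked = np.vstack([r.reindex(grid, fill_value=0.0).to_numpy() for r in runs])
    mean = pd.Series(stacked.mean(axis=0), index=grid)
    mean.index.name = "bin_start"
    return CountSeries(scenario.location_id, scenario.bin_width, mean)


# ---------------------------------------------------------------------------
# Scenario / route files
# ---------------------------------------------------------------------------

def load_route_geojson(path, checkpoint=None, geodesic: bool = False) -> Route:
    """Load a GeoJSON LineString route.

    ``checkpoint`` is either arc metres (number) or a coordinate pair to
    be projected onto the line; a checkpoint may instead live in the
    GeoJSON properties under ``checkpoint_arc_m`` or ``checkpoint``.
    """
    with open(path) as fh:
        gj = json.load(fh)
    props = {}
    geom = gj
    if gj.get("type") == "FeatureCollection":
        if not gj.get("features"):
            raise StreamError(f"{path}: empty FeatureCollection")
        geom = gj["features"][0]
    if geom.get("type") == "Feature":
        props = geom.get("properties") or {}
        geom = geom["geometry"]
    if geom.get("type") != "LineString":
        raise StreamError(
            f"{path}: route geometry must be a LineString, got {geom.get('type')!r}"
        )
    coords = geom.get("coordinates", [])
    if len(coords) < 2:
        raise StreamError(f"{path}: LineString needs at least 2 points")
    if checkpoint is None:
        checkpoint = props.get("checkpoint_arc_m", props.get("checkpoint"))
    if checkpoint is None:
        raise StreamError(f"{path}: no checkpoint given or found in properties")
    if isinstance(checkpoint, (int, float)):
        return Route.from_coords(coords, checkpoint_arc=float(checkpoint),
                                 geodesic=geodesic)
    return Route.from_coords(coords, checkpoint_coord=checkpoint,
                             geodesic=geodesic)


def load_scenario(config_path, route_path) -> tuple[EventScenario, Route]:
    """Load an event scenario (YAML/JSON) together with its route."""
    text = Path(config_path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise StreamError(f"{config_path}: scenario must be a mapping")
    known = {
        "n_participants", "assembly_window_s", "start_time", "speed_low",
        "speed_high", "n_runs", "time_step_s", "return_crosses_checkpoint",
        "bin_width_s", "location_id", "checkpoint", "geodesic",
    }
    unknown = set(cfg) - known
    if unknown:
        raise StreamError(f"{config_path}: unknown scenario keys {sorted(unknown)}")
    kwargs = {}
    if "n_participants" in cfg:
        kwargs["n_participants"] = int(cfg["n_participants"])
    if "assembly_window_s" in cfg:
        kwargs["assembly_window"] = pd.Timedelta(seconds=float(cfg["assembly_window_s"]))
    if "start_time" in cfg:
        kwargs["start_time"] = pd.Timestamp(cfg["start_time"])
    for k in ("speed_low", "speed_high", "time_step"):
        src = k if k != "time_step" else "time_step_s"
        if src in cfg:
            kwargs[k] = float(cfg[src])
    if "n_runs" in cfg:
        kwargs["n_runs"] = int(cfg["n_runs"])
    if "return_crosses_checkpoint" in cfg:
        kwargs["return_crosses_checkpoint"] = bool(cfg["return_crosses_checkpoint"])
    if "bin_width_s" in cfg:
        kwargs["bin_width"] = pd.Timedelta(seconds=float(cfg["bin_width_s"]))
    if "location_id" in cfg:
        kwargs["location_id"] = str(cfg["location_id"])
    scenario = EventScenario(**kwargs)
    route = load_route_geojson(
        route_path,
        checkpoint=cfg.get("checkpoint"),
        geodesic=bool(cfg.get("geodesic", False)),
    )
    return scenario, route
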