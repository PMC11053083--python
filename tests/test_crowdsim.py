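"""Crowd-event simulator: kinematics, conservation, routes, determinism."""

import json

import numpy as np
import pandas as pd
import pytest

from heattwin.crowdsim import (
    EventScenario,
    Route,
    average_runs,
    load_route_geojson,
    load_scenario,
    simulate_event,
)
from heattwin.streams import StreamError

START = pd.Timestamp("2020-08-22 11:00")
BEND_COORDS = np.array([[0.0, 0.0], [800.0, 0.0], [800.0, 400.0]])


@pytest.fixture
def route():
    return Route(BEND_COORDS, checkpoint=600.0)


def scenario(**kwargs):
    defaults = dict(start_time=START, bin_width=pd.Timedelta(minutes=5))
    defaults.update(kwargs)
    return EventScenario(**defaults)


class TestKinematics:
    def test_uniform_speed_crowd_crosses_at_exactly_d_over_v(self, route):
        scn = scenario(n_participants=10, speed_low=1.0, speed_high=1.0)
        series, agents = simulate_event(scn, route, seed=1, return_agents=True)
        assert series.total == 10
        for agent in agents:
            assert agent.crossing_times == (600.0,)
        # all ten land in the bin containing start + 600 s
        assert series.counts.idxmax() == START + pd.Timedelta(minutes=10)

    def test_no_participants_gives_empty_series(self, route):
        assert len(simulate_event(scenario(n_participants=0), route, seed=0)) == 0

    def test_crossing_times_bounded_by_speed_range(self, route):
        scn = scenario(n_participants=500, speed_low=0.5, speed_high=1.0)
        _, agents = simulate_event(scn, route, seed=9, return_agents=True)
        times = np.array([a.crossing_times[0] for a in agents])
        assert len(times) == 500
        assert times.min() >= 600.0 / 1.0 - 1e-9
        assert times.max() <= 600.0 / 0.5 + 1e-9

    def test_every_agent_crosses_exactly_once(self, route):
        scn = scenario(n_participants=200)
        series, agents = simulate_event(scn, route, seed=4, return_agents=True)
        assert all(len(a.crossing_times) == 1 for a in agents)
        assert series.total == 200

    def test_return_pass_doubles_crossings(self, route):
        scn = scenario(n_participants=50, return_crosses_checkpoint=True)
        series, agents = simulate_event(scn, route, seed=2, return_agents=True)
        assert all(len(a.crossing_times) == 2 for a in agents)
        assert series.total == 100

    def test_halving_the_time_step_changes_nothing(self, route):
        a = simulate_event(scenario(n_participants=100, time_step=1.0), route, 7)
        b = simulate_event(scenario(n_participants=100, time_step=0.5), route, 7)
        pd.testing.assert_series_equal(a.counts, b.counts, check_freq=False)

    def test_seed_determinism_is_bit_for_bit(self, route):
        scn = scenario(n_participants=300)
        a = simulate_event(scn, route, seed=5)
        b = simulate_event(scn, route, seed=5)
        pd.testing.assert_series_equal(a.counts, b.counts)

    def test_more_participants_never_fewer_expected_crossings(self, route):
        # expectation over 50 seeds, bin-wise
        small = scenario(n_participants=100, time_step=10.0)
        large = scenario(n_participants=150, time_step=10.0)
        tot_small = np.mean([simulate_event(small, route, s).total for s in range(50)])
        tot_large = np.mean([simulate_event(large, route, s).total for s in range(50)])
        assert tot_large >= tot_small


class TestAverageRuns:
    def test_deterministic_scenario_average_equals_single_run(self, route):
        scn = scenario(n_participants=40, speed_low=0.8, speed_high=0.8, n_runs=5)
        avg = average_runs(scn, route, base_seed=3)
        single = simulate_event(scn, route, seed=3)
        pd.testing.assert_series_equal(
            avg.counts[avg.counts > 0], single.counts[single.counts > 0],
            check_freq=False,
        )

    @pytest.mark.parametrize("base_seed", [0, 17, 123456])
    def test_average_conserves_the_participant_total(self, route, base_seed):
        scn = scenario(n_participants=500, n_runs=10)
        assert average_runs(scn, route, base_seed).total == pytest.approx(500.0)

    def test_run_averaging_shrinks_variance_roughly_as_one_over_n(self, route):
        # variance of a mid-range bin across independent averaged estimates
        probe = START + pd.Timedelta(minutes=15)
        variances = {}
        for n_runs in (1, 4, 16):
            scn = scenario(n_participants=200, n_runs=n_runs, time_step=10.0)
            vals = [
                average_runs(scn, route, base_seed=1000 * rep + n_runs).counts.get(probe, 0.0)
                for rep in range(20)
            ]
            variances[n_runs] = np.var(vals)
        # each 4x increase in runs should cut variance by roughly 4 (loose band)
        assert variances[1] / variances[4] == pytest.approx(4.0, rel=0.8)
        assert variances[4] / variances[16] == pytest.approx(4.0, rel=0.8)


class TestRoutes:
    def test_two_point_route_checkpoint_projects_to_midpoint(self):
        r = Route.from_coords([[0, 0], [1000, 0]], checkpoint_coord=[500, 123])
        assert r.checkpoint == pytest.approx(500.0, abs=1.0)
        assert r.length == pytest.approx(1000.0)

    def test_bent_polyline_length_matches_euclidean_oracle(self):
        segs = np.diff(BEND_COORDS, axis=0)
        expected = sum(np.sqrt((s**2).sum()) for s in segs)
        r = Route(BEND_COORDS, checkpoint=600.0)
        assert r.length == pytest.approx(expected, rel=1e-12)

    def test_geodesic_length_matches_haversine_oracle(self):
        # a short path in a lon/lat city grid
        coords = np.array([[-84.99, 32.46], [-84.98, 32.46], [-84.98, 32.47]])
        R = 6_371_008.8

        def hav(a, b):
            la1, la2 = np.radians(a[1]), np.radians(b[1])
            dlat = la2 - la1
            dlon = np.radians(b[0] - a[0])
            h = np.sin(dlat / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2) ** 2
            return 2 * R * np.arcsin(np.sqrt(h))

        expected = hav(coords[0], coords[1]) + hav(coords[1], coords[2])
        r = Route(coords, checkpoint=500.0, geodesic=True)
        assert r.length == pytest.approx(expected, rel=1e-3)

    def test_degenerate_route_rejected(self):
        with pytest.raises(StreamError):
            Route(np.array([[0.0, 0.0], [0.0, 0.0]]), checkpoint=1.0)

    @pytest.mark.parametrize("d", [0.0, -5.0, 1200.0, 2000.0])
    def test_checkpoint_must_be_strictly_interior(self, d):
        with pytest.raises(StreamError, match="checkpoint"):
            Route(BEND_COORDS, checkpoint=d)

    def test_invalid_speeds_rejected(self):
        with pytest.raises(StreamError):
            EventScenario(speed_low=0.0)
        with pytest.raises(StreamError):
            EventScenario(speed_low=1.5, speed_high=1.0)


class TestScenarioFiles:
    def test_geojson_non_linestring_rejected(self, tmp_path):
        p = tmp_path / "bad.geojson"
        p.write_text(json.dumps({"type": "Point", "coordinates": [0, 0]}))
        with pytest.raises(StreamError, match="LineString"):
            load_route_geojson(p, checkpoint=1.0)

    def test_scenario_round_trip_from_benchmark_bundle(self, benchmark_dir):
        scn, route = load_scenario(benchmark_dir["scenario"], benchmark_dir["route"])
        assert scn.n_participants == 500
        assert scn.speed_low == 0.5 and scn.speed_high == 1.0
        assert scn.assembly_window == pd.Timedelta(hours=1)
        assert scn.n_runs == 10
        assert route.checkpoint == pytest.approx(600.0)
        assert route.length == pytest.approx(1200.0)

    def test_unknown_scenario_keys_rejected(self, tmp_path, benchmark_dir):
        p = tmp_path / "scn.yaml"
        p.write_text("n_participants: 10\nchekpoint: 5\ncheckpoint: 600\n")
        with pytest.raises(StreamError, match="chekpoint"):
            load_scenario(p, benchmark_dir["route"])
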