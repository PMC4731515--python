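"""Linking, the 5 um filter, speed profiles, stop/go segmentation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from endodance.synthetic import MotionModel, RootHairGeometry, simulate_population
from endodance.tracking import (LinkingParams, filter_tracks, iter_tracks,
                                link_spots, segment_stop_go, speed_profile)

from conftest import make_tracks


def spots_table(per_frame, dt=0.1):
    """per_frame: list of lists of (x, y) per frame."""
    rows = []
    for f, pts in enumerate(per_frame):
        for x, y in pts:
            rows.append({"frame": f, "t": f * dt, "x": x, "y": y,
                         "intensity": 1.0})
    return pd.DataFrame(rows)


def brute_force_min_cost(prev_pts, new_pts, gate):
    """Oracle: over all maximal feasible matchings, the minimum total
    squared displacement (exhaustive enumeration, <= 4 spots per frame)."""
    prev_pts, new_pts = np.asarray(prev_pts), np.asarray(new_pts)
    n1, n2 = len(prev_pts), len(new_pts)
    for k in range(min(n1, n2), -1, -1):
        costs = []
        for sub1 in itertools.combinations(range(n1), k):
            for sub2 in itertools.permutations(range(n2), k):
                d2 = [((prev_pts[i] - new_pts[j]) ** 2).sum()
                      for i, j in zip(sub1, sub2)]
                if all(c <= gate**2 for c in d2):
                    costs.append(sum(d2))
        if costs:
            return k, min(costs)
    return 0, 0.0


def links_of(tracks, f0, f1):
    """(x0, y0) -> (x1, y1) links between two frames from a track table."""
    out = []
    for tr in iter_tracks(tracks):
        sel0 = tr.frames == f0
        sel1 = tr.frames == f1
        if sel0.any() and sel1.any():
            out.append(((tr.x[sel0][0], tr.y[sel0][0]),
                        (tr.x[sel1][0], tr.y[sel1][0])))
    return out


class TestLinkSpots:
    def test_single_particle_three_frames(self):
        spots = spots_table([[(0.0, 0.0)], [(0.3, 0.0)], [(0.6, 0.0)]])
        tracks = link_spots(spots, LinkingParams())
        assert tracks["track_id"].nunique() == 1
        assert len(tracks) == 3

    def test_parallel_movers_no_swap(self):
        """Two particles on parallel lines 5 um apart never exchange
        identity with a 2 um gate."""
        frames = [[(x, 0.0), (x, 5.0)] for x in np.arange(0, 3.0, 0.5)]
        tracks = link_spots(spots_table(frames), LinkingParams(max_displacement=2.0))
        assert tracks["track_id"].nunique() == 2
        for tr in iter_tracks(tracks):
            assert np.ptp(tr.y) == 0.0
            assert tr.n_spots == 6

    def test_gate_terminates_track(self):
        """A 3 um jump with a 2 um gate starts a new track."""
        spots = spots_table([[(0.0, 0.0)], [(0.5, 0.0)], [(3.5, 0.0)]])
        tracks = link_spots(spots, LinkingParams(max_displacement=2.0,
                                                 max_gap=0))
        assert tracks["track_id"].nunique() == 2

    def test_empty_input(self):
        assert len(link_spots(pd.DataFrame(columns=["frame", "t", "x", "y"]))) == 0

    def test_gap_closed_with_inferred_spot(self):
        spots = spots_table([[(0.0, 0.0)], [], [(0.6, 0.0)], [(0.9, 0.0)]])
        tracks = link_spots(spots, LinkingParams(max_displacement=0.5, max_gap=1))
        assert tracks["track_id"].nunique() == 1
        bridged = tracks[tracks["frame"] == 1]
        assert bridged["inferred"].iloc[0]
        assert np.isnan(bridged["intensity"].iloc[0])
        assert bridged["x"].iloc[0] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_assignment_matches_exhaustive_minimum(self, seed):
        """Frame-pair linking is the optimal feasible matching: same link
        count and total squared cost as brute-force enumeration."""
        rng = np.random.default_rng(seed)
        gate = 2.0
        n1, n2 = rng.integers(1, 5), rng.integers(1, 5)
        p0 = rng.uniform(0, 6, size=(n1, 2))
        p1 = rng.uniform(0, 6, size=(n2, 2))
        spots = spots_table([list(map(tuple, p0)), list(map(tuple, p1))])
        tracks = link_spots(spots, LinkingParams(max_displacement=gate, max_gap=0))
        got = links_of(tracks, 0, 1)
        cost = sum(((np.array(a) - np.array(b)) ** 2).sum() for a, b in got)
        k_opt, cost_opt = brute_force_min_cost(p0, p1, gate)
        assert len(got) == k_opt
        assert cost == pytest.approx(cost_opt, abs=1e-9)

    def test_crossing_particles_keep_identity(self):
        """Particles crossing axially on lanes separated beyond the gate
        are recovered with exactly the ground-truth identities."""
        n = 40
        lanes = [0.0, 2.0, 4.0, 6.0]
        frames = []
        for k in range(n):
            pts = []
            for i, lane in enumerate(lanes):
                # alternate directions so every pair crosses in x
                x = 0.55 * k if i % 2 == 0 else 22.0 - 0.55 * k
                pts.append((x + 0.1 * i, lane))
            frames.append(pts)
        tracks = link_spots(spots_table(frames),
                            LinkingParams(max_displacement=0.96))
        assert tracks["track_id"].nunique() == len(lanes)
        for tr in iter_tracks(tracks):
            assert np.ptp(tr.y) == 0.0          # never left its lane
            assert tr.n_spots == n

    def test_ground_truth_positions_yield_one_track_per_particle(self, geometry):
        """Linking noise-free generator positions at low density produces
        exactly one unbroken track per simulated particle."""
        truth = simulate_population(
            geometry, "FYVE", 6, 10.0, seed=3,
            motion_overrides=MotionModel(kind="stop_and_go", v=5.5),
            n_dancing_pairs=0, n_fusion_pairs=0)
        spots = truth.particles[["frame", "t", "x", "y", "intensity"]]
        tracks = link_spots(spots, LinkingParams(max_displacement=0.96))
        assert tracks["track_id"].nunique() == 6
        for tr in iter_tracks(tracks):
            assert tr.n_spots == truth.n_frames


class TestFilterTracks:
    def make_path(self, length, n=50):
        step = length / n
        xy = np.column_stack([np.arange(n + 1) * step, np.zeros(n + 1)])
        return make_tracks({0: xy})

    def test_five_micron_rule_boundaries(self):
        """4.9 um is excluded, 5.1 um retained."""
        params = LinkingParams(min_path_length=5.0)
        assert len(filter_tracks(self.make_path(4.9), params)) == 0
        assert len(filter_tracks(self.make_path(5.1), params)) > 0

    def test_empty(self):
        out = filter_tracks(pd.DataFrame(columns=["track_id", "frame", "t",
                                                  "x", "y", "intensity",
                                                  "inferred"]))
        assert len(out) == 0

    @given(st.integers(0, 10**6))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        trajs = {i: np.cumsum(rng.uniform(-0.4, 0.5, size=(20, 2)), axis=0)
                 for i in range(4)}
        tracks = make_tracks(trajs)
        once = filter_tracks(tracks)
        twice = filter_tracks(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_net_displacement_mode(self):
        # 10 um out and back: path 20 um, net ~0
        out = np.column_stack([np.linspace(0, 10, 25), np.zeros(25)])
        xy = np.vstack([out, out[::-1][1:]])
        tracks = make_tracks({0: xy})
        assert len(filter_tracks(tracks, LinkingParams(filter_on="path"))) > 0
        assert len(filter_tracks(tracks, LinkingParams(filter_on="net"))) == 0


class TestSpeedProfile:
    def test_stationary(self):
        tracks = make_tracks({0: np.tile([3.0, 3.0], (10, 1))})
        prof = speed_profile(tracks)
        assert (prof["speed"] == 0).all()

    def test_constant_speed(self):
        xy = np.column_stack([np.arange(10) * 0.5, np.zeros(10)])
        prof = speed_profile(make_tracks({0: xy}))
        assert prof["speed"].to_numpy() == pytest.approx(5.0)

    def test_single_spot_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            speed_profile(make_tracks({0: [[0.0, 0.0]]}))

    def test_max_at_least_mean(self):
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.normal(0, 0.3, size=(30, 2)), axis=0)
        tr = next(iter_tracks(make_tracks({0: xy})))
        assert tr.max_speed >= tr.mean_speed >= 0


class TestSegmentStopGo:
    def test_all_stop(self):
        prof = pd.DataFrame({"t": np.arange(10) * 0.1, "dt": 0.1,
                             "speed": np.zeros(10)})
        phases = segment_stop_go(prof)
        assert phases == [("stop", 0.0, pytest.approx(1.0))]

    def test_all_go(self):
        prof = pd.DataFrame({"t": np.arange(10) * 0.1, "dt": 0.1,
                             "speed": np.full(10, 5.0)})
        phases = segment_stop_go(prof, v_stop=0.5)
        assert phases == [("go", 0.0, pytest.approx(1.0))]

    def test_phases_partition_time_span(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame({"t": np.arange(50) * 0.1, "dt": 0.1,
                             "speed": rng.uniform(0, 2, 50)})
        phases = segment_stop_go(prof)
        assert phases[0][1] == 0.0
        assert phases[-1][2] == pytest.approx(5.0)
        for (_, _, e0), (_, s1, _) in zip(phases, phases[1:]):
            assert e0 == pytest.approx(s1)

    def test_recovers_generator_switch_times(self, geometry):
        """Stop/go segmentation of a ground-truth trajectory recovers the
        scripted phase switches within 2 frames."""
        truth = simulate_population(
            geometry, "FYVE", 1, 20.0, seed=8,
            motion_overrides=MotionModel(kind="stop_and_go", v=5.5),
            n_dancing_pairs=0, n_fusion_pairs=0)
        g = truth.particles.sort_values("frame")
        prof = speed_profile(next(iter_tracks(truth.as_tracks())))
        phases = segment_stop_go(prof, v_stop=1.0, min_phase=0.3)
        states = g["motion_state"].to_numpy()
        true_switches = g["t"].to_numpy()[1:][states[1:] != states[:-1]]
        got_switches = np.array([s for _, s, _ in phases[1:]])
        assert len(got_switches) == len(true_switches)
        assert np.abs(got_switches - true_switches).max() <= 0.2 + 1e-9
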