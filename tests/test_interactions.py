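"""Dancing and clustering/fusion detection, population composition, rates."""

import numpy as np
import pandas as pd
import pytest

from endodance.interactions import (InteractionEvent, InteractionParams,
                                    classify_population, detect_cluster_fusion,
                                    detect_dancing, event_rates,
                                    pairwise_distance_series)
from endodance.regions import AxisFrame, make_zone_mask
from endodance.synthetic import MotionModel, simulate_population

from conftest import make_tracks


def jiggled_pair(seed=0, n=400, dt=0.1, sep0=4.0, close=0.8, t_in=8.0,
                 t_out=30.0, merged_intensity=None):
    """Two tracks approaching to ``close`` um at t_in, co-jiggling until
    t_out, then separating. Synchrony comes from a shared jiggle."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    common = np.cumsum(rng.normal(0, 0.09, size=(n, 2)), axis=0)
    common -= common * (np.arange(n) / n)[:, None] * 0.5  # keep bounded-ish
    sep = np.full(n, sep0)
    ramp_in = (t >= t_in - 1.5) & (t < t_in)
    sep[ramp_in] = close + (t_in - t[ramp_in]) / 1.5 * (sep0 - close)
    win = (t >= t_in) & (t <= t_out)
    sep[win] = close
    ramp_out = t > t_out
    sep[ramp_out] = np.minimum(close + (t[ramp_out] - t_out) * 2.2, sep0)
    base = np.array([20.0, 6.0])
    p1 = base + common + np.column_stack([sep / 2, np.zeros(n)])
    p2 = base + common - np.column_stack([sep / 2, np.zeros(n)])
    i1 = np.full(n, 2.0)
    i2 = np.full(n, 3.0)
    if merged_intensity is not None:
        i1[win] = merged_intensity
        i2[win] = merged_intensity
    return make_tracks({0: p1, 1: p2}, frame_interval=dt,
                       intensities={0: i1, 1: i2})


class TestPairwiseDistance:
    def test_identical_tracks_zero(self):
        xy = np.cumsum(np.ones((10, 2)) * 0.1, axis=0)
        tracks = make_tracks({0: xy, 1: xy})
        series = pairwise_distance_series(tracks, (0, 1))
        assert series["distance"].to_numpy() == pytest.approx(0.0)

    def test_parallel_offset(self):
        xy = np.column_stack([np.linspace(0, 5, 20), np.zeros(20)])
        tracks = make_tracks({0: xy, 1: xy + [0.0, 1.5]})
        series = pairwise_distance_series(tracks, (0, 1))
        assert series["distance"].to_numpy() == pytest.approx(1.5)

    def test_threshold_crossing_frame(self):
        """Converging tracks cross the 1 um proximity line exactly where
        scripted."""
        n = 50
        gap = np.linspace(3.0, 0.2, n)          # crosses 1.0 at index...
        cross = int(np.argmax(gap < 1.0))
        a = np.column_stack([np.zeros(n), np.zeros(n)])
        b = np.column_stack([gap, np.zeros(n)])
        series = pairwise_distance_series(make_tracks({0: a, 1: b}), (0, 1))
        got = int(np.argmax(series["distance"].to_numpy() < 1.0))
        assert got == cross

    def test_no_overlap_rejected(self):
        a = make_tracks({0: np.zeros((5, 2))})
        b = make_tracks({1: np.zeros((5, 2))}, frame_offsets={1: 10})
        with pytest.raises(ValueError, match="overlap"):
            pairwise_distance_series(pd.concat([a, b]), (0, 1))


class TestDetectDancing:
    def test_distant_walkers_no_events(self):
        rng = np.random.default_rng(0)
        a = np.array([5.0, 5.0]) + np.cumsum(rng.normal(0, 0.1, (200, 2)), axis=0)
        b = np.array([25.0, 5.0]) + np.cumsum(rng.normal(0, 0.1, (200, 2)), axis=0)
        assert detect_dancing(make_tracks({0: a, 1: b})) == []

    def test_scripted_pair_recovered_with_duration(self, geometry):
        """A generator dancing pair with T = 12 s, d_eq = 0.8 um yields
        exactly one event of duration 12 +/- 1 s at sub-micron range."""
        truth = simulate_population(
            geometry, "FYVE", 2, 30.0, seed=21,
            motion_overrides=MotionModel(kind="stop_and_go", v=5.5,
                                         d_eq=0.8, T_dance=12.0),
            n_dancing_pairs=1, n_fusion_pairs=0)
        events = detect_dancing(truth.as_tracks())
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "dancing"
        assert ev.t_end - ev.t_start == pytest.approx(12.0, abs=1.0)
        assert ev.min_distance < 1.0
        assert ev.sync_score >= 0.5

    def test_sustained_intensity_sum_routes_to_fusion(self):
        """A 'pair' at 0.8 um whose intensity sits at the member sum for
        >20 s is one fused object seen twice, not dancing."""
        tracks = jiggled_pair(merged_intensity=5.0)  # 2.0 + 3.0
        events = detect_dancing(tracks)
        assert len(events) == 1
        assert events[0].type == "cluster_fusion"
        assert events[0].intensity_ratio == pytest.approx(5.0 / 2.0, rel=0.05)

    def test_genuine_dance_not_routed(self):
        tracks = jiggled_pair()
        events = detect_dancing(tracks)
        assert len(events) == 1
        assert events[0].type == "dancing"
        assert events[0].t_start == pytest.approx(8.0, abs=1.5)
        assert events[0].t_end == pytest.approx(30.0, abs=1.5)

    def test_d_dance_monotonicity(self, geometry):
        """A wider distance envelope never loses dancing events."""
        truth = simulate_population(geometry, "FYVE", 8, 60.0, seed=13,
                                    n_dancing_pairs=3, n_fusion_pairs=0)
        tracks = truth.as_tracks()
        n = []
        for d in (1.2, 2.0, 2.6):
            params = InteractionParams(d_dance=d)
            n.append(len(detect_dancing(tracks, params)))
        assert n[0] <= n[1] <= n[2] or n == sorted(n)


class TestDetectClusterFusion:
    def test_no_merges_no_events(self):
        xy = np.column_stack([np.linspace(0, 8, 80), np.zeros(80)])
        tracks = make_tracks({0: xy, 1: xy + [0, 6.0]})
        assert detect_cluster_fusion(tracks) == []

    def test_scripted_fusion_ratio(self, geometry):
        """Members of 100 and 150 a.u. fuse into a 250 a.u. product: one
        event with ratio 2.5 relative to the dimmer member."""
        truth = simulate_population(geometry, "FYVE", 2, 60.0, seed=5,
                                    n_dancing_pairs=0,
                                    fusion_specs=[(100.0, 150.0, 10.0)])
        events = detect_cluster_fusion(truth.as_tracks())
        assert len(events) == 1
        ev = events[0]
        assert set(ev.member_track_ids) == {0, 1}
        assert ev.intensity_ratio == pytest.approx(2.5, rel=0.02)
        assert ev.t_start == pytest.approx(10.0, abs=0.2)

    def test_merge_into_continuing_track(self):
        """Pattern: one member ends next to a continuing track whose
        intensity steps up to the sum and stays."""
        n = 400
        xy_b = np.column_stack([np.linspace(5, 25, n), np.full(n, 6.0)])
        k = 150
        xy_a = xy_b[:k] + [0.4, 0.3]
        i_b = np.concatenate([np.full(k, 3.0), np.full(n - k, 5.0)])
        tracks = make_tracks({0: xy_a, 1: xy_b},
                             intensities={0: 2.0, 1: i_b})
        events = detect_cluster_fusion(tracks)
        assert len(events) == 1
        assert events[0].product_track_id == 1

    def test_transient_colocalization_rejected(self):
        """A 5 s co-localization with a temporary intensity rise is not a
        fusion (persistence rule)."""
        n = 400
        xy_b = np.column_stack([np.linspace(5, 25, n), np.full(n, 6.0)])
        k = 150
        xy_a = xy_b[:k] + [0.4, 0.3]
        i_b = np.full(n, 3.0)
        i_b[k:k + 50] = 5.0               # elevated for 5 s only
        tracks = make_tracks({0: xy_a, 1: xy_b},
                             intensities={0: 2.0, 1: i_b})
        assert detect_cluster_fusion(tracks) == []

    def test_occlusion_without_intensity_sum_rejected(self, geometry):
        truth = simulate_population(geometry, "FYVE", 8, 60.0, seed=9,
                                    n_dancing_pairs=0, n_fusion_pairs=0,
                                    n_transient_pairs=2, n_occlusion_pairs=2)
        assert detect_cluster_fusion(truth.as_tracks()) == []

    def test_persistence_monotonicity(self, geometry):
        """Raising the persistence requirement never adds fusion events."""
        truth = simulate_population(geometry, "FYVE", 6, 60.0, seed=2,
                                    n_dancing_pairs=0, n_fusion_pairs=3)
        tracks = truth.as_tracks()
        counts = [len(detect_cluster_fusion(
            tracks, InteractionParams(fusion_persistence=p)))
            for p in (10.0, 20.0, 45.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_members_consumed_once(self, geometry):
        """Each fused product's members appear in exactly one event."""
        truth = simulate_population(geometry, "FYVE", 8, 60.0, seed=6,
                                    n_dancing_pairs=0, n_fusion_pairs=4)
        events = detect_cluster_fusion(truth.as_tracks())
        members = [m for e in events for m in e.member_track_ids]
        assert len(members) == len(set(members))

    def test_mutual_exclusion_with_dancing(self, geometry):
        """No pair is reported both dancing and fusing over a window."""
        truth = simulate_population(geometry, "FYVE", 12, 60.0, seed=17,
                                    n_dancing_pairs=2, n_fusion_pairs=2)
        tracks = truth.as_tracks()
        dancing = detect_dancing(tracks)
        fusion = detect_cluster_fusion(tracks)
        d_pairs = {frozenset(e.member_track_ids) for e in dancing
                   if e.type == "dancing"}
        f_pairs = {frozenset(e.member_track_ids) for e in fusion}
        assert not d_pairs & f_pairs


class TestPopulationAndRates:
    @pytest.fixture
    def mask(self):
        axis = AxisFrame([[51.0, 6.0], [1.0, 6.0]])
        hair = np.zeros((47, 203), dtype=bool)
        hair[4:43, 4:197] = True
        return make_zone_mask((47, 203), axis, hair, pixel_size=0.26)

    @staticmethod
    def tracks_n(n):
        return make_tracks({i: np.tile([2.0 + i, 6.0], (30, 1))
                            for i in range(n)})

    def test_no_events_all_individual(self, mask):
        counts = classify_population(self.tracks_n(5), [], mask)
        assert counts["individual"] == 5
        assert counts["dancing"] == counts["clustered"] == 0

    def test_label_arithmetic(self, mask):
        events = [
            InteractionEvent("dancing", (0, 1), 1.0, 12.0),
            InteractionEvent("cluster_fusion", (2, 3), 2.0, 30.0),
        ]
        counts = classify_population(self.tracks_n(10), events, mask)
        assert (counts["individual"], counts["dancing"], counts["clustered"]) \
            == (6, 2, 2)

    def test_fusion_precedence_over_dancing(self, mask):
        events = [
            InteractionEvent("dancing", (0, 1), 1.0, 12.0),
            InteractionEvent("cluster_fusion", (1, 2), 15.0, 30.0),
        ]
        counts = classify_population(self.tracks_n(4), events, mask)
        assert counts["clustered"] == 2
        assert counts["dancing"] == 1       # track 0 only
        assert counts["labels"][1] == "clustered"

    def test_population_counted_in_tip_roi(self, mask):
        # tip at x=51; tracks at 2+i um from base -> distance below tip ~49-i
        tracks = make_tracks({
            0: np.tile([45.0, 6.0], (5, 1)),   # 6 um below tip: in ROI
            1: np.tile([10.0, 6.0], (5, 1)),   # 41 um below tip: outside
        })
        counts = classify_population(tracks, [], mask)
        assert counts["population_first_frame"] == 1

    def test_event_rates_arithmetic(self, mask):
        events = [InteractionEvent("dancing", (i, i + 10), 1.0, 5.0,
                                   x=46.0, y=6.0) for i in range(4)]
        rates = event_rates(events, mask, observation_duration=20.0)
        assert rates["apical"]["dancing"] == pytest.approx(0.2)
        assert rates["subapical"]["dancing"] == 0.0

    def test_zone_boundaries(self, mask):
        # tip at x = 51 um: 8 um below tip -> apical, 12 um -> subapical
        ev_api = InteractionEvent("dancing", (0, 1), 0.0, 6.0, x=43.0, y=6.0)
        ev_sub = InteractionEvent("cluster_fusion", (2, 3), 0.0, 25.0,
                                  x=39.0, y=6.0)
        rates = event_rates([ev_api, ev_sub], mask, 10.0)
        assert rates["apical"]["dancing"] == pytest.approx(0.1)
        assert rates["subapical"]["cluster_fusion"] == pytest.approx(0.1)

    def test_zero_events(self, mask):
        rates = event_rates([], mask, 10.0)
        assert all(v == 0.0 for zone in rates.values() for v in zone.values())

    def test_zero_duration_rejected(self, mask):
        with pytest.raises(ValueError, match="positive"):
            event_rates([], mask, 0.0)
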