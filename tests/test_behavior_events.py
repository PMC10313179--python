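"""Chase classification, detector-box attribution, and chaining logic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_tracks, straight_run
from flytrax.arena_io import ArenaConfig
from flytrax.behavior_events import (
    BehaviorEvent,
    ChainRecord,
    ChaseParams,
    attribute_detector_events,
    chain_components,
    classify_kinematic_chases,
    detect_chaining,
    events_active_per_frame,
)
from flytrax.synthetic_arena import Chase, ScenarioScript, simulate
from flytrax.tracking import TrackerParams, assign_heads, link_detections


def brute_force_chain_count(edges):
    """Independent oracle: enumerate undirected components by flood fill,
    count edges per component, sum (|flies| - 1) over components with >= 2
    distinct edges."""
    edges = set(edges)
    nodes = {v for e in edges for v in e}
    seen, total = set(), 0
    for start in sorted(nodes):
        if start in seen:
            continue
        comp, frontier = {start}, [start]
        while frontier:
            u = frontier.pop()
            for a, b in edges:
                for v in ((b,) if a == u else (a,) if b == u else ()):
                    if v not in comp:
                        comp.add(v)
                        frontier.append(v)
        seen |= comp
        n_edges = sum(1 for a, b in edges if a in comp)
        if n_edges >= 2 and len(comp) >= 3:
            total += len(comp) - 1
    return total


class TestChainComponents:
    def test_single_edge_is_never_chaining(self):
        assert chain_components([(1, 2)]) == ()

    def test_two_chases_of_one_target_form_a_chain(self):
        comps = chain_components([(1, 3), (2, 3)])
        assert comps == (frozenset({1, 2, 3}),)
        assert ChainRecord(0, comps).chain_count == 2

    def test_ring_of_ten_counts_n_minus_one(self):
        edges = [(i, i % 10 + 1) for i in range(1, 11)]
        comps = chain_components(edges)
        assert comps == (frozenset(range(1, 11)),)
        assert ChainRecord(0, comps).chain_count == 9

    def test_path_over_n_flies_counts_n_minus_one(self):
        for n in (3, 5, 8, 13):
            edges = [(i, i + 1) for i in range(1, n)]
            assert ChainRecord(0, chain_components(edges)).chain_count == n - 1

    def test_two_disjoint_chains_sum(self):
        edges = [(1, 2), (2, 3), (7, 8), (9, 8)]
        rec = ChainRecord(0, chain_components(edges))
        assert rec.chain_count == 2 + 2
        assert len(rec.components) == 2

    def test_parallel_edges_collapse(self):
        # two chase events on the same ordered pair are one relation
        assert chain_components([(1, 2), (1, 2)]) == ()

    @settings(max_examples=300, deadline=None)
    @given(
        n=st.integers(3, 8),
        edges=st.data(),
    )
    def test_random_digraphs_match_enumeration_oracle(self, n, edges):
        pairs = [(a, b) for a in range(1, n + 1) for b in range(1, n + 1) if a != b]
        chosen = edges.draw(st.lists(st.sampled_from(pairs), max_size=12))
        rec = ChainRecord(0, chain_components(chosen))
        assert rec.chain_count == brute_force_chain_count(chosen)
        # structural invariants
        flat = [v for c in rec.components for v in c]
        assert len(flat) == len(set(flat))  # disjoint
        assert all(len(c) >= 3 for c in rec.components)
        assert rec.chain_count <= n - 1


class TestDetectChaining:
    def test_frames_without_edges_yield_zero(self):
        recs = detect_chaining([], (0, 5), n=10)
        assert [r.chain_count for r in recs] == [0] * 5

    def test_events_toggle_chain_membership_over_time(self):
        events = [
            BehaviorEvent("chase", 0, 10, 1, 3),
            BehaviorEvent("chase", 5, 15, 2, 3),
        ]
        recs = detect_chaining(events, (0, 15), n=5)
        counts = [r.chain_count for r in recs]
        assert counts == [0] * 5 + [2] * 5 + [0] * 5


class TestKinematicChases:
    def test_stationary_flies_produce_no_events(self, pair_config):
        pos = [[(100, 100), (300, 100)]] * 60  # 10 mm apart, no motion
        tracks = make_tracks(pos)
        assert classify_kinematic_chases(tracks, pair_config) == []

    def test_close_but_reversed_heading_produces_no_events(self, pair_config):
        # follower within 3 mm of leader but heading 180 degrees away
        heads = [[math.pi, 0.0]] * 60
        pos = [[(100 + 4 * f, 100), (160 + 4 * f, 100)] for f in range(60)]
        tracks = make_tracks(pos, fps_heading=heads)
        assert classify_kinematic_chases(tracks, pair_config) == []

    def test_scripted_follower_yields_one_event_covering_frames(self, pair_config):
        # follower 3 mm (60 px) behind a leader walking +x at 4 px/frame (6 mm/s)
        heads = [[0.0, 0.0]] * 60
        pos = [[(100 + 4 * f, 100), (160 + 4 * f, 100)] for f in range(60)]
        tracks = make_tracks(pos, fps_heading=heads)
        events = classify_kinematic_chases(tracks, pair_config)
        assert len(events) == 1
        ev = events[0]
        assert (ev.actor_id, ev.target_id, ev.source) == (1, 2, "kinematic")
        assert ev.n_frames >= 55

    def test_actor_unique_per_frame_prefers_nearer_target(self):
        config = ArenaConfig(n=3, mm_per_px=0.05)
        heads = [[0.0, 0.0, 0.0]] * 40
        # targets at 2 mm and 4 mm ahead, both inside the gate
        pos = [[(100 + 4 * f, 100), (140 + 4 * f, 100), (180 + 4 * f, 100)] for f in range(40)]
        tracks = make_tracks(pos, fps_heading=heads)
        events = classify_kinematic_chases(tracks, config)
        mine = [e for e in events if e.actor_id == 1]
        assert {e.target_id for e in mine} == {2}

    def test_loosening_thresholds_never_loses_chase_frames(self, config):
        sim = simulate(
            ScenarioScript(n=13, duration=150, seed=9, directives=(
                Chase(actor=1, target=2, start=0, end=150),
                Chase(actor=3, target=4, start=20, end=120),
            )),
            config,
        )
        tracks = assign_heads(link_detections(sim.detections, config),
                              sim.detections, TrackerParams())
        tight = ChaseParams()
        loose = ChaseParams(d_max_mm=8.0, v_min_mm_s=1.0, align_max_rad=math.pi / 3,
                            min_frames=10, merge_gap_frames=8)
        fr = (int(tracks["frame"].min()), int(tracks["frame"].max()) + 1)
        frames_tight = events_active_per_frame(classify_kinematic_chases(tracks, config, tight), fr, "chase").sum()
        frames_loose = events_active_per_frame(classify_kinematic_chases(tracks, config, loose), fr, "chase").sum()
        assert frames_loose >= frames_tight > 0

    def test_single_fly_returns_empty(self):
        config = ArenaConfig(n=1, mm_per_px=0.05)
        tracks = make_tracks([[(100, 100)]] * 30)
        assert classify_kinematic_chases(tracks, config) == []


class TestDetectorAttribution:
    def _tracks_two_flies(self, n_frames=1):
        heads = [[0.0, math.pi]] * n_frames  # fly 1 faces fly 2; fly 2 faces away
        pos = [[(100, 100), (160, 100)]] * n_frames
        return make_tracks(pos, fps_heading=heads)

    def test_chase_box_actor_is_the_aligned_member(self, pair_config):
        # both flies covered; fly 1's heading (0) points at fly 2 -> actor 1
        tracks = self._tracks_two_flies(5)
        boxes = pd.DataFrame([{"frame": f, "label": "chase", "conf": 1.0,
                               "x": 90, "y": 95, "w": 80, "h": 10} for f in range(5)])
        events = attribute_detector_events(boxes, tracks, pair_config)
        assert len(events) == 1
        ev = events[0]
        assert (ev.type, ev.actor_id, ev.target_id, ev.source) == ("chase", 1, 2, "detector")
        assert (ev.start_frame, ev.end_frame) == (0, 5)

    def test_wing_ext_box_over_one_fly(self, pair_config):
        heads = [[0.0, 0.0]]
        pos = [[(100, 100), (300, 300)]]
        tracks = make_tracks(pos, fps_heading=heads)
        box = pd.DataFrame([{"frame": 0, "label": "wing_ext", "conf": 1.0,
                             "x": 92, "y": 95, "w": 16, "h": 10}])
        events = attribute_detector_events(box, tracks, pair_config)
        assert len(events) == 1
        assert events[0].type == "wing_ext" and events[0].actor_id == 1
        assert events[0].target_id is None  # fly 2 is outside the heading cone

    def test_wing_ext_cone_target(self, pair_config):
        heads = [[0.0, 0.0]]
        pos = [[(100, 100), (180, 100)]]  # fly 2 dead ahead of fly 1
        tracks = make_tracks(pos, fps_heading=heads)
        box = pd.DataFrame([{"frame": 0, "label": "wing_ext", "conf": 1.0,
                             "x": 92, "y": 95, "w": 16, "h": 10}])
        events = attribute_detector_events(box, tracks, pair_config)
        assert events[0].target_id == 2

    def test_orphan_box_dropped(self, pair_config):
        tracks = self._tracks_two_flies()
        box = pd.DataFrame([{"frame": 0, "label": "chase", "conf": 1.0,
                             "x": 600, "y": 600, "w": 20, "h": 20}])
        assert attribute_detector_events(box, tracks, pair_config) == []

    def test_jittered_simulator_boxes_attribute_perfectly(self, config):
        """Detector-style chase boxes jittered by simulation noise still map to
        the right actor/target pairs."""
        sim = simulate(
            ScenarioScript(n=13, duration=60, seed=21, emit_detector_events=True,
                           jitter_sigma_px=1.0,
                           directives=(Chase(1, 2, 0, 60), Chase(3, 4, 0, 60))),
            config,
        )
        # attribute against ground-truth tracks (which carry true ids/headings)
        events = attribute_detector_events(
            sim.detections[sim.detections["label"] == "chase"], sim.truth_tracks, config)
        pairs = {(e.actor_id, e.target_id) for e in events}
        assert pairs == {(1, 2), (3, 4)}
        total = sum(e.n_frames for e in events)
        assert total == 120  # every box attributed, none dropped
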