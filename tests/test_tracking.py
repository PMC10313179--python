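"""Distance-sort linking, coasting, head assignment and corrections."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from flytrax.arena_io import ArenaConfig
from flytrax.synthetic_arena import ScenarioScript, Tether, initial_positions, simulate
from flytrax.tracking import Correction, TrackerParams, apply_corrections, assign_heads, link_detections


def det_row(frame, label, cx, cy, w=12.0, h=6.0, conf=1.0):
    return {"frame": frame, "label": label, "conf": conf,
            "x": cx - w / 2, "y": cy - h / 2, "w": w, "h": h, "cx": cx, "cy": cy}


def dets(rows):
    return pd.DataFrame(rows)


class TestLinkDetections:
    def test_single_fly_two_frames(self):
        config = ArenaConfig(n=1, mm_per_px=0.05)
        d = dets([det_row(0, "body", 100, 100), det_row(1, "body", 110, 105)])
        tracks = link_detections(d, config)
        assert list(tracks["id"]) == [1, 1]
        assert list(tracks["observed"]) == [True, True]
        assert list(tracks["cx"]) == [100, 110]

    def test_empty_stream_yields_empty_tracks(self, pair_config):
        tracks = link_detections(dets([]).reindex(columns=["frame", "label", "conf", "x", "y", "w", "h"]),
                                 pair_config)
        assert len(tracks) == 0

    def test_gap_frame_coasts_all_tracks(self, pair_config):
        d = dets([
            det_row(0, "body", 100, 100), det_row(0, "body", 300, 300),
            # frame 1 empty
            det_row(2, "body", 104, 100), det_row(2, "body", 304, 300),
        ])
        tracks = link_detections(d, pair_config)
        f1 = tracks[tracks["frame"] == 1].sort_values("id")
        assert list(f1["observed"]) == [False, False]
        assert list(f1["cx"]) == [100, 300]  # parked at previous positions
        f2 = tracks[tracks["frame"] == 2].sort_values("id")
        assert list(f2["observed"]) == [True, True]
        assert list(f2["cx"]) == [104, 304]

    def test_coasting_fixpoint_repeats_anchor(self):
        config = ArenaConfig(n=2, mm_per_px=0.05)
        rows = [det_row(0, "body", 100, 100), det_row(0, "body", 300, 300)]
        for f in range(1, 6):  # fly 2 vanishes for 5 frames
            rows.append(det_row(f, "body", 100 + 2 * f, 100))
        rows.append(det_row(6, "body", 112, 100))
        rows.append(det_row(6, "body", 302, 300))
        tracks = link_detections(dets(rows), config)
        coasting = tracks[(tracks["id"] == 2) & (~tracks["observed"])]
        assert len(coasting) == 5
        assert set(coasting["cx"]) == {300} and set(coasting["cy"]) == {300}
        assert tracks[(tracks["id"] == 2) & (tracks["frame"] == 6)]["observed"].item()

    def test_first_frame_ids_by_y_then_x(self, pair_config):
        d = dets([det_row(0, "body", 300, 50), det_row(0, "body", 100, 200)])
        tracks = link_detections(d, pair_config)
        f0 = tracks[tracks["frame"] == 0]
        assert f0[f0["id"] == 1]["cy"].item() == 50  # smaller y gets id 1
        assert f0[f0["id"] == 2]["cy"].item() == 200

    def test_fixed_population_drops_surplus_and_reconciles(self):
        config = ArenaConfig(n=1, mm_per_px=0.05)
        d = dets([
            det_row(0, "body", 100, 100),
            det_row(1, "body", 102, 100), det_row(1, "body", 500, 500),
        ])
        tracks, dropped = link_detections(d, config, return_dropped=True)
        assert len(tracks) == 2 and set(tracks["id"]) == {1}
        assert len(dropped) == 1 and dropped["cx"].item() == 500
        # conservation: every body detection is a track point or dropped
        assert tracks["observed"].sum() + len(dropped) == 3

    def test_population_constant_after_initialization(self, config):
        """Under fixed population the ID set never changes after frame one,
        even when detector dropout hides flies for stretches of frames."""
        sim = simulate(ScenarioScript(n=13, duration=200, seed=5, dropout=0.1), config)
        with pytest.warns(UserWarning, match="first populated frame"):
            tracks = link_detections(sim.detections, config)
        per_frame_ids = tracks.groupby("frame")["id"].agg(lambda s: tuple(sorted(s)))
        first = per_frame_ids.iloc[0]
        assert set(per_frame_ids) == {first}
        assert first == tuple(range(1, len(first) + 1))

    def test_matches_hungarian_on_well_separated_instance(self, config):
        """Greedy distance-sort equals optimal assignment when gaps dominate steps."""
        script = ScenarioScript(
            n=13, duration=300, step_sigma_px=3.0, seed=11,
            directives=tuple(Tether(fly=i, radius_px=20.0) for i in range(1, 14)),
        )
        sim = simulate(script, config)
        _assert_perfect_and_hungarian_equal(sim, config)


def _assert_perfect_and_hungarian_equal(sim, config):
    """Linker output carries ground-truth ids and equals per-frame Hungarian."""
    tracks = link_detections(sim.detections, config)
    truth = sim.truth_tracks
    # ground-truth accuracy modulo the fixed first-frame relabeling
    t0 = tracks[tracks["frame"] == 0].sort_values("id")
    g0 = truth[truth["frame"] == 0]
    relabel = {}
    for _, row in t0.iterrows():
        m = g0[(g0["cx"] == row["cx"]) & (g0["cy"] == row["cy"])]
        relabel[row["id"]] = m["id"].item()
    merged = tracks.assign(gid=tracks["id"].map(relabel)).merge(
        truth, left_on=("frame", "gid"), right_on=("frame", "id"), suffixes=("", "_t"))
    assert len(merged) == len(tracks)
    assert (merged["cx"] == merged["cx_t"]).all() and (merged["cy"] == merged["cy_t"]).all()

    # per-frame Hungarian on the same cost matrices reproduces the same links
    prev = tracks[tracks["frame"] == 0].sort_values("id")[["id", "cx", "cy"]]
    frames = sorted(tracks["frame"].unique())
    body = sim.detections[sim.detections["label"] == "body"]
    for f in frames[1:]:
        cur = body[body["frame"] == f]
        cost = np.hypot(prev["cx"].to_numpy()[:, None] - cur["cx"].to_numpy()[None, :],
                        prev["cy"].to_numpy()[:, None] - cur["cy"].to_numpy()[None, :])
        ri, ci = linear_sum_assignment(cost)
        hungarian = {prev["id"].iloc[r]: (cur["cx"].iloc[c], cur["cy"].iloc[c]) for r, c in zip(ri, ci)}
        ours = tracks[(tracks["frame"] == f) & tracks["observed"]]
        got = {row["id"]: (row["cx"], row["cy"]) for _, row in ours.iterrows()}
        assert got == hungarian
        prev = tracks[tracks["frame"] == f].sort_values("id")[["id", "cx", "cy"]]


class TestAssignHeads:
    def test_head_right_of_body_gives_zero_heading(self, pair_config):
        body = dets([det_row(0, "body", 100, 100), det_row(0, "body", 300, 300)])
        tracks = link_detections(body, pair_config)
        heads = dets([det_row(0, "head", 104, 100, w=6, h=6)])
        out = assign_heads(tracks, heads, TrackerParams())
        h = out[(out["frame"] == 0) & (out["cx"] == 100)]["heading"].item()
        assert h == pytest.approx(0.0)

    def test_head_above_body_gives_plus_half_pi(self, pair_config):
        body = dets([det_row(0, "body", 100, 100), det_row(0, "body", 300, 300)])
        tracks = link_detections(body, pair_config)
        heads = dets([det_row(0, "head", 100, 97, w=6, h=6)])  # smaller image-y
        out = assign_heads(tracks, heads, TrackerParams())
        h = out[(out["frame"] == 0) & (out["cx"] == 100)]["heading"].item()
        assert h == pytest.approx(math.pi / 2)

    def test_orphan_head_is_skipped(self, pair_config):
        body = dets([det_row(0, "body", 100, 100), det_row(0, "body", 300, 300)])
        tracks = link_detections(body, pair_config)
        heads = dets([det_row(0, "head", 600, 600, w=6, h=6)])
        out = assign_heads(tracks, heads, TrackerParams())
        assert out["heading"].isna().all()

    def test_simulated_headings_recovered_exactly(self, config):
        """Noiseless synthetic head boxes recover the true heading to < 1e-6 rad."""
        sim = simulate(ScenarioScript(n=13, duration=100, seed=2), config)
        tracks = link_detections(sim.detections, config)
        tracks = assign_heads(tracks, sim.detections, TrackerParams())
        relabel = _first_frame_relabel(tracks, sim.truth_tracks)
        merged = tracks.assign(gid=tracks["id"].map(relabel)).merge(
            sim.truth_tracks, left_on=("frame", "gid"), right_on=("frame", "id"), suffixes=("", "_t"))
        got, want = merged["heading"].to_numpy(), merged["heading_t"].to_numpy()
        assert not np.isnan(got).any()
        err = np.abs(np.angle(np.exp(1j * (got - want))))
        assert err.mean() < 1e-6


def _first_frame_relabel(tracks, truth):
    t0 = tracks[tracks["frame"] == 0]
    g0 = truth[truth["frame"] == 0]
    return {
        row["id"]: g0[(g0["cx"] == row["cx"]) & (g0["cy"] == row["cy"])]["id"].item()
        for _, row in t0.iterrows()
    }


class TestCorrections:
    def _tracks(self):
        rows = []
        for f in range(20):
            rows += [det_row(f, "body", 100 + f, 100), det_row(f, "body", 300, 300 + f)]
        return link_detections(dets(rows), ArenaConfig(n=2, mm_per_px=0.05))

    def test_swap_is_involution(self):
        tracks = self._tracks()
        c = Correction(frame=10, id_a=1, id_b=2)
        twice = apply_corrections(apply_corrections(tracks, [c]), [c])
        pd.testing.assert_frame_equal(twice, tracks)

    def test_swap_changes_ids_from_frame_onward(self):
        tracks = self._tracks()
        out = apply_corrections(tracks, [Correction(frame=10, id_a=1, id_b=2)])
        before = out[(out["frame"] == 9) & (out["id"] == 1)]["cx"].item()
        after = out[(out["frame"] == 10) & (out["id"] == 2)]["cx"].item()
        assert before == 109 and after == 110  # id 1's geometry now under id 2

    def test_swap_with_one_sided_track_conserves_points(self):
        rows = [det_row(f, "body", 100 + f, 100) for f in range(5)]  # id 1 ends at f=4
        rows += [det_row(f, "body", 300, 300 + f) for f in range(20)]
        tracks = link_detections(dets(rows), ArenaConfig(n=2, mm_per_px=0.05))
        # drop id 1's coasting tail to make it genuinely end early
        tracks = tracks[~((tracks["id"] == 1) & (~tracks["observed"]))].reset_index(drop=True)
        out = apply_corrections(tracks, [Correction(frame=10, id_a=1, id_b=2)])
        assert len(out) == len(tracks)
        assert (out[out["frame"] >= 10]["id"] == 1).sum() == 10  # old id 2 points relabeled

    def test_unknown_id_raises(self):
        with pytest.raises(KeyError, match="99"):
            apply_corrections(self._tracks(), [Correction(frame=0, id_a=1, id_b=99)])

    def test_identical_ids_rejected(self):
        with pytest.raises(ValueError):
            Correction(frame=0, id_a=3, id_b=3)

    def test_scripted_crossing_corrected_to_full_accuracy(self):
        """A crossing that fools greedy linking is fully repaired by one swap."""
        config = ArenaConfig(n=2, mm_per_px=0.05)
        rows = []
        # two flies swap positions during a 1-frame mutual occlusion at f=10:
        # fly A walks right along y=100, fly B walks left along y=104; at the
        # crossing the detector reports them at swapped continuation points.
        for f in range(21):
            ax = 100.0 + 10 * f
            bx = 300.0 - 10 * f
            if f < 10:
                rows += [det_row(f, "body", ax, 100), det_row(f, "body", bx, 104)]
            else:
                # identities swap: the fly continuing A's line is truly B
                rows += [det_row(f, "body", ax, 104), det_row(f, "body", bx, 100)]
        tracks = link_detections(dets(rows), config)
        # greedy keeps spatial continuity, so ids 1/2 now follow the wrong flies
        out = apply_corrections(tracks, [Correction(frame=10, id_a=1, id_b=2)])
        # after correction, id 1 (started at y=100) is on y=104 from f>=10: the true fly
        a_pts = out[out["id"] == 1].sort_values("frame")
        assert list(a_pts["cy"][:10]) == [100] * 10
        assert list(a_pts["cy"][10:]) == [104] * 11
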