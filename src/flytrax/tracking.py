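"""Link per-frame body detections into identity-stable tracks.

The linker implements greedy "distance-sort" association: in each frame all
candidate (track, detection) pairs within a distance gate are sorted by
ascending centroid distance and accepted greedily while both sides are still
unmatched, so each fly inherits the ID of its nearest neighbor in the previous
frame.  A track whose fly is lost (occluded, missed by the detector) *coasts*:
its ID stays parked at the last observed position until the fly reappears —
there is no coasting timeout.  Identity switches that survive the greedy rule
are repaired with explicit :class:`Correction` records (the programmatic
counterpart of a manual review pass).

Tracks are plain :class:`pandas.DataFrame` objects in the dialect of
:mod:`flytrax.arena_io` (columns ``frame, id, x, y, w, h, conf, observed,
heading, cx, cy``), one row per (frame, track) pair.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .arena_io import ArenaConfig, empty_tracks

__all__ = [
    "Correction",
    "TrackerParams",
    "apply_corrections",
    "assign_heads",
    "link_detections",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrackerParams:
    """Tuning knobs of the distance-sort linker.

    gate_px
        Maximum centroid distance (pixels) a track may move in one frame step
        and still be matched; candidate pairs beyond the gate are never linked.
    fixed_population
        When true (the default, matching a closed chamber with a known group
        size) the set of track IDs is frozen after the first populated frame:
        surplus detections are dropped with a warning instead of opening new
        tracks.
    head_overlap_min
        Minimum fraction of a head box's area that must overlap a body box for
        the head to be assigned to that track.
    """

    gate_px: float = 30.0
    fixed_population: bool = True
    head_overlap_min: float = 0.25

    def __post_init__(self):
        if not self.gate_px > 0:
            raise ValueError(f"gate_px must be > 0, got {self.gate_px}")
        if not 0 < self.head_overlap_min <= 1:
            raise ValueError(f"head_overlap_min must be in (0, 1], got {self.head_overlap_min}")


@dataclass(frozen=True)
class Correction:
    """Swap track ids ``id_a`` and ``id_b`` from ``frame`` onward (inclusive)."""

    frame: int
    id_a: int
    id_b: int

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError("correction must name two distinct ids")


def _point(frame: int, tid: int, x, y, w, h, conf, observed: bool) -> dict:
    return {
        "frame": frame, "id": tid, "x": x, "y": y, "w": w, "h": h,
        "conf": conf, "observed": observed, "heading": math.nan,
        "cx": x + w / 2.0, "cy": y + h / 2.0,
    }


def link_detections(
    detections: pd.DataFrame,
    config: ArenaConfig,
    params: TrackerParams | None = None,
    return_dropped: bool = False,
):
    """Link body detections into tracks by greedy distance-sort.

    Parameters
    ----------
    detections : DataFrame
        Detections in the :func:`flytrax.arena_io.read_detections` layout;
        only rows with ``label == "body"`` are linked.
    config : ArenaConfig
        Supplies the expected group size ``n`` under ``fixed_population``.
    params : TrackerParams, optional
    return_dropped : bool
        When true, also return the DataFrame of body detections that were
        dropped (gated out or surplus under a fixed population), so that
        input detections reconcile exactly with track points plus drops.

    Returns
    -------
    tracks : DataFrame
        One row per (frame, id); IDs ``1..k`` are assigned in the first
        populated frame by ascending ``(cy, cx)`` of the centroid.  Unmatched
        tracks coast: they repeat their last observed geometry with
        ``observed=False`` until re-matched.  An empty detection stream
        yields an empty track set.
    """
    params = params or TrackerParams()
    body = detections[detections["label"] == "body"] if len(detections) else detections
    if len(body) == 0:
        return (empty_tracks(), body.copy()) if return_dropped else empty_tracks()
    if "cx" not in body.columns:
        body = body.assign(cx=body["x"] + body["w"] / 2.0, cy=body["y"] + body["h"] / 2.0)

    frames = body.groupby("frame", sort=True)
    frame_ids = list(frames.groups)
    first_frame, last_frame = frame_ids[0], frame_ids[-1]

    rows: list[dict] = []
    dropped: list[int] = []  # positional indices into `body`

    # --- first populated frame: ids 1..k by ascending (cy, cx)
    f0 = frames.get_group(first_frame).sort_values(["cy", "cx"], kind="mergesort")
    if params.fixed_population and len(f0) != config.n:
        warnings.warn(
            f"first populated frame has {len(f0)} body detections, expected n={config.n}; "
            f"proceeding with {len(f0)} tracks",
            stacklevel=2,
        )
    anchors: dict[int, dict] = {}  # id -> last observed point
    for tid, (_, det) in enumerate(f0.iterrows(), start=1):
        pt = _point(first_frame, tid, det["x"], det["y"], det["w"], det["h"], det["conf"], True)
        rows.append(pt)
        anchors[tid] = pt

    lookup = {f: frames.get_group(f) for f in frame_ids}
    for frame in range(first_frame + 1, last_frame + 1):
        dets = lookup.get(frame)
        ids = sorted(anchors)
        if dets is None or len(dets) == 0:
            for tid in ids:
                a = anchors[tid]
                rows.append(_point(frame, tid, a["x"], a["y"], a["w"], a["h"], math.nan, False))
            continue

        # candidate pairs within the gate, ascending by (distance, id, cy, cx)
        ax = np.array([anchors[t]["cx"] for t in ids])
        ay = np.array([anchors[t]["cy"] for t in ids])
        dx = dets["cx"].to_numpy()[None, :] - ax[:, None]
        dy = dets["cy"].to_numpy()[None, :] - ay[:, None]
        dist = np.hypot(dx, dy)
        ti, di = np.nonzero(dist <= params.gate_px)
        order = sorted(
            range(len(ti)),
            key=lambda k: (dist[ti[k], di[k]], ids[ti[k]], dets["cy"].iat[di[k]], dets["cx"].iat[di[k]]),
        )
        matched_t: set[int] = set()
        matched_d: set[int] = set()
        for k in order:
            t, d = int(ti[k]), int(di[k])
            if t in matched_t or d in matched_d:
                continue
            matched_t.add(t)
            matched_d.add(d)
            det = dets.iloc[d]
            pt = _point(frame, ids[t], det["x"], det["y"], det["w"], det["h"], det["conf"], True)
            rows.append(pt)
            anchors[ids[t]] = pt

        for t, tid in enumerate(ids):
            if t not in matched_t:
                a = anchors[tid]
                rows.append(_point(frame, tid, a["x"], a["y"], a["w"], a["h"], math.nan, False))

        leftovers = [d for d in range(len(dets)) if d not in matched_d]
        if leftovers:
            if params.fixed_population:
                logger.warning("frame %d: dropped %d surplus body detection(s)", frame, len(leftovers))
                dropped.extend(dets.index[leftovers])
            else:
                new = dets.iloc[leftovers].sort_values(["cy", "cx"], kind="mergesort")
                next_id = max(anchors, default=0) + 1
                for _, det in new.iterrows():
                    pt = _point(frame, next_id, det["x"], det["y"], det["w"], det["h"], det["conf"], True)
                    rows.append(pt)
                    anchors[next_id] = pt
                    next_id += 1

    tracks = pd.DataFrame(rows).sort_values(["frame", "id"], kind="mergesort").reset_index(drop=True)
    tracks = tracks.astype({"frame": int, "id": int, "observed": bool})
    if return_dropped:
        return tracks, body.loc[dropped]
    return tracks


# ---------------------------------------------------------------------------
# head assignment
# ---------------------------------------------------------------------------


def _overlap_fraction(hx, hy, hw, hh, bx, by, bw, bh) -> np.ndarray:
    """Fraction of the head box area intersecting each body box."""
    ix = np.maximum(0.0, np.minimum(hx + hw, bx + bw) - np.maximum(hx, bx))
    iy = np.maximum(0.0, np.minimum(hy + hh, by + bh) - np.maximum(hy, by))
    return ix * iy / (hw * hh)


def assign_heads(
    tracks: pd.DataFrame,
    head_detections: pd.DataFrame,
    params: TrackerParams | None = None,
) -> pd.DataFrame:
    """Assign head boxes to body tracks and fill per-point headings.

    Each head box goes to the body track with the largest head-box overlap
    fraction (ties broken by nearest centroid); heads overlapping no body by
    at least ``head_overlap_min`` are skipped and counted in a log message.
    The heading is the angle of the vector from body centroid to head
    centroid in a y-up mathematical frame (image y negated), in (−π, π].
    Frames whose track received no head keep ``heading`` = NaN.
    """
    params = params or TrackerParams()
    tracks = tracks.copy()
    heads = head_detections[head_detections["label"] == "head"] if len(head_detections) else head_detections
    if len(tracks) == 0 or len(heads) == 0:
        return tracks
    if "cx" not in heads.columns:
        heads = heads.assign(cx=heads["x"] + heads["w"] / 2.0, cy=heads["y"] + heads["h"] / 2.0)

    tracks_by_frame = dict(tuple(tracks.groupby("frame", sort=True)))
    skipped = 0
    for frame, hgrp in heads.groupby("frame", sort=True):
        tgrp = tracks_by_frame.get(frame)
        if tgrp is None:
            skipped += len(hgrp)
            continue
        bx, by = tgrp["x"].to_numpy(), tgrp["y"].to_numpy()
        bw, bh = tgrp["w"].to_numpy(), tgrp["h"].to_numpy()
        bcx, bcy = tgrp["cx"].to_numpy(), tgrp["cy"].to_numpy()
        # best head per track: (overlap, -distance) maximized
        best: dict[int, tuple[float, float, float]] = {}  # row position -> (ov, -d, angle)
        for _, head in hgrp.iterrows():
            ov = _overlap_fraction(head["x"], head["y"], head["w"], head["h"], bx, by, bw, bh)
            d = np.hypot(head["cx"] - bcx, head["cy"] - bcy)
            eligible = ov >= params.head_overlap_min
            if not eligible.any():
                skipped += 1
                continue
            # maximize overlap; ties -> nearest centroid
            key = np.where(eligible, ov, -np.inf) * 1e9 - d
            j = int(np.argmax(np.where(eligible, key, -np.inf)))
            angle = math.atan2(-(head["cy"] - bcy[j]), head["cx"] - bcx[j])
            if angle <= -math.pi:
                angle += 2 * math.pi
            score = (float(ov[j]), float(-d[j]))
            if j not in best or score > best[j][:2]:
                best[j] = (*score, angle)
        for j, (_, _, angle) in best.items():
            tracks.loc[tgrp.index[j], "heading"] = angle
    if skipped:
        logger.info("assign_heads: %d head box(es) skipped (no body overlap >= %.2f)", skipped, params.head_overlap_min)
    return tracks


# ---------------------------------------------------------------------------
# ID-switch corrections
# ---------------------------------------------------------------------------


def apply_corrections(tracks: pd.DataFrame, corrections: Sequence[Correction]) -> pd.DataFrame:
    """Apply pairwise ID swaps from a frame onward.

    For each correction, all points of ``id_a`` and ``id_b`` at frames >=
    ``correction.frame`` exchange ids.  The operation is an involution:
    applying the same correction twice restores the input.  Unknown ids raise
    ``KeyError`` naming the id.
    """
    tracks = tracks.copy()
    known = set(tracks["id"].unique())
    for corr in corrections:
        for tid in (corr.id_a, corr.id_b):
            if tid not in known:
                raise KeyError(f"correction references unknown track id {tid}")
        late = tracks["frame"] >= corr.frame
        a = late & (tracks["id"] == corr.id_a)
        b = late & (tracks["id"] == corr.id_b)
        tracks.loc[a, "id"] = corr.id_b
        tracks.loc[b, "id"] = corr.id_a
    return tracks.sort_values(["frame", "id"], kind="mergesort").reset_index(drop=True)
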