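"""Typed behavior events and chaining analysis.

Courtship in male-male groups decomposes into a few stereotyped elements:
*chasing/following* (one fly pursuing another), *wing extension* ("singing",
the unilateral wing vibration of courtship song) and *mounting* (attempted
copulation).  This module produces such events along two routes:

* :func:`attribute_detector_events` ingests behavior boxes emitted by an
  object detector (classes ``chase``, ``wing_ext``, ``mount``) and attributes
  them to track identities by box overlap;
* :func:`classify_kinematic_chases` classifies chases directly from
  trajectories — close, fast, and aligned with the bearing to the target —
  for pipelines without a trained event detector.

*Chaining* is the group phenotype in which males form chains or rings, each
chasing the fly ahead.  Per frame, chase relations form a directed graph
(edge actor→target); a weakly connected component containing at least two
chase edges (hence at least three flies) is a chain, and the per-frame chain
count is B(d) = Σ over chain components of (|component| − 1).  Under this
formalization two chasers of one target form a chain, and a full path or ring
over all N flies yields the maximum B(max) = N − 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .arena_io import ArenaConfig

__all__ = [
    "BehaviorEvent",
    "ChainRecord",
    "ChaseParams",
    "attribute_detector_events",
    "classify_kinematic_chases",
    "detect_chaining",
    "events_active_per_frame",
]

logger = logging.getLogger(__name__)

EVENT_TYPES = ("chase", "wing_ext", "mount")


@dataclass(frozen=True)
class BehaviorEvent:
    """A typed behavior interval, half-open over frames [start, end).

    ``actor_id`` performs the behavior; ``target_id`` is the fly it is
    directed at (absent for an unattributed wing extension).  ``source``
    records whether the event came from detector boxes or from the kinematic
    classifier.
    """

    type: str
    start_frame: int
    end_frame: int
    actor_id: int
    target_id: int | None = None
    source: str = "detector"

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if not self.start_frame < self.end_frame:
            raise ValueError(f"empty interval [{self.start_frame}, {self.end_frame})")
        if self.target_id is not None and self.actor_id == self.target_id:
            raise ValueError("actor and target must differ")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def active_at(self, frame: int) -> bool:
        return self.start_frame <= frame < self.end_frame


@dataclass(frozen=True)
class ChaseParams:
    """Thresholds of the kinematic chase classifier.

    A fly is chasing a target in a frame when the actor→target gap is at most
    ``d_max_mm``, the actor moves at >= ``v_min_mm_s``, and the actor's
    heading is within ``align_max_rad`` of the bearing to the target.  Runs of
    such frames separated by gaps of at most ``merge_gap_frames`` are bridged,
    and only runs lasting >= ``min_frames`` become events (0.5 s at 30 fps by
    default).
    """

    d_max_mm: float = 5.0
    v_min_mm_s: float = 2.0
    align_max_rad: float = math.pi / 6
    min_frames: int = 15
    merge_gap_frames: int = 5

    def __post_init__(self):
        if min(self.d_max_mm, self.v_min_mm_s, self.align_max_rad, self.min_frames, self.merge_gap_frames) <= 0:
            raise ValueError("all ChaseParams must be strictly positive")
        if not self.align_max_rad < math.pi:
            raise ValueError("align_max_rad must be < pi")


@dataclass(frozen=True)
class ChainRecord:
    """Per-frame chain components of the chase graph.

    ``components`` are disjoint sets of fly ids, each of size >= 3;
    ``chain_count`` is B(d) = Σ (|component| − 1).
    """

    frame: int
    components: tuple[frozenset[int], ...] = ()

    @property
    def chain_count(self) -> int:
        return sum(len(c) - 1 for c in self.components)


def _angdiff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed smallest difference a − b, wrapped to (−π, π]."""
    d = np.asarray(a) - np.asarray(b)
    return -np.mod(math.pi - d, 2 * math.pi) + math.pi


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean vector."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), stops.tolist()))


def merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Bridge gaps of <= max_gap frames between consecutive half-open runs."""
    if not runs:
        return []
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] <= max_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return [tuple(r) for r in merged]


# ---------------------------------------------------------------------------
# kinematic chase classification
# ---------------------------------------------------------------------------


def _track_arrays(tracks: pd.DataFrame):
    """Pivot a tracks frame to dense (frames, ids, cx, cy, heading, observed)."""
    ids = np.array(sorted(tracks["id"].unique()))
    f0, f1 = int(tracks["frame"].min()), int(tracks["frame"].max())
    frames = np.arange(f0, f1 + 1)
    shape = (len(frames), len(ids))
    cx = np.full(shape, np.nan)
    cy = np.full(shape, np.nan)
    heading = np.full(shape, np.nan)
    observed = np.zeros(shape, dtype=bool)
    col = {tid: j for j, tid in enumerate(ids)}
    fi = tracks["frame"].to_numpy() - f0
    ji = np.array([col[t] for t in tracks["id"]])
    cx[fi, ji] = tracks["cx"].to_numpy()
    cy[fi, ji] = tracks["cy"].to_numpy()
    heading[fi, ji] = tracks["heading"].to_numpy()
    observed[fi, ji] = tracks["observed"].to_numpy()
    return frames, ids, cx, cy, heading, observed


def _speeds_and_headings(cx, cy, heading, config: ArenaConfig):
    """Per-frame forward speeds (mm/s) and effective headings.

    The speed at frame f is the displacement over [f, f+1) (the last frame
    reuses the previous step).  Where no head-derived heading exists, the
    velocity direction stands in; frames that are both headingless and
    stationary stay NaN (unclassifiable as actor).
    """
    dx = np.diff(cx, axis=0)
    dy = np.diff(cy, axis=0)
    step = np.hypot(dx, dy)
    if len(step):
        step = np.vstack([step, step[-1:]])
        dx = np.vstack([dx, dx[-1:]])
        dy = np.vstack([dy, dy[-1:]])
    else:
        step = np.zeros_like(cx)
        dx = np.zeros_like(cx)
        dy = np.zeros_like(cx)
    speed = config.speed_mm_s(step)
    vel_heading = np.where(step > 0, np.arctan2(-dy, dx), np.nan)
    eff = np.where(np.isnan(heading), vel_heading, heading)
    return speed, eff


def classify_kinematic_chases(
    tracks: pd.DataFrame,
    config: ArenaConfig,
    params: ChaseParams | None = None,
) -> list[BehaviorEvent]:
    """Classify chases from trajectories alone.

    For every ordered fly pair (actor, target) and frame, the instantaneous
    chase predicate requires gap <= ``d_max_mm``, actor speed >=
    ``v_min_mm_s`` and |heading − bearing(actor→target)| <=
    ``align_max_rad``.  A fly is the actor of at most one chase per frame;
    when several targets qualify the smallest gap wins, then the smallest
    alignment angle, then the smallest target id.  Qualifying runs are
    bridged over gaps <= ``merge_gap_frames`` and kept when >= ``min_frames``
    long, yielding events with ``source="kinematic"``.
    """
    params = params or ChaseParams()
    if len(tracks) == 0 or tracks["id"].nunique() < 2:
        return []
    frames, ids, cx, cy, heading, _ = _track_arrays(tracks)
    speed, eff_heading = _speeds_and_headings(cx, cy, heading, config)

    F, K = cx.shape
    gap_mm = config.to_mm(np.hypot(cx[:, :, None] - cx[:, None, :], cy[:, :, None] - cy[:, None, :]))
    bearing = np.arctan2(-(cy[:, None, :] - cy[:, :, None]), cx[:, None, :] - cx[:, :, None])
    align = np.abs(_angdiff(eff_heading[:, :, None], bearing))

    with np.errstate(invalid="ignore"):
        pred = (
            (gap_mm <= params.d_max_mm)
            & (speed[:, :, None] >= params.v_min_mm_s)
            & (align <= params.align_max_rad)
        )
    pred &= ~np.eye(K, dtype=bool)[None, :, :]

    # actor uniqueness: keep the best target per (frame, actor)
    rank = np.where(pred, gap_mm + align * 1e-6 + np.arange(K)[None, None, :] * 1e-12, np.inf)
    best = rank.argmin(axis=2)
    chosen = np.zeros_like(pred)
    fi, ai = np.nonzero(pred.any(axis=2))
    chosen[fi, ai, best[fi, ai]] = True

    events: list[BehaviorEvent] = []
    for a in range(K):
        for t in range(K):
            if a == t or not chosen[:, a, t].any():
                continue
            for start, stop in merge_runs(_runs(chosen[:, a, t]), params.merge_gap_frames):
                if stop - start >= params.min_frames:
                    events.append(
                        BehaviorEvent(
                            type="chase",
                            start_frame=int(frames[start]),
                            end_frame=int(frames[stop - 1]) + 1,
                            actor_id=int(ids[a]),
                            target_id=int(ids[t]),
                            source="kinematic",
                        )
                    )
    events.sort(key=lambda e: (e.start_frame, e.actor_id, e.target_id or -1))
    return events


# ---------------------------------------------------------------------------
# detector-box attribution
# ---------------------------------------------------------------------------


def _box_overlap(ax, ay, aw, ah, bx, by, bw, bh) -> np.ndarray:
    """Intersection area of box a with each box b, as a fraction of b's area."""
    ix = np.maximum(0.0, np.minimum(ax + aw, bx + bw) - np.maximum(ax, bx))
    iy = np.maximum(0.0, np.minimum(ay + ah, by + bh) - np.maximum(ay, by))
    return ix * iy / (bw * bh)


def attribute_detector_events(
    event_detections: pd.DataFrame,
    tracks: pd.DataFrame,
    config: ArenaConfig,
    cone_rad: float = math.pi / 6,
) -> list[BehaviorEvent]:
    """Attribute detector-labeled behavior boxes to track identities.

    Each ``chase``/``mount`` box is attributed to the two tracks whose body
    boxes it covers best; the actor is the member whose heading points toward
    the other (smaller |heading − bearing| wins, ties to the lower id).  A
    ``wing_ext`` box is attributed to the single best-covered track, with the
    nearest fly inside the singer's heading cone (half-angle ``cone_rad``) as
    optional target.  Boxes covering fewer tracks than required are dropped
    and logged.  Consecutive same-(type, actor, target) frames merge into one
    event interval.
    """
    ev = event_detections[event_detections["label"].isin(EVENT_TYPES)] if len(event_detections) else event_detections
    if len(ev) == 0 or len(tracks) == 0:
        return []
    if "cx" not in ev.columns:
        ev = ev.assign(cx=ev["x"] + ev["w"] / 2.0, cy=ev["y"] + ev["h"] / 2.0)

    tracks_by_frame = dict(tuple(tracks.groupby("frame", sort=True)))
    per_frame: dict[tuple[str, int, int | None], list[int]] = {}
    dropped = 0
    for _, box in ev.sort_values(["frame", "label", "x", "y"], kind="mergesort").iterrows():
        frame = int(box["frame"])
        tgrp = tracks_by_frame.get(frame)
        if tgrp is None:
            dropped += 1
            continue
        ov = _box_overlap(
            box["x"], box["y"], box["w"], box["h"],
            tgrp["x"].to_numpy(), tgrp["y"].to_numpy(), tgrp["w"].to_numpy(), tgrp["h"].to_numpy(),
        )
        tids = tgrp["id"].to_numpy()
        order = np.lexsort((tids, -ov))  # descending overlap, ties to lower id
        kind = box["label"]
        need = 1 if kind == "wing_ext" else 2
        covered = order[: need]
        if len(covered) < need or ov[covered[-1]] <= 0:
            dropped += 1
            continue
        if kind == "wing_ext":
            j = covered[0]
            actor = int(tids[j])
            target = _cone_target(tgrp, j, cone_rad)
            key = ("wing_ext", actor, target)
        else:
            j1, j2 = covered
            actor_j, target_j = _chase_actor(tgrp, j1, j2)
            key = (kind, int(tids[actor_j]), int(tids[target_j]))
        per_frame.setdefault(key, []).append(frame)
    if dropped:
        logger.warning("attribute_detector_events: %d box(es) dropped (insufficient track overlap)", dropped)

    events: list[BehaviorEvent] = []
    for (kind, actor, target), frame_list in per_frame.items():
        fr = np.unique(frame_list)
        idx = np.zeros(fr[-1] - fr[0] + 1, dtype=bool)
        idx[fr - fr[0]] = True
        for start, stop in _runs(idx):
            events.append(
                BehaviorEvent(
                    type=kind,
                    start_frame=int(fr[0] + start),
                    end_frame=int(fr[0] + stop),
                    actor_id=actor,
                    target_id=target,
                    source="detector",
                )
            )
    events.sort(key=lambda e: (e.start_frame, e.type, e.actor_id, e.target_id or -1))
    return events


def _bearing(tgrp: pd.DataFrame, i: int, j: int) -> float:
    dx = tgrp["cx"].iat[j] - tgrp["cx"].iat[i]
    dy = tgrp["cy"].iat[j] - tgrp["cy"].iat[i]
    return math.atan2(-dy, dx)


def _chase_actor(tgrp: pd.DataFrame, j1: int, j2: int) -> tuple[int, int]:
    """Of two overlapped tracks, pick the actor: heading points at the other."""

    def misalign(a: int, b: int) -> float:
        h = tgrp["heading"].iat[a]
        if math.isnan(h):
            return math.pi  # headingless member loses the actor contest
        return abs(float(_angdiff(h, _bearing(tgrp, a, b))))

    m1, m2 = misalign(j1, j2), misalign(j2, j1)
    if m1 < m2 or (m1 == m2 and tgrp["id"].iat[j1] < tgrp["id"].iat[j2]):
        return j1, j2
    return j2, j1


def _cone_target(tgrp: pd.DataFrame, j: int, cone_rad: float) -> int | None:
    """Nearest other fly inside track j's heading cone, if any."""
    h = tgrp["heading"].iat[j]
    if math.isnan(h):
        return None
    best, best_d = None, math.inf
    for k in range(len(tgrp)):
        if k == j:
            continue
        d = math.hypot(tgrp["cx"].iat[k] - tgrp["cx"].iat[j], tgrp["cy"].iat[k] - tgrp["cy"].iat[j])
        if abs(float(_angdiff(h, _bearing(tgrp, j, k)))) <= cone_rad and d < best_d:
            best, best_d = int(tgrp["id"].iat[k]), d
    return best


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def detect_chaining(
    chase_events: Iterable[BehaviorEvent],
    frame_range: tuple[int, int],
    n: int,
) -> list[ChainRecord]:
    """Aggregate chase events into per-frame chain records.

    For every frame in the half-open ``frame_range``, the active chase events
    define a directed graph (edge actor→target).  Weakly connected components
    with >= 2 edges are chain components; a single isolated chase edge never
    counts as chaining.  Per frame, ``chain_count`` = Σ (|component| − 1),
    bounded by N − 1.
    """
    chases = [e for e in chase_events if e.type == "chase" and e.target_id is not None]
    start, stop = frame_range
    records = []
    for frame in range(start, stop):
        edges = [(e.actor_id, e.target_id) for e in chases if e.active_at(frame)]
        records.append(ChainRecord(frame=frame, components=chain_components(edges)))
        if records[-1].chain_count > n - 1:
            raise ValueError(
                f"frame {frame}: chain_count {records[-1].chain_count} exceeds N-1={n - 1}; "
                "check event input for duplicate flies"
            )
    return records


def chain_components(edges: Sequence[tuple[int, int]]) -> tuple[frozenset[int], ...]:
    """Weakly connected components of the chase digraph with >= 2 chase
    relations over >= 3 flies.

    Returns the fly-id sets of qualifying components, ordered by smallest
    member.  Parallel/duplicate edges are collapsed first: two chase events
    between the same ordered pair are one relation, not two; likewise a
    mutual chase within a pair (1→2 and 2→1) involves only two flies and is
    not chaining.
    """
    if not edges:
        return ()
    g = nx.DiGraph()
    g.add_edges_from(edges)
    comps = []
    for comp in nx.weakly_connected_components(g):
        if len(comp) >= 3 and g.subgraph(comp).number_of_edges() >= 2:
            comps.append(frozenset(comp))
    comps.sort(key=min)
    return tuple(comps)


def events_active_per_frame(
    events: Iterable[BehaviorEvent],
    frame_range: tuple[int, int],
    event_type: str,
) -> np.ndarray:
    """Count events of a type active in each frame of the half-open range."""
    start, stop = frame_range
    counts = np.zeros(stop - start, dtype=int)
    for ev in events:
        if ev.type != event_type:
            continue
        lo = max(ev.start_frame, start)
        hi = min(ev.end_frame, stop)
        if lo < hi:
            counts[lo - start: hi - start] += 1
    return counts
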