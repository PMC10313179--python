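"""Quantitative behavioral readouts for fly groups.

The central readout is the behavior index

    Index = B(d) / B(max) × 100%

where B(d) is the number of behavior events detected in a frame and B(max)
the maximum number possible in a group of N flies: N for chasing and singing
(every fly can chase/sing at once), and N − 1 for chaining (a single chain or
ring through all N flies contains N − 1 chain links).  Five chasing pairs in
a 10-fly group give an index of 50%; ten flies chasing in a closed ring give
100%.  The index is computed per frame and averaged over the observation;
the per-frame series is retained for rug plots.

The module also provides the classical assay readouts: the courtship index
(percentage of observed time a fly performs any courtship step), the
time-based chaining index (percentage of time at least three flies are
engaged in courtship together), two-choice preference, social space
(nearest-neighbor distance and neighbor counts), pairwise encounter counts,
foraging visits and dwell time in a food region, and locomotion-state
classification (resting / walking / running / jumping).

Ratios with an empty denominator (a male that never courts, zero observed
frames) are reported as missing (``None``), never as 0 — zero is a
meaningful outcome and must stay distinguishable from "not measurable".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arena_io import ArenaConfig
from .behavior_events import BehaviorEvent, ChainRecord, _runs, events_active_per_frame, merge_runs

__all__ = [
    "BehaviorIndex",
    "MetricParams",
    "behavior_index",
    "chaining_index_time",
    "compute_metrics",
    "count_encounters",
    "courtship_index",
    "foraging_metrics",
    "locomotion_classify",
    "preference_index",
    "social_space",
]

B_MAX_RULES = {"chase": "n", "sing": "n", "wing_ext": "n", "chain": "n_minus_1"}

LOCOMOTION_STATES = ("resting", "walking", "running", "jumping")


@dataclass(frozen=True)
class MetricParams:
    """Thresholds of the descriptive metrics; all distances in mm.

    neighbor_radius_mm
        Radius of the "surrounding neighbors" count in the social-space
        readout.
    encounter_radius_mm, encounter_min_frames
        A social encounter is a pair staying within the radius for at least
        the minimum run length (0.5 s at 30 fps by default).
    forage_min_frames, forage_gap_frames
        A foraging visit is a stay in the food region of at least
        ``forage_min_frames`` (1 s at 30 fps); excursions shorter than
        ``forage_gap_frames`` outside the region do not split a visit.
    rest_max_mm_s, walk_max_mm_s
        Speed cutoffs separating resting / walking / running.
    jump_min_body_lengths_per_frame
        A single-frame displacement of at least this many body lengths is a
        jump regardless of the speed bins.
    """

    neighbor_radius_mm: float = 5.0
    encounter_radius_mm: float = 5.0
    encounter_min_frames: int = 15
    forage_min_frames: int = 30
    forage_gap_frames: int = 15
    rest_max_mm_s: float = 0.5
    walk_max_mm_s: float = 10.0
    jump_min_body_lengths_per_frame: float = 4.0

    def __post_init__(self):
        vals = (
            self.neighbor_radius_mm, self.encounter_radius_mm, self.encounter_min_frames,
            self.forage_min_frames, self.forage_gap_frames, self.rest_max_mm_s,
            self.walk_max_mm_s, self.jump_min_body_lengths_per_frame,
        )
        if min(vals) <= 0:
            raise ValueError("all MetricParams must be strictly positive")
        if not self.rest_max_mm_s < self.walk_max_mm_s:
            raise ValueError("rest_max_mm_s must be < walk_max_mm_s")


@dataclass(frozen=True)
class BehaviorIndex:
    """A behavior index: overall mean % plus the per-frame % series."""

    behavior: str
    mean: float
    per_frame: np.ndarray

    def __float__(self) -> float:
        return self.mean


def behavior_index(b_d: Sequence[int] | np.ndarray, n: int, behavior: str) -> BehaviorIndex:
    """Index = B(d)/B(max) × 100%, per frame, averaged over frames.

    ``b_d`` is the per-frame count of detected events; B(max) is N for
    chasing/singing and N − 1 for chaining.  Counts exceeding B(max)
    (possible with noisy event input) are capped at B(max) with a warning so
    the index stays within [0, 100] by construction.

    Raises ``ValueError`` for N < 2 (the chaining B(max) would be < 1) or
    negative counts.
    """
    if behavior not in B_MAX_RULES:
        raise ValueError(f"unknown behavior {behavior!r}; expected one of {sorted(B_MAX_RULES)}")
    if n < 2:
        raise ValueError(f"behavior_index requires N >= 2, got N={n}")
    b_d = np.asarray(b_d, dtype=float)
    if b_d.size == 0:
        raise ValueError("behavior_index requires at least one frame")
    if (b_d < 0).any():
        raise ValueError("per-frame event counts must be >= 0")
    b_max = n if B_MAX_RULES[behavior] == "n" else n - 1
    if (b_d > b_max).any():
        warnings.warn(
            f"{behavior}: {int((b_d > b_max).sum())} frame(s) exceed B(max)={b_max}; capping at 100%",
            stacklevel=2,
        )
        b_d = np.minimum(b_d, b_max)
    per_frame = b_d / b_max * 100.0
    return BehaviorIndex(behavior=behavior, mean=float(per_frame.mean()), per_frame=per_frame)


def courtship_index(courting: Sequence[bool] | np.ndarray) -> float | None:
    """CI: percentage of observed time the fly performed any courtship step.

    ``courting`` holds one flag per observed frame.  Zero observed frames
    make the CI undefined (returns ``None``).
    """
    courting = np.asarray(courting, dtype=bool)
    if courting.size == 0:
        return None
    return float(100.0 * courting.sum() / courting.size)


def chaining_index_time(chains: Sequence[ChainRecord], n_frames: int) -> float | None:
    """Percentage of observed time with at least one active chain.

    This is the time-based chaining index of the group assay: the fraction
    of frames in which >= 3 flies are engaged in courtship together.
    """
    if n_frames <= 0:
        return None
    chained = sum(1 for rec in chains if rec.chain_count > 0)
    return float(100.0 * chained / n_frames)


def preference_index(target_labels: Sequence[str]) -> float | None:
    """Two-choice preference: % of courtship time directed at target "A".

    ``target_labels`` holds one of ``"A"``, ``"B"``, ``"none"`` per frame.
    Returns 100 × frames(A) / (frames(A) + frames(B)); undefined (``None``)
    when the male never courts.
    """
    labels = np.asarray(target_labels)
    a = int((labels == "A").sum())
    b = int((labels == "B").sum())
    if a + b == 0:
        return None
    return float(100.0 * a / (a + b))


# ---------------------------------------------------------------------------
# geometry metrics
# ---------------------------------------------------------------------------


def _positions_tensor(tracks: pd.DataFrame):
    """Dense (frames, ids, X, Y) arrays from a tracks frame."""
    ids = np.array(sorted(tracks["id"].unique()))
    f0, f1 = int(tracks["frame"].min()), int(tracks["frame"].max())
    frames = np.arange(f0, f1 + 1)
    X = np.full((len(frames), len(ids)), np.nan)
    Y = np.full_like(X, np.nan)
    col = {tid: j for j, tid in enumerate(ids)}
    fi = tracks["frame"].to_numpy() - f0
    ji = np.array([col[t] for t in tracks["id"]])
    X[fi, ji] = tracks["cx"].to_numpy()
    Y[fi, ji] = tracks["cy"].to_numpy()
    return frames, ids, X, Y


def social_space(
    tracks: pd.DataFrame,
    config: ArenaConfig,
    params: MetricParams | None = None,
    frames: Sequence[int] | None = None,
) -> dict:
    """Nearest-neighbor distance (mm) and neighbor count per fly.

    For each fly and frame: the minimum pairwise centroid distance converted
    to millimetres, and the number of other flies within
    ``neighbor_radius_mm``.  ``frames`` restricts the measurement (e.g. to
    frames after a settling period); by default every frame with >= 2 flies
    present is measured.  Returns per-frame series and across-frame means,
    keyed by fly id.
    """
    params = params or MetricParams()
    if len(tracks) == 0 or tracks["id"].nunique() < 2:
        raise ValueError("social_space requires >= 2 tracked flies")
    all_frames, ids, X, Y = _positions_tensor(tracks)
    if frames is not None:
        keep = np.isin(all_frames, np.asarray(frames))
        all_frames, X, Y = all_frames[keep], X[keep], Y[keep]

    d = np.hypot(X[:, :, None] - X[:, None, :], Y[:, :, None] - Y[:, None, :])
    K = len(ids)
    d[:, np.arange(K), np.arange(K)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        nn_mm = config.to_mm(np.nanmin(d, axis=2))
        neigh = np.nansum(config.to_mm(d) <= params.neighbor_radius_mm, axis=2)
    present = ~np.isnan(X)
    neigh = np.where(present, neigh, -1)

    out = {"frames": all_frames, "ids": ids, "nn_mm": nn_mm, "neighbor_count": neigh}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["nn_mm_mean"] = {int(t): float(np.nanmean(nn_mm[:, j])) for j, t in enumerate(ids)}
        out["neighbor_count_mean"] = {
            int(t): float(np.mean(neigh[:, j][neigh[:, j] >= 0])) if (neigh[:, j] >= 0).any() else None
            for j, t in enumerate(ids)
        }
    return out


def count_encounters(
    tracks: pd.DataFrame,
    config: ArenaConfig,
    params: MetricParams | None = None,
) -> int:
    """Total number of pairwise social encounters.

    An encounter is a maximal run of >= ``encounter_min_frames`` consecutive
    frames during which one pair's centroid gap stays within
    ``encounter_radius_mm``; the count sums such runs over all pairs.
    """
    params = params or MetricParams()
    if len(tracks) == 0 or tracks["id"].nunique() < 2:
        raise ValueError("count_encounters requires >= 2 tracked flies")
    _, ids, X, Y = _positions_tensor(tracks)
    total = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            gap = config.to_mm(np.hypot(X[:, i] - X[:, j], Y[:, i] - Y[:, j]))
            with np.errstate(invalid="ignore"):
                close = gap <= params.encounter_radius_mm
            close &= ~np.isnan(gap)
            total += sum(1 for s, e in _runs(close) if e - s >= params.encounter_min_frames)
    return total


def foraging_metrics(
    tracks: pd.DataFrame,
    config: ArenaConfig,
    params: MetricParams | None = None,
) -> dict:
    """Per-fly foraging visit counts and dwell times in the food region.

    A visit is a stay in ``config.food_roi`` of at least
    ``forage_min_frames``; excursions shorter than ``forage_gap_frames``
    outside the region are bridged into the same visit (a visit's length is
    its in-region frames).  Dwell is the total in-region time in seconds,
    counted regardless of whether any stay was long enough to be a visit.
    """
    params = params or MetricParams()
    if config.food_roi is None:
        raise ValueError("foraging_metrics requires config.food_roi")
    visits: dict[int, int] = {}
    dwell_s: dict[int, float] = {}
    for tid, grp in tracks.groupby("id", sort=True):
        grp = grp.sort_values("frame", kind="mergesort")
        inside = np.asarray(config.food_roi.contains(grp["cx"].to_numpy(), grp["cy"].to_numpy()))
        runs = merge_runs(_runs(inside), params.forage_gap_frames - 1)
        n_visits = 0
        for s, e in runs:
            if int(inside[s:e].sum()) >= params.forage_min_frames:
                n_visits += 1
        visits[int(tid)] = n_visits
        dwell_s[int(tid)] = float(inside.sum() / config.fps)
    return {"visits": visits, "dwell_s": dwell_s}


def locomotion_classify(
    tracks: pd.DataFrame,
    config: ArenaConfig,
    params: MetricParams | None = None,
) -> dict:
    """Per-frame locomotion states and per-fly event counts.

    The speed at frame f is the centroid displacement over [f, f+1) scaled
    to mm/s (the last frame reuses the previous step).  A single-frame
    displacement of >= ``jump_min_body_lengths_per_frame`` body lengths is a
    jump; otherwise the two speed cutoffs split resting / walking / running.
    Coasting frames (track not observed) are classed as resting.  Events are
    maximal same-state runs.
    """
    params = params or MetricParams()
    states: dict[int, np.ndarray] = {}
    frames_by_id: dict[int, np.ndarray] = {}
    event_counts: dict[int, dict[str, int]] = {}
    fractions: dict[int, dict[str, float]] = {}
    jump_px = params.jump_min_body_lengths_per_frame * config.body_length_mm / config.mm_per_px
    for tid, grp in tracks.groupby("id", sort=True):
        grp = grp.sort_values("frame", kind="mergesort")
        if len(grp) < 2:
            raise ValueError(f"locomotion_classify requires >= 2 frames per track (id {tid})")
        step = np.hypot(np.diff(grp["cx"].to_numpy()), np.diff(grp["cy"].to_numpy()))
        step = np.append(step, step[-1])
        speed = config.speed_mm_s(step)
        state = np.where(
            step >= jump_px,
            "jumping",
            np.where(speed <= params.rest_max_mm_s, "resting",
                     np.where(speed <= params.walk_max_mm_s, "walking", "running")),
        )
        state[~grp["observed"].to_numpy()] = "resting"
        states[int(tid)] = state
        frames_by_id[int(tid)] = grp["frame"].to_numpy()
        counts = {s: 0 for s in LOCOMOTION_STATES}
        for s in LOCOMOTION_STATES:
            counts[s] = len(_runs(state == s))
        event_counts[int(tid)] = counts
        fractions[int(tid)] = {s: float(100.0 * (state == s).mean()) for s in LOCOMOTION_STATES}
    return {"states": states, "frames": frames_by_id, "event_counts": event_counts, "fractions": fractions}


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


def courting_flags(
    events: Iterable[BehaviorEvent],
    fly_id: int,
    frame_range: tuple[int, int],
) -> np.ndarray:
    """Per-frame flag: is the fly the actor of any courtship-step event?

    Courtship steps are chasing/following, wing extension (singing) and
    mounting — any event type, with the fly as actor.
    """
    start, stop = frame_range
    flags = np.zeros(stop - start, dtype=bool)
    for ev in events:
        if ev.actor_id != fly_id:
            continue
        lo, hi = max(ev.start_frame, start), min(ev.end_frame, stop)
        if lo < hi:
            flags[lo - start: hi - start] = True
    return flags


def compute_metrics(
    tracks: pd.DataFrame,
    events: Sequence[BehaviorEvent],
    chains: Sequence[ChainRecord],
    config: ArenaConfig,
    params: MetricParams | None = None,
) -> dict:
    """Assemble the full metrics report for one recording.

    Combines the behavior indexes (chasing, singing, chaining — each with
    its per-frame series), the time-based chaining index, per-fly courtship
    indices, social space, encounter count, foraging (when a food region is
    configured) and locomotion states into one JSON-serializable dict.
    """
    params = params or MetricParams()
    if len(tracks) == 0:
        raise ValueError("compute_metrics requires non-empty tracks")
    f0, f1 = int(tracks["frame"].min()), int(tracks["frame"].max())
    frame_range = (f0, f1 + 1)
    n_frames = f1 + 1 - f0
    n = config.n

    chase_series = events_active_per_frame(events, frame_range, "chase")
    sing_series = events_active_per_frame(events, frame_range, "wing_ext")
    chain_series = np.zeros(n_frames, dtype=int)
    for rec in chains:
        if f0 <= rec.frame <= f1:
            chain_series[rec.frame - f0] = rec.chain_count

    report: dict = {
        "n": n,
        "fps": config.fps,
        "frame_range": [f0, f1 + 1],
        "indexes": {},
        "per_frame": {
            "chase_events": chase_series.tolist(),
            "wing_ext_events": sing_series.tolist(),
            "chain_count": chain_series.tolist(),
        },
    }
    if n >= 2:
        for name, series in (("chase", chase_series), ("sing", sing_series), ("chain", chain_series)):
            bi = behavior_index(series, n, name)
            report["indexes"][name] = bi.mean
        report["chaining_index_time"] = chaining_index_time(chains, n_frames)

    report["courtship_index"] = {
        int(tid): courtship_index(courting_flags(events, int(tid), frame_range))
        for tid in sorted(tracks["id"].unique())
    }

    if tracks["id"].nunique() >= 2:
        space = social_space(tracks, config, params)
        report["social_space"] = {
            "nn_mm_mean": space["nn_mm_mean"],
            "neighbor_count_mean": space["neighbor_count_mean"],
        }
        report["encounters"] = count_encounters(tracks, config, params)

    if config.food_roi is not None:
        report["foraging"] = foraging_metrics(tracks, config, params)

    loco = locomotion_classify(tracks, config, params)
    report["locomotion"] = {
        "event_counts": loco["event_counts"],
        "fractions": loco["fractions"],
    }
    return report
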