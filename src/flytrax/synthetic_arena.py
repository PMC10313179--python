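"""Agent-based arena simulator.

Generates per-frame detection streams with complete ground truth (identities,
behavior events, chain structure) so that the tracker, event logic and
metrics can be tested without video or a trained detector.  Flies live in a
circular chamber; undirected flies perform a reflective random walk, and
scripted directives overlay stereotyped behaviors:

``chase(actor, target, start, end)``
    The target cruises on a circular orbit at a steady walking speed; the
    actor trails it on the same orbit, one chord of the chase gap behind,
    heading locked on the target — so gap, speed and alignment of the
    canonical following geometry are exact at every frame.
``ring(members, start, end)``
    The members rotate on a common circle, each heading at (and chasing) the
    fly ahead of it — the closed chasing ring that maximizes the chasing and
    chaining indexes.
``goto_food(fly, start)``
    The fly walks to the food region and stays inside it.
``decapitated(fly)``
    A static target (as in two-choice assays with beheaded flies).
``tether(fly, radius_px)``
    Restricts a fly's random walk to a disc around its start position; used
    to build well-separated scenarios with provable spacing.

Each fly emits an axis-aligned body box (12×6 px, ≈ a 2.5 mm fly at the
default 0.05 mm/px) and a 6×6 px head box centred 4 px ahead of the centroid
along the fly's heading; that geometry keeps the head box overlapping its own
body box by at least a third of its area at every orientation, so head
assignment never starves.  Detection noise is optional: per-fly-frame dropout
and Gaussian centroid jitter.  All randomness flows from one seeded
generator; the same script and seed reproduce byte-identical outputs.
Random-walk steps are Gaussian with the step norm clipped at 3σ, so per-frame
displacement has a hard bound of 3σ pixels — scripts can therefore guarantee
the "minimum gap exceeds twice the maximum step" regime in which greedy
nearest-neighbor linking is provably identical to optimal assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .arena_io import ArenaConfig
from .behavior_events import BehaviorEvent, ChainRecord, chain_components

__all__ = [
    "BODY_H",
    "BODY_W",
    "Chase",
    "Decapitated",
    "GotoFood",
    "HEAD_OFFSET",
    "Ring",
    "ScenarioScript",
    "SimulationResult",
    "Tether",
    "make_worked_examples",
    "simulate",
]

BODY_W, BODY_H = 12.0, 6.0
HEAD_W, HEAD_H = 6.0, 6.0
HEAD_OFFSET = 4.0  # px ahead of the body centroid, along the heading


@dataclass(frozen=True)
class Chase:
    """Actor trails the target at ``gap_mm``, aligned, over [start, end).

    The target orbits a fixed centre (``center_px``, default its initial
    position, pulled inward if needed so the whole pair stays in the
    chamber) at ``speed_mm_s``; the orbit radius is ``2 × gap_mm`` and the
    actor rides the same orbit one chord of ``gap_mm`` behind.
    """

    actor: int
    target: int
    start: int
    end: int
    gap_mm: float = 2.0
    speed_mm_s: float = 5.0
    center_px: tuple[float, float] | None = None

    @property
    def orbit_radius_mm(self) -> float:
        return 2.0 * self.gap_mm


@dataclass(frozen=True)
class Ring:
    """Members rotate on a circle, each chasing the next member, over [start, end)."""

    members: tuple[int, ...]
    start: int
    end: int
    gap_mm: float = 3.0
    speed_mm_s: float = 5.0


@dataclass(frozen=True)
class GotoFood:
    """From ``start`` on, the fly walks to the food region and stays there."""

    fly: int
    start: int
    speed_mm_s: float = 5.0


@dataclass(frozen=True)
class Decapitated:
    """The fly is a static (beheaded) target for the whole clip."""

    fly: int


@dataclass(frozen=True)
class Tether:
    """Restrict a fly's random walk to a disc of ``radius_px`` around its start."""

    fly: int
    radius_px: float


Directive = Chase | Ring | GotoFood | Decapitated | Tether


@dataclass(frozen=True)
class ScenarioScript:
    """A simulation scenario: population, motion model, directives, noise.

    ``step_sigma_px`` is the random-walk step scale for undirected flies
    (per-frame displacement is capped at 3σ); ``dropout`` is the per-fly,
    per-frame probability that the detector misses the fly entirely;
    ``jitter_sigma_px`` jitters emitted box centroids.  When
    ``emit_detector_events`` is set, scripted chases additionally emit
    detector-style ``chase`` boxes spanning actor and target.
    """

    n: int
    duration: int
    step_sigma_px: float = 2.0
    dropout: float = 0.0
    jitter_sigma_px: float = 0.0
    emit_detector_events: bool = False
    seed: int = 0
    directives: tuple[Directive, ...] = ()

    def __post_init__(self):
        if self.n < 1 or self.duration < 1:
            raise ValueError("need n >= 1 flies and duration >= 1 frames")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        self._validate_directives()

    def _validate_directives(self):
        ids = range(1, self.n + 1)
        actor_spans: dict[int, list[tuple[int, int]]] = {}
        for d in self.directives:
            if isinstance(d, Chase):
                refs, span = (d.actor, d.target), (d.start, d.end)
                if d.actor == d.target:
                    raise ValueError("chase actor and target must differ")
                spans = [(d.actor, span)]
            elif isinstance(d, Ring):
                refs, span = d.members, (d.start, d.end)
                if len(d.members) < 3:
                    raise ValueError("ring needs >= 3 members")
                if len(set(d.members)) != len(d.members):
                    raise ValueError("ring members must be distinct")
                spans = [(m, span) for m in d.members]
            elif isinstance(d, GotoFood):
                refs, span, spans = (d.fly,), (d.start, self.duration), []
            elif isinstance(d, (Decapitated, Tether)):
                refs, span, spans = (d.fly,), (0, self.duration), []
            else:  # pragma: no cover
                raise TypeError(f"unknown directive {d!r}")
            for fly in refs:
                if fly not in ids:
                    raise ValueError(f"directive references unknown fly {fly}")
            if not (0 <= span[0] < span[1] <= self.duration):
                raise ValueError(f"directive frame range {span} outside [0, {self.duration}]")
            for fly, (s, e) in spans:
                for s2, e2 in actor_spans.get(fly, []):
                    if s < e2 and s2 < e:
                        raise ValueError(f"fly {fly} is the actor of two overlapping chase directives")
                actor_spans.setdefault(fly, []).append((s, e))


@dataclass
class SimulationResult:
    """Simulator output: emitted detections plus full ground truth."""

    detections: pd.DataFrame
    truth_tracks: pd.DataFrame
    truth_events: list[BehaviorEvent]
    truth_chains: list[ChainRecord]
    script: ScenarioScript
    config: ArenaConfig


def initial_positions(n: int, config: ArenaConfig) -> np.ndarray:
    """Deterministic starting layout: a golden-angle spiral inside the chamber."""
    ch = config.chamber
    pos = np.empty((n, 2))
    golden = math.pi * (3 - math.sqrt(5))
    for i in range(n):
        r = ch.r * 0.82 * math.sqrt((i + 0.5) / n)
        th = i * golden
        pos[i] = (ch.cx + r * math.cos(th), ch.cy + r * math.sin(th))
    return pos


def _reflect_into(pos: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Reflect a point radially back inside a circle (physical wall bounce)."""
    v = pos - center
    d = float(np.hypot(*v))
    if d <= radius or d == 0.0:
        return pos
    folded = d
    while folded > radius:
        folded = abs(2 * radius - folded)
    return center + v / d * folded


def _pull_inside(point: np.ndarray, center: np.ndarray, max_dist: float) -> np.ndarray:
    """Move a point radially toward ``center`` until within ``max_dist``."""
    v = point - center
    d = float(np.hypot(*v))
    if d <= max_dist:
        return point
    return center + v / d * max_dist


def simulate(script: ScenarioScript, config: ArenaConfig) -> SimulationResult:
    """Run the scenario and return detections plus ground truth.

    Positions stay inside the chamber at all times.  Ground-truth tracks use
    ids 1..n; ground-truth chase events mirror the scripted directives, and
    ground-truth chain records are the per-frame chain components of the
    scripted chase graph.
    """
    if script.n != config.n:
        raise ValueError(f"script.n={script.n} disagrees with config.n={config.n}")
    rng = np.random.default_rng(script.seed)
    n, F = script.n, script.duration
    ch = config.chamber
    center = np.array([ch.cx, ch.cy])
    wall = ch.r - max(BODY_W, BODY_H)  # keep whole boxes inside
    px_per_mm = 1.0 / config.mm_per_px

    pos = initial_positions(n, config)
    heading = rng.uniform(-math.pi, math.pi, size=n)

    static = np.zeros(n, dtype=bool)
    tether: dict[int, tuple[np.ndarray, float]] = {}
    food_walkers: list[GotoFood] = []
    chase_states: list[dict] = []
    ring_states: list[dict] = []
    chase_edges: list[list[tuple[int, int]]] = [[] for _ in range(F)]
    truth_events: list[BehaviorEvent] = []

    for d in script.directives:
        if isinstance(d, Decapitated):
            static[d.fly - 1] = True
        elif isinstance(d, Tether):
            tether[d.fly - 1] = (pos[d.fly - 1].copy(), d.radius_px)
        elif isinstance(d, GotoFood):
            if config.food_roi is None:
                raise ValueError("goto_food directive requires config.food_roi")
            food_walkers.append(d)
        elif isinstance(d, Chase):
            a, t = d.actor - 1, d.target - 1
            r_orbit = d.orbit_radius_mm * px_per_mm
            gap_px = d.gap_mm * px_per_mm
            if d.center_px is not None:
                c = _pull_inside(np.array(d.center_px, dtype=float), center, wall - r_orbit - gap_px)
            else:
                c = None  # anchored at the target's position when the chase starts
            chase_states.append({
                "a": a, "t": t, "span": (d.start, d.end), "center": c,
                "r": r_orbit, "gap": gap_px,
                "omega": (d.speed_mm_s * px_per_mm / config.fps) / r_orbit,
                "phase": rng.uniform(-math.pi, math.pi),
                # actor trails on the same orbit, one chord of gap_px behind,
                # so gap, speed and alignment are exact at every frame
                "delta": 2 * math.asin(gap_px / (2 * r_orbit)),
            })
            for f in range(d.start, d.end):
                chase_edges[f].append((a, t))
            truth_events.append(BehaviorEvent("chase", d.start, d.end, d.actor, d.target, source="kinematic"))
        elif isinstance(d, Ring):
            m = len(d.members)
            chord = d.gap_mm * px_per_mm
            radius = chord / (2 * math.sin(math.pi / m))
            ring_states.append({
                "members": [i - 1 for i in d.members], "radius": radius,
                "omega": (d.speed_mm_s * px_per_mm / config.fps) / radius,
                "span": (d.start, d.end), "center": center.copy(),
            })
            for k, mem in enumerate(d.members):
                nxt = d.members[(k + 1) % m]
                for f in range(d.start, d.end):
                    chase_edges[f].append((mem - 1, nxt - 1))
                truth_events.append(BehaviorEvent("chase", d.start, d.end, mem, nxt, source="kinematic"))
    truth_events.sort(key=lambda e: (e.start_frame, e.actor_id, e.target_id or -1))

    track_rows: list[dict] = []
    det_rows: list[dict] = []

    def emit(frame: int, fly: int, p: np.ndarray, th: float):
        cx, cy = float(p[0]), float(p[1])
        track_rows.append({
            "frame": frame, "id": fly + 1,
            "x": cx - BODY_W / 2, "y": cy - BODY_H / 2, "w": BODY_W, "h": BODY_H,
            "conf": 1.0, "observed": True, "heading": th, "cx": cx, "cy": cy,
        })
        if script.dropout and rng.random() < script.dropout:
            return
        jx = jy = 0.0
        if script.jitter_sigma_px:
            jx, jy = rng.normal(0.0, script.jitter_sigma_px, size=2)
        hx = cx + HEAD_OFFSET * math.cos(th)
        hy = cy - HEAD_OFFSET * math.sin(th)  # image y grows downward
        det_rows.append({"frame": frame, "label": "body", "conf": 1.0,
                         "x": cx - BODY_W / 2 + jx, "y": cy - BODY_H / 2 + jy,
                         "w": BODY_W, "h": BODY_H})
        det_rows.append({"frame": frame, "label": "head", "conf": 1.0,
                         "x": hx - HEAD_W / 2 + jx, "y": hy - HEAD_H / 2 + jy,
                         "w": HEAD_W, "h": HEAD_H})

    for f in range(F):
        new_pos = pos.copy()
        new_heading = heading.copy()
        scripted = np.zeros(n, dtype=bool)

        for ring in ring_states:
            s, e = ring["span"]
            if not s <= f < e:
                continue
            m = len(ring["members"])
            pts = [
                ring["center"] + ring["radius"] * np.array([
                    math.cos(ring["omega"] * f + 2 * math.pi * k / m),
                    math.sin(ring["omega"] * f + 2 * math.pi * k / m),
                ])
                for k in range(m)
            ]
            for k, i in enumerate(ring["members"]):
                new_pos[i] = pts[k]
                v = pts[(k + 1) % m] - pts[k]  # heading at the member ahead
                new_heading[i] = math.atan2(-v[1], v[0])
                scripted[i] = True

        for st in chase_states:
            s, e = st["span"]
            if not s <= f < e:
                continue
            a, t = st["a"], st["t"]
            phase = st["phase"] + st["omega"] * f
            if st["center"] is None:
                # anchor the orbit so the target starts from where it stands
                anchor = pos[t] - st["r"] * np.array([math.cos(phase), math.sin(phase)])
                st["center"] = _pull_inside(anchor, center, wall - st["r"] - st["gap"])
            tgt = st["center"] + st["r"] * np.array([math.cos(phase), math.sin(phase)])
            if not scripted[t]:
                v = tgt - pos[t]
                if np.hypot(*v) > 0:
                    new_heading[t] = math.atan2(-v[1], v[0])
                new_pos[t] = tgt
                scripted[t] = True
            if not scripted[a]:
                ph_a = phase - st["delta"]
                new_pos[a] = st["center"] + st["r"] * np.array([math.cos(ph_a), math.sin(ph_a)])
                u = tgt - new_pos[a]
                new_heading[a] = math.atan2(-u[1], u[0])
                scripted[a] = True

        for d in food_walkers:
            i = d.fly - 1
            if f >= d.start and not scripted[i] and not static[i]:
                roi = config.food_roi
                goal = np.array([roi.cx, roi.cy])
                v = goal - pos[i]
                dist = float(np.hypot(*v))
                step = d.speed_mm_s * px_per_mm / config.fps
                if dist > step:
                    new_pos[i] = pos[i] + v / dist * step
                    new_heading[i] = math.atan2(-v[1], v[0])
                else:
                    new_pos[i] = goal
                scripted[i] = True

        for i in range(n):
            if scripted[i] or static[i]:
                continue
            if f > 0:
                step = rng.normal(0.0, script.step_sigma_px, size=2)
                norm = float(np.hypot(*step))
                cap = 3.0 * script.step_sigma_px
                if norm > cap > 0:
                    step *= cap / norm
                new_pos[i] = pos[i] + step
                if i in tether:
                    home, rad = tether[i]
                    new_pos[i] = _reflect_into(new_pos[i], home, rad)
                new_pos[i] = _reflect_into(new_pos[i], center, wall)
                moved = new_pos[i] - pos[i]
                if np.hypot(*moved) > 0:
                    new_heading[i] = math.atan2(-moved[1], moved[0])

        pos, heading = new_pos, new_heading
        for i in range(n):
            emit(f, i, pos[i], float(heading[i]))
        if script.emit_detector_events:
            for a, t in chase_edges[f]:
                x0 = min(pos[a][0], pos[t][0]) - BODY_W / 2
                y0 = min(pos[a][1], pos[t][1]) - BODY_H / 2
                x1 = max(pos[a][0], pos[t][0]) + BODY_W / 2
                y1 = max(pos[a][1], pos[t][1]) + BODY_H / 2
                det_rows.append({"frame": f, "label": "chase", "conf": 1.0,
                                 "x": x0, "y": y0, "w": x1 - x0, "h": y1 - y0})

    detections = pd.DataFrame(det_rows, columns=["frame", "label", "conf", "x", "y", "w", "h"])
    detections["cx"] = detections["x"] + detections["w"] / 2.0
    detections["cy"] = detections["y"] + detections["h"] / 2.0
    detections = detections.sort_values(["frame", "label", "x", "y"], kind="mergesort").reset_index(drop=True)
    truth_tracks = pd.DataFrame(track_rows).sort_values(["frame", "id"], kind="mergesort").reset_index(drop=True)

    truth_chains = [
        ChainRecord(frame=f, components=chain_components([(a + 1, t + 1) for a, t in chase_edges[f]]))
        for f in range(F)
    ]
    return SimulationResult(detections, truth_tracks, truth_events, truth_chains, script, config)


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------


def make_worked_examples(duration: int = 300) -> dict[str, tuple[ScenarioScript, ArenaConfig]]:
    """The two canonical 10-fly chasing scenarios, as (script, config) pairs.

    ``five_pairs``: five simultaneous chases sustained over the whole clip,
    zero noise — through the full pipeline the chasing index is 50%
    (B(d) = 5 events per frame, B(max) = N = 10).  ``ring``: all ten flies
    in one scripted chasing ring — chasing index 100% (B(d) = 10) and chain
    count N − 1 = 9 in every frame.  The five chase orbits are spread on a
    ring of centres so distinct pairs always stay farther apart than the
    kinematic chase gate; both scripts are fully deterministic (every fly is
    scripted, so no random-walk randomness enters the motion).
    """
    config = ArenaConfig(n=10, mm_per_px=0.05)  # 4-cm chamber -> radius 400 px
    ch = config.chamber
    spread = 250.0  # px, radius of the ring of orbit centres
    centres = [
        (ch.cx + spread * math.cos(2 * math.pi * k / 5), ch.cy + spread * math.sin(2 * math.pi * k / 5))
        for k in range(5)
    ]
    five = ScenarioScript(
        n=10,
        duration=duration,
        seed=0,
        directives=tuple(
            Chase(actor=2 * k + 1, target=2 * k + 2, start=0, end=duration, center_px=centres[k])
            for k in range(5)
        ),
    )
    ring = ScenarioScript(
        n=10,
        duration=duration,
        seed=0,
        directives=(Ring(members=tuple(range(1, 11)), start=0, end=duration),),
    )
    return {"five_pairs": (five, config), "ring": (ring, config)}
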