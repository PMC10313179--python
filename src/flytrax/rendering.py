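"""Visual summaries and their underlying numeric tables.

Three renderers mirror the standard figures of group-courtship analysis:

* **event maps** — every fly in every frame of a segment (default 1.5 min at
  30 fps = 2,700 frames) is marked as one colored dot and the frames are
  overlaid, so trajectories and behavior states show in a single image
  (gray: resting/walking; blue: following/chase; salmon: singing/wing
  extension);
* **occupancy heatmaps** — fly-frame counts binned on a spatial grid, e.g.
  to show how strongly flies gather in the food area;
* **chain series** — the per-frame chaining-event count, the column behind
  rug plots.

The numeric tables are the authoritative output; the PNG images are derived
artifacts (tests assert on tables, never on pixels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .arena_io import ArenaConfig
from .behavior_events import BehaviorEvent, ChainRecord

__all__ = [
    "EventMapSpec",
    "export_chain_series",
    "occupancy_heatmap",
    "render_event_map",
]

DEFAULT_COLORS = {
    "rest_walk": (128, 128, 128),   # gray
    "chase": (70, 100, 220),        # blue: following
    "wing_ext": (250, 128, 114),    # salmon: singing
    "mount": (150, 70, 190),
}


@dataclass(frozen=True)
class EventMapSpec:
    """Layout of an event map.

    ``segment_frames`` defaults to 2,700 — a 90-second segment at 30 frames
    per second, short enough that the overlay stays readable.  ``colors``
    maps a behavior state to an RGB triple; any renderable state must have a
    color.  ``canvas_px`` defaults to the chamber bounding square.
    """

    segment_frames: int = 2_700
    dot_radius_px: int = 2
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    canvas_px: tuple[int, int] | None = None

    def __post_init__(self):
        if self.segment_frames <= 0:
            raise ValueError("segment_frames must be > 0")
        missing = {"rest_walk", "chase", "wing_ext", "mount"} - set(self.colors)
        if missing:
            raise ValueError(f"colors missing states: {sorted(missing)}")


def _state_at(events_by_actor: dict[int, list[BehaviorEvent]], fly: int, frame: int) -> str:
    """Behavior state of a fly at a frame; event membership wins over rest_walk.

    Wing extension outranks chase outranks mount when events overlap, so the
    rarer courtship element stays visible in the overlay.
    """
    best = "rest_walk"
    priority = {"mount": 1, "chase": 2, "wing_ext": 3}
    score = 0
    for ev in events_by_actor.get(fly, ()):
        if ev.active_at(frame) and priority[ev.type] > score:
            best, score = ev.type, priority[ev.type]
    return best


def render_event_map(
    tracks: pd.DataFrame,
    events: Sequence[BehaviorEvent],
    spec: EventMapSpec,
    config: ArenaConfig,
    segment_start: int | None = None,
) -> tuple[Image.Image, pd.DataFrame]:
    """Overlay one dot per fly per frame of a segment, colored by behavior.

    Returns the PNG-ready image and the per-dot table
    (``frame, fly_id, x, y, state``); the table has exactly one row per fly
    present per segment frame.  An empty segment yields a blank canvas and
    an empty table.
    """
    ch = config.chamber
    size = spec.canvas_px or (int(math.ceil(2 * ch.r)), int(math.ceil(2 * ch.r)))
    origin = (ch.cx - size[0] / 2.0, ch.cy - size[1] / 2.0)
    img = Image.new("RGB", size, (255, 255, 255))
    draw = ImageDraw.Draw(img)

    columns = ["frame", "fly_id", "x", "y", "state"]
    if len(tracks) == 0:
        return img, pd.DataFrame(columns=columns)

    start = int(tracks["frame"].min()) if segment_start is None else int(segment_start)
    stop = start + spec.segment_frames
    seg = tracks[(tracks["frame"] >= start) & (tracks["frame"] < stop)]
    events_by_actor: dict[int, list[BehaviorEvent]] = {}
    for ev in events:
        events_by_actor.setdefault(ev.actor_id, []).append(ev)

    rows = []
    r = spec.dot_radius_px
    for _, pt in seg.sort_values(["frame", "id"], kind="mergesort").iterrows():
        state = _state_at(events_by_actor, int(pt["id"]), int(pt["frame"]))
        px = pt["cx"] - origin[0]
        py = pt["cy"] - origin[1]
        draw.ellipse([px - r, py - r, px + r, py + r], fill=spec.colors[state])
        rows.append({"frame": int(pt["frame"]), "fly_id": int(pt["id"]),
                     "x": float(pt["cx"]), "y": float(pt["cy"]), "state": state})
    return img, pd.DataFrame(rows, columns=columns)


def occupancy_heatmap(
    tracks: pd.DataFrame,
    grid_shape: tuple[int, int],
    config: ArenaConfig,
) -> tuple[np.ndarray, Image.Image]:
    """Bin fly-frame centroids on a grid over the chamber bounding square.

    Cell (i, j) counts the fly-frames whose centroid falls in that cell; the
    matrix total equals the number of observed fly-frames (mass
    conservation), with out-of-square positions clipped into the edge cells.
    Returns the count matrix (rows = y bins) and a grayscale image.
    """
    ny, nx = grid_shape
    if ny <= 0 or nx <= 0:
        raise ValueError("grid_shape must be positive")
    ch = config.chamber
    x0, x1 = ch.cx - ch.r, ch.cx + ch.r
    y0, y1 = ch.cy - ch.r, ch.cy + ch.r
    matrix = np.zeros((ny, nx), dtype=int)
    if len(tracks):
        xi = np.clip(((tracks["cx"].to_numpy() - x0) / (x1 - x0) * nx).astype(int), 0, nx - 1)
        yi = np.clip(((tracks["cy"].to_numpy() - y0) / (y1 - y0) * ny).astype(int), 0, ny - 1)
        np.add.at(matrix, (yi, xi), 1)
    peak = matrix.max() if matrix.max() > 0 else 1
    img = Image.fromarray((255 - matrix / peak * 255).astype(np.uint8), mode="L")
    return matrix, img


def export_chain_series(chains: Iterable[ChainRecord]) -> pd.DataFrame:
    """Per-frame chain counts for rug plots: one row per frame.

    Lossless with respect to the chains file: the column is exactly the
    per-frame ``chain_count`` of the records, ordered by frame.
    """
    df = pd.DataFrame(
        [{"frame": rec.frame, "chain_count": rec.chain_count} for rec in chains],
        columns=["frame", "chain_count"],
    )
    return df.sort_values("frame", kind="mergesort").reset_index(drop=True)
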