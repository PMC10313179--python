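"""Readers and writers for detections, tracks, events, chain records, metric
reports, and arena configuration.

These are the format contracts the rest of the package depends on:

* ``detections.csv`` — per-frame object detections, columns
  ``frame,label,conf,x,y,w,h``.  ``label`` is one of ``body``, ``head``,
  ``chase``, ``wing_ext``, ``mount``; ``x, y`` are the box left/top edge in
  pixels, ``w, h`` width/height.
* ``tracks.csv`` — identity-stable trajectories in a MOT-style dialect,
  columns ``frame,id,x,y,w,h,conf,observed,heading``; ``heading`` is radians
  in (−π, π] serialized to 6 decimal places and left empty when no head was
  assigned; ``observed`` is 1 when the point comes from a detection and 0 when
  the track is coasting at its last seen position.
* ``events.json`` — typed behavior events (see :mod:`flytrax.behavior_events`).
* ``chains.csv`` — per-frame chaining records, columns
  ``frame,chain_count,components`` with components serialized as
  ``1+2+3;7+8+9`` (flies joined by ``+``, components by ``;``).
* ``config.toml`` — flat arena configuration (chamber geometry, mm-per-pixel
  scale, frame rate, food region, group size).

Coordinates follow the image convention: origin at the top-left, x rightward,
y downward, pixel units, 0-based frame indices.
"""

from __future__ import annotations

import json
import math
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArenaConfig",
    "Circle",
    "DETECTION_LABELS",
    "FormatError",
    "IntegrityError",
    "Polygon",
    "ValidationError",
    "read_chains",
    "read_config",
    "read_detections",
    "read_events",
    "read_tracks",
    "write_chains",
    "write_config",
    "write_detections",
    "write_events",
    "write_metrics",
    "write_tracks",
]

DETECTION_LABELS = ("body", "head", "chase", "wing_ext", "mount")

DETECTION_COLUMNS = ["frame", "label", "conf", "x", "y", "w", "h"]
TRACK_COLUMNS = ["frame", "id", "x", "y", "w", "h", "conf", "observed", "heading"]
CHAIN_COLUMNS = ["frame", "chain_count", "components"]


class FormatError(ValueError):
    """A file does not match the documented dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """A value violates a field invariant (e.g. conf outside [0, 1])."""


class IntegrityError(ValueError):
    """Records are structurally inconsistent (e.g. duplicate (frame, id))."""


# ---------------------------------------------------------------------------
# arena configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Circle:
    """A circle in pixel coordinates (image frame)."""

    cx: float
    cy: float
    r: float

    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-circle test (boundary inclusive)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.hypot(x - self.cx, y - self.cy) <= self.r


@dataclass(frozen=True)
class Polygon:
    """A simple polygon given as vertex arrays in pixel coordinates."""

    xs: tuple[float, ...]
    ys: tuple[float, ...]

    def __post_init__(self):
        if len(self.xs) != len(self.ys) or len(self.xs) < 3:
            raise ValidationError("polygon needs >= 3 (x, y) vertex pairs")

    def contains(self, x, y) -> np.ndarray:
        from matplotlib.path import Path as MplPath

        pts = np.column_stack([np.atleast_1d(x).astype(float), np.atleast_1d(y).astype(float)])
        path = MplPath(np.column_stack([self.xs, self.ys]))
        inside = path.contains_points(pts, radius=1e-9)
        return inside if np.ndim(x) else inside[0]

    @property
    def cx(self) -> float:
        return float(np.mean(self.xs))

    @property
    def cy(self) -> float:
        return float(np.mean(self.ys))


@dataclass(frozen=True)
class ArenaConfig:
    """Chamber geometry, scale, frame rate, food region and group size.

    Every unit conversion in the package goes through this object: pixel
    distances are multiplied by ``mm_per_px`` to obtain millimetres and frame
    counts divided by ``fps`` to obtain seconds.

    Parameters
    ----------
    n : int
        Number of flies in the group (>= 1).
    mm_per_px : float
        Image scale, millimetres per pixel.
    fps : float
        Frame rate of the recording; standard group-assay videos run at
        30 frames per second, which is the default.
    chamber : Circle
        Circular chamber footprint in pixels.  When not given, a 4 cm
        diameter chamber (the standard group-courtship chamber) is assumed
        and converted through ``mm_per_px``, centred at (r, r).
    food_roi : Circle | Polygon | None
        Optional food region, used by the foraging metrics.
    body_length_mm : float
        Nominal fly body length, used by the jump classifier (default 2.5).
    """

    n: int
    mm_per_px: float
    fps: float = 30.0
    chamber: Circle | None = None
    food_roi: Circle | Polygon | None = None
    body_length_mm: float = 2.5

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"group size n must be >= 1, got {self.n}")
        if not self.mm_per_px > 0:
            raise ValidationError(f"mm_per_px must be > 0, got {self.mm_per_px}")
        if not self.fps > 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        if self.chamber is None:
            # default: 4 cm diameter chamber, centred at (r, r)
            r = 20.0 / self.mm_per_px
            object.__setattr__(self, "chamber", Circle(r, r, r))
        if not self.chamber.r > 0:
            raise ValidationError("chamber radius must be > 0")
        if self.food_roi is not None:
            self._check_roi_in_chamber()

    def _check_roi_in_chamber(self):
        roi = self.food_roi
        ch = self.chamber
        if isinstance(roi, Circle):
            ok = math.hypot(roi.cx - ch.cx, roi.cy - ch.cy) + roi.r <= ch.r + 1e-9
        else:
            ok = bool(np.all(np.hypot(np.array(roi.xs) - ch.cx, np.array(roi.ys) - ch.cy) <= ch.r + 1e-9))
        if not ok:
            raise ValidationError("food_roi must lie within the chamber")

    @property
    def px_per_mm(self) -> float:
        return 1.0 / self.mm_per_px

    def to_mm(self, px) -> np.ndarray | float:
        return np.asarray(px) * self.mm_per_px if np.ndim(px) else px * self.mm_per_px

    def speed_mm_s(self, px_per_frame) -> np.ndarray | float:
        """Convert a per-frame pixel displacement to mm/s."""
        return np.asarray(px_per_frame) * self.mm_per_px * self.fps


_KNOWN_CONFIG_KEYS = {"n", "group_size", "mm_per_px", "fps", "body_length_mm", "chamber", "food_roi"}


def read_config(path: str | Path) -> ArenaConfig:
    """Read an :class:`ArenaConfig` from a flat TOML file.

    Recognized keys: ``n`` (or ``group_size``), ``mm_per_px``, ``fps``,
    ``body_length_mm``, ``[chamber]`` (``center_x, center_y, radius``),
    ``[food_roi]`` (circle: ``center_x, center_y, radius``; polygon:
    ``xs = [...], ys = [...]``).  Unknown keys raise a warning, not an error;
    omitted keys take their documented defaults (``fps`` = 30).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    for key in raw:
        if key not in _KNOWN_CONFIG_KEYS:
            warnings.warn(f"unknown config key {key!r} in {path.name} ignored", stacklevel=2)
    if "n" not in raw and "group_size" not in raw:
        raise FormatError(f"{path.name}: missing required key 'n'")
    if "mm_per_px" not in raw:
        raise FormatError(f"{path.name}: missing required key 'mm_per_px'")
    n = int(raw.get("n", raw.get("group_size")))
    chamber = None
    if "chamber" in raw:
        c = raw["chamber"]
        chamber = Circle(float(c["center_x"]), float(c["center_y"]), float(c["radius"]))
    food_roi = None
    if "food_roi" in raw:
        f = raw["food_roi"]
        if "radius" in f:
            food_roi = Circle(float(f["center_x"]), float(f["center_y"]), float(f["radius"]))
        else:
            food_roi = Polygon(tuple(map(float, f["xs"])), tuple(map(float, f["ys"])))
    return ArenaConfig(
        n=n,
        mm_per_px=float(raw["mm_per_px"]),
        fps=float(raw.get("fps", 30.0)),
        chamber=chamber,
        food_roi=food_roi,
        body_length_mm=float(raw.get("body_length_mm", 2.5)),
    )


def write_config(config: ArenaConfig, path: str | Path) -> None:
    """Write an :class:`ArenaConfig` back to its TOML dialect."""
    lines = [
        f"n = {config.n}",
        f"mm_per_px = {config.mm_per_px!r}",
        f"fps = {config.fps!r}",
        f"body_length_mm = {config.body_length_mm!r}",
        "",
        "[chamber]",
        f"center_x = {config.chamber.cx!r}",
        f"center_y = {config.chamber.cy!r}",
        f"radius = {config.chamber.r!r}",
    ]
    roi = config.food_roi
    if isinstance(roi, Circle):
        lines += ["", "[food_roi]", f"center_x = {roi.cx!r}", f"center_y = {roi.cy!r}", f"radius = {roi.r!r}"]
    elif isinstance(roi, Polygon):
        lines += ["", "[food_roi]", f"xs = {list(roi.xs)!r}", f"ys = {list(roi.ys)!r}"]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------


def _read_csv_checked(path: Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path.name}: empty file, expected a header row") from None
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    return df


def _to_numeric(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    # to_numeric only flags bad rows; astype(float) does the actual parse
    # because its conversion is exactly round-trip for repr-formatted floats
    probe = pd.to_numeric(df[col], errors="coerce")
    bad = probe.isna() & df[col].notna()
    if bad.any():
        # +2: header line plus 1-based line numbering
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path.name}, line {line}: non-numeric value {df[col][bad.idxmax()]!r} in column {col!r}")
    return df[col].astype(float)


def read_detections(path: str | Path) -> pd.DataFrame:
    """Read a detections CSV into a validated, deterministically ordered frame.

    Returns a DataFrame with columns ``frame, label, conf, x, y, w, h`` plus
    derived centroid columns ``cx, cy``, sorted by ``(frame, label, x, y)``.

    Raises
    ------
    FormatError
        Missing column, or non-numeric geometry (reported with line number).
    ValidationError
        ``conf`` outside [0, 1], non-positive ``w``/``h``, negative ``frame``,
        or an unknown label.
    """
    path = Path(path)
    df = _read_csv_checked(path, DETECTION_COLUMNS)
    if len(df) == 0:
        out = pd.DataFrame(columns=DETECTION_COLUMNS + ["cx", "cy"])
        return out.astype({"frame": int, "label": str, **{c: float for c in ("conf", "x", "y", "w", "h", "cx", "cy")}})
    for col in ("frame", "conf", "x", "y", "w", "h"):
        df[col] = _to_numeric(df, col, path)
    bad_label = ~df["label"].isin(DETECTION_LABELS)
    if bad_label.any():
        line = int(bad_label.idxmax()) + 2
        raise ValidationError(f"{path.name}, line {line}: unknown label {df['label'][bad_label.idxmax()]!r}")
    if (df["frame"] < 0).any():
        line = int((df["frame"] < 0).idxmax()) + 2
        raise ValidationError(f"{path.name}, line {line}: negative frame index")
    if ((df["conf"] < 0) | (df["conf"] > 1)).any():
        line = int(((df["conf"] < 0) | (df["conf"] > 1)).idxmax()) + 2
        raise ValidationError(f"{path.name}, line {line}: conf outside [0, 1]")
    if ((df["w"] <= 0) | (df["h"] <= 0)).any():
        line = int(((df["w"] <= 0) | (df["h"] <= 0)).idxmax()) + 2
        raise ValidationError(f"{path.name}, line {line}: box width/height must be > 0")
    df["frame"] = df["frame"].astype(int)
    df["cx"] = df["x"] + df["w"] / 2.0
    df["cy"] = df["y"] + df["h"] / 2.0
    df = df.sort_values(["frame", "label", "x", "y"], kind="mergesort").reset_index(drop=True)
    return df[DETECTION_COLUMNS + ["cx", "cy"]]


def write_detections(detections: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write detections in the documented CSV dialect (deterministic bytes)."""
    df = detections.copy()
    if len(df):
        df = df.sort_values(["frame", "label", "x", "y"], kind="mergesort")
    _write_csv(df[DETECTION_COLUMNS] if len(df) else pd.DataFrame(columns=DETECTION_COLUMNS),
               path, header_comment)


def _write_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def write_tracks(tracks: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write tracks to the MOT-style CSV dialect.

    Rows are sorted by ``(frame, id)``; ``observed`` serializes as 1/0 and
    ``heading`` as radians with 6 decimal places (empty when absent).
    """
    df = tracks.copy()
    if len(df):
        if df.duplicated(["frame", "id"]).any():
            raise IntegrityError("duplicate (frame, id) in tracks")
        df = df.sort_values(["frame", "id"], kind="mergesort")
        df["observed"] = df["observed"].astype(bool).astype(int)
        df["heading"] = df["heading"].map(lambda h: "" if pd.isna(h) else f"{h:.6f}")
    else:
        df = pd.DataFrame(columns=TRACK_COLUMNS)
    _write_csv(df[TRACK_COLUMNS] if len(df) else df, path, header_comment)


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a tracks CSV; inverse of :func:`write_tracks`.

    Returns columns ``frame, id, x, y, w, h, conf, observed, heading`` plus
    centroids ``cx, cy``; ``observed`` is boolean and ``heading`` NaN where
    absent.  Duplicate ``(frame, id)`` pairs raise :class:`IntegrityError`.
    """
    path = Path(path)
    df = _read_csv_checked(path, TRACK_COLUMNS)
    if len(df) == 0:
        return empty_tracks()
    for col in ("frame", "id", "x", "y", "w", "h", "observed"):
        df[col] = _to_numeric(df, col, path)
    df["conf"] = _to_numeric(df, "conf", path)
    df["heading"] = df["heading"].astype(float)
    df["frame"] = df["frame"].astype(int)
    df["id"] = df["id"].astype(int)
    df["observed"] = df["observed"].astype(bool)
    if df.duplicated(["frame", "id"]).any():
        dup = df[df.duplicated(["frame", "id"])].iloc[0]
        raise IntegrityError(f"{path.name}: duplicate (frame={int(dup['frame'])}, id={int(dup['id'])})")
    df["cx"] = df["x"] + df["w"] / 2.0
    df["cy"] = df["y"] + df["h"] / 2.0
    return df.sort_values(["frame", "id"], kind="mergesort").reset_index(drop=True)


def empty_tracks() -> pd.DataFrame:
    """An empty tracks frame with the canonical columns and dtypes."""
    df = pd.DataFrame(columns=TRACK_COLUMNS + ["cx", "cy"])
    return df.astype({"frame": int, "id": int, "observed": bool,
                      **{c: float for c in ("x", "y", "w", "h", "conf", "heading", "cx", "cy")}})


# ---------------------------------------------------------------------------
# events / chains / metrics
# ---------------------------------------------------------------------------


def write_events(events: Iterable, path: str | Path) -> None:
    """Write behavior events to ``events.json``."""
    payload = [
        {
            "type": ev.type,
            "start_frame": int(ev.start_frame),
            "end_frame": int(ev.end_frame),
            "actor_id": int(ev.actor_id),
            "target_id": None if ev.target_id is None else int(ev.target_id),
            "source": ev.source,
        }
        for ev in events
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_events(path: str | Path) -> list:
    from .behavior_events import BehaviorEvent

    payload = json.loads(Path(path).read_text())
    return [
        BehaviorEvent(
            type=d["type"],
            start_frame=d["start_frame"],
            end_frame=d["end_frame"],
            actor_id=d["actor_id"],
            target_id=d.get("target_id"),
            source=d.get("source", "detector"),
        )
        for d in payload
    ]


def write_chains(chains: Iterable, path: str | Path, header_comment: str | None = None) -> None:
    """Write per-frame chain records to ``chains.csv``.

    Components serialize as ``;``-separated groups of ``+``-joined fly ids,
    each group sorted ascending, groups ordered by their smallest member.
    """
    rows = []
    for rec in chains:
        comps = sorted((sorted(c) for c in rec.components), key=lambda c: c[0])
        rows.append({
            "frame": int(rec.frame),
            "chain_count": int(rec.chain_count),
            "components": ";".join("+".join(map(str, c)) for c in comps),
        })
    df = pd.DataFrame(rows, columns=CHAIN_COLUMNS)
    if len(df):
        df = df.sort_values("frame", kind="mergesort")
    _write_csv(df, path, header_comment)


def read_chains(path: str | Path) -> list:
    from .behavior_events import ChainRecord

    path = Path(path)
    df = _read_csv_checked(path, CHAIN_COLUMNS)
    out = []
    for _, row in df.iterrows():
        comp_str = row["components"]
        comps = []
        if isinstance(comp_str, str) and comp_str:
            comps = [frozenset(int(i) for i in grp.split("+")) for grp in comp_str.split(";")]
        out.append(ChainRecord(frame=int(row["frame"]), components=tuple(comps)))
        if out[-1].chain_count != int(row["chain_count"]):
            raise IntegrityError(
                f"{path.name}: chain_count {row['chain_count']} inconsistent with components at frame {row['frame']}"
            )
    return out


def write_metrics(report: dict, path: str | Path) -> None:
    """Write a metrics report (nested dict) to ``metrics.json``."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=1, default=_default, allow_nan=False) + "\n")
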