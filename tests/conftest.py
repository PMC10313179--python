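import math

import numpy as np
import pandas as pd
import pytest

from flytrax.arena_io import ArenaConfig, Circle


@pytest.fixture
def config():
    """Standard 4-cm chamber at 0.05 mm/px (radius 400 px), 30 fps, 13 flies."""
    return ArenaConfig(n=13, mm_per_px=0.05)


@pytest.fixture
def pair_config():
    return ArenaConfig(n=2, mm_per_px=0.05)


def make_tracks(positions, fps_heading=None, observed=None, w=12.0, h=6.0):
    """Build a tracks frame from positions[frame][id-1] = (cx, cy).

    ``fps_heading[frame][id-1]`` optionally supplies headings (radians).
    """
    rows = []
    for f, frame_pos in enumerate(positions):
        for i, (cx, cy) in enumerate(frame_pos):
            rows.append({
                "frame": f, "id": i + 1,
                "x": cx - w / 2, "y": cy - h / 2, "w": w, "h": h,
                "conf": 1.0,
                "observed": True if observed is None else bool(observed[f][i]),
                "heading": math.nan if fps_heading is None else fps_heading[f][i],
                "cx": cx, "cy": cy,
            })
    return pd.DataFrame(rows)


def straight_run(n_frames, start, step, fly_count=1, spacing=(0.0, 50.0)):
    """Positions for flies moving in lockstep along a constant step vector."""
    out = []
    for f in range(n_frames):
        frame = []
        for i in range(fly_count):
            frame.append((start[0] + f * step[0] + i * spacing[0],
                          start[1] + f * step[1] + i * spacing[1]))
        out.append(frame)
    return out
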