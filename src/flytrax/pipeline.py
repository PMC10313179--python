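"""End-to-end convenience: detections → tracks → events → chains → metrics.

Thin composition of the stage modules so scripts, tests and the CLI run the
same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .arena_io import ArenaConfig
from .behavior_events import (
    BehaviorEvent,
    ChainRecord,
    ChaseParams,
    attribute_detector_events,
    classify_kinematic_chases,
    detect_chaining,
)
from .social_metrics import MetricParams, compute_metrics
from .tracking import TrackerParams, assign_heads, link_detections

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    tracks: pd.DataFrame
    events: list[BehaviorEvent]
    chains: list[ChainRecord]
    metrics: dict


def run_pipeline(
    detections: pd.DataFrame,
    config: ArenaConfig,
    tracker_params: TrackerParams | None = None,
    chase_params: ChaseParams | None = None,
    metric_params: MetricParams | None = None,
    use_detector_events: bool = False,
) -> PipelineResult:
    """Link, classify, aggregate and measure in one call.

    Body detections are linked by distance-sort, head detections supply
    headings, chases come either from detector-labeled boxes
    (``use_detector_events``) or the kinematic classifier, chases aggregate
    into per-frame chain records, and the full metrics report is computed.
    """
    tracker_params = tracker_params or TrackerParams()
    tracks = link_detections(detections, config, tracker_params)
    if len(tracks) == 0:
        raise ValueError("no body detections to link")
    tracks = assign_heads(tracks, detections, tracker_params)
    if use_detector_events:
        events = attribute_detector_events(detections, tracks, config)
    else:
        events = classify_kinematic_chases(tracks, config, chase_params)
    frame_range = (int(tracks["frame"].min()), int(tracks["frame"].max()) + 1)
    chains = detect_chaining(events, frame_range, config.n)
    metrics = compute_metrics(tracks, events, chains, config, metric_params)
    return PipelineResult(tracks=tracks, events=events, chains=chains, metrics=metrics)
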