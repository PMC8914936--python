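"""End-to-end orchestration: filter, segment, classify, decode, trigger.

``run_full_pipeline`` runs the two recognition chains over one trace:

1. action chain -- moving-average filter, window labeling, motion-unit
   extraction; as soon as the second motion unit has closed, the 18-value
   action vector is matched against the template library (later units are
   ignored: the call is made once, as early as possible);
2. state chain -- per-window features of the hand's composite angular
   velocity, GRNN decoding at the state stride, and the grasp trigger.

The report echoes every tunable that affects the output, so re-running
with the echoed configuration on the same input reproduces it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import pandas as pd

from . import __version__
from .action_dtw import TemplateLibrary, classify_action
from .errors import NotReadyError
from .grasp_control import run_stream
from .segmentation import (
    DEFAULT_MOVE_THRESH_DEG,
    DEFAULT_STATIC_THRESH_DEG,
    build_action_vector,
    extract_motion_units,
    segment_trace,
    segments_to_records,
    units_to_records,
)
from .signal_processing import (
    DEFAULT_FILTER_WIDTH,
    DEFAULT_WINDOW_LENGTH,
    filter_trace,
)
from .state_grnn import GrnnModel
from .trace import Trace

logger = logging.getLogger("limbintent")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable that affects pipeline output."""

    window_length: int = DEFAULT_WINDOW_LENGTH
    segmentation_stride: int = 1
    state_stride: int = 10
    static_thresh: float = DEFAULT_STATIC_THRESH_DEG
    move_thresh: float = DEFAULT_MOVE_THRESH_DEG
    filter_width: int = DEFAULT_FILTER_WIDTH
    filter_velocities: bool = True
    state_part: str = "hand"
    template_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 2 or self.segmentation_stride < 1 or self.state_stride < 1:
            raise ValueError("window length and strides must be positive")
        if not (0.0 < self.static_thresh < self.move_thresh):
            raise ValueError("need 0 < static_thresh < move_thresh")
        if self.filter_width < 1 or self.filter_width % 2 == 0:
            raise ValueError("filter width must be a positive odd integer")


@dataclass
class RunReport:
    """Self-contained result of one pipeline run."""

    action: str | None  # None while fewer than two motion units exist
    action_ready: bool
    distances: dict[str, float]
    margin: float | None
    segments: list[dict]
    motion_units: list[dict]
    state_timeline: pd.DataFrame
    commands: list[dict]
    config: dict
    version: str
    input_digest: str

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "action_ready": self.action_ready,
            "distances": self.distances,
            "margin": self.margin,
            "segments": self.segments,
            "motion_units": self.motion_units,
            "state_timeline": self.state_timeline.to_dict(orient="list"),
            "commands": self.commands,
            "config": self.config,
            "version": self.version,
            "input_digest": self.input_digest,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def trace_digest(trace: Trace) -> str:
    """Stable content digest of a trace (12 hex chars of SHA-256)."""
    payload = trace.data.round(9).to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_full_pipeline(
    trace: Trace,
    config: PipelineConfig,
    model: GrnnModel,
    library: TemplateLibrary,
) -> RunReport:
    logger.info(
        "pipeline start: filter_width=%d window=%d seg_stride=%d state_stride=%d "
        "thresholds=(%.3g, %.3g)",
        config.filter_width, config.window_length, config.segmentation_stride,
        config.state_stride, config.static_thresh, config.move_thresh,
    )
    filtered = filter_trace(
        trace, width=config.filter_width,
        include_velocities=config.filter_velocities,
    )
    segments = segment_trace(
        filtered,
        length=config.window_length,
        stride=config.segmentation_stride,
        static_thresh=config.static_thresh,
        move_thresh=config.move_thresh,
    )
    units = extract_motion_units(filtered, segments)

    action = None
    distances: dict[str, float] = {}
    margin = None
    ready = False
    try:
        vector = build_action_vector(units[:2])
    except NotReadyError:
        logger.info("action call not ready: %d motion unit(s) so far", len(units))
    else:
        result = classify_action(vector, library)
        action, distances, margin = result.action, result.distances, result.margin
        ready = True
        logger.info("action classified as %r (margin %.4g)", action, margin)

    timeline, commands = run_stream(
        filtered, model,
        stride=config.state_stride,
        length=config.window_length,
        part=config.state_part,
    )
    return RunReport(
        action=action,
        action_ready=ready,
        distances={a: float(d) for a, d in distances.items()},
        margin=None if margin is None else float(margin),
        segments=segments_to_records(filtered, segments),
        motion_units=units_to_records(filtered, units),
        state_timeline=timeline,
        commands=[{"t": c.t, "command": c.command} for c in commands],
        config=asdict(config),
        version=__version__,
        input_digest=trace_digest(trace),
    )
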