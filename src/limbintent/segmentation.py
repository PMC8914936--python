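"""Static/movement labeling, motion-unit extraction, and action vectors.

A window is *static* when, on every one of the 9 Euler-angle channels
(3 parts x 3 axes), the largest absolute difference between adjacent
samples stays below 0.3 deg; it is *movement* when any channel exceeds
1 deg.  The band in between is not defined by those two rules, so such
windows are labeled *indeterminate* and inherit the previous resolved
label (hysteresis); a trace is assumed to start at rest, so a leading
indeterminate run resolves to static.

Maximal runs of equally labeled samples form alternating static and
movement segments.  Each movement segment is a *motion unit*; its
9 per-channel angle deltas (angle at the segment's last sample minus
angle at its first) are the unit's signature, and the concatenated
deltas of the first two units form the 18-value action feature vector
matched against the template library.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import NotReadyError
from .signal_processing import DEFAULT_WINDOW_LENGTH, Window, slide_windows
from .trace import ANGLE_AXES, PARTS, Trace

DEFAULT_STATIC_THRESH_DEG = 0.3
DEFAULT_MOVE_THRESH_DEG = 1.0


class SegmentLabel(str, enum.Enum):
    STATIC = "static"
    MOVEMENT = "movement"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Segment:
    """A maximal run of same-labeled samples (inclusive 0-based indices)."""

    label: SegmentLabel
    start_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if self.start_idx > self.end_idx:
            raise ValueError("segment start must not exceed its end")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass(frozen=True)
class MotionUnit:
    """One maximal movement segment with its 9 angle deltas (degrees).

    ``deltas`` is ordered (upper_arm, lower_arm, hand) x (roll, pitch, yaw).
    """

    ordinal: int
    start_idx: int
    end_idx: int
    deltas: np.ndarray

    def __post_init__(self) -> None:
        if self.deltas.shape != (9,):
            raise ValueError("deltas must have exactly 9 entries")

    def deltas_by_part(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for i, part in enumerate(PARTS):
            out[part] = {
                axis: float(self.deltas[3 * i + j])
                for j, axis in enumerate(ANGLE_AXES)
            }
        return out


def _check_thresholds(static_thresh: float, move_thresh: float) -> None:
    if not (0.0 < static_thresh < move_thresh):
        raise ValueError(
            "thresholds must satisfy 0 < static_thresh < move_thresh, got "
            f"static={static_thresh}, move={move_thresh}"
        )


def label_window(
    window: Window,
    static_thresh: float = DEFAULT_STATIC_THRESH_DEG,
    move_thresh: float = DEFAULT_MOVE_THRESH_DEG,
) -> SegmentLabel:
    """Label one window static / movement / indeterminate.

    Computes, for each of the 9 angle channels, the maximum absolute
    adjacent-sample difference inside the window; static requires all nine
    maxima below ``static_thresh``, movement requires any maximum above
    ``move_thresh``.
    """
    _check_thresholds(static_thresh, move_thresh)
    angles = window.angle_slice()
    maxima = np.max(np.abs(np.diff(angles, axis=0)), axis=0)
    if np.all(maxima < static_thresh):
        return SegmentLabel.STATIC
    if np.any(maxima > move_thresh):
        return SegmentLabel.MOVEMENT
    return SegmentLabel.INDETERMINATE


def per_sample_labels(
    trace: Trace,
    length: int = DEFAULT_WINDOW_LENGTH,
    stride: int = 1,
    static_thresh: float = DEFAULT_STATIC_THRESH_DEG,
    move_thresh: float = DEFAULT_MOVE_THRESH_DEG,
) -> list[SegmentLabel]:
    """Resolved per-sample labels (static or movement only).

    Window labels are attached to each window's last sample; the leading
    ``length - 1`` samples inherit the first window's label.  Indeterminate
    windows inherit the previous resolved label (the first window defaults
    to static).  With stride > 1, samples between consecutive window ends
    take the label of the window that closes at or after them; trailing
    samples inherit the last window's label.
    """
    _check_thresholds(static_thresh, move_thresh)
    windows = slide_windows(trace, length=length, stride=stride)
    resolved: list[SegmentLabel] = []
    prev = SegmentLabel.STATIC  # actions start at rest
    for w in windows:
        raw = label_window(w, static_thresh=static_thresh, move_thresh=move_thresh)
        prev = prev if raw is SegmentLabel.INDETERMINATE else raw
        resolved.append(prev)

    n = trace.n_samples
    labels: list[SegmentLabel] = [SegmentLabel.STATIC] * n
    ends = [w.end for w in windows]
    wi = 0
    for i in range(n):
        while wi < len(ends) - 1 and ends[wi] < i:
            wi += 1
        labels[i] = resolved[wi]
    return labels


def segment_trace(
    trace: Trace,
    length: int = DEFAULT_WINDOW_LENGTH,
    stride: int = 1,
    static_thresh: float = DEFAULT_STATIC_THRESH_DEG,
    move_thresh: float = DEFAULT_MOVE_THRESH_DEG,
    min_samples: int = 1,
) -> list[Segment]:
    """Merge per-sample labels into alternating static/movement segments.

    ``min_samples`` optionally absorbs segments shorter than the given
    length into their predecessor (morphological cleanup, off by default).
    """
    labels = per_sample_labels(
        trace, length=length, stride=stride,
        static_thresh=static_thresh, move_thresh=move_thresh,
    )
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] is not labels[start]:
            segments.append(Segment(labels[start], start, i - 1))
            start = i
    if min_samples > 1:
        segments = _absorb_short_segments(segments, min_samples)
    return segments


def _absorb_short_segments(segments: list[Segment], min_samples: int) -> list[Segment]:
    merged: list[Segment] = []
    for seg in segments:
        if merged and (seg.n_samples < min_samples or merged[-1].label is seg.label):
            prev = merged.pop()
            merged.append(Segment(prev.label, prev.start_idx, seg.end_idx))
        else:
            merged.append(seg)
    return merged


def extract_motion_units(trace: Trace, segments: list[Segment]) -> list[MotionUnit]:
    """One motion unit per movement segment, in temporal order.

    Deltas are angle(end_idx) - angle(start_idx) on the trace as given;
    pass a filtered trace to measure deltas on smoothed angles.
    """
    angles = trace.angle_matrix()
    units = []
    for seg in segments:
        if seg.label is not SegmentLabel.MOVEMENT:
            continue
        deltas = angles[seg.end_idx] - angles[seg.start_idx]
        units.append(
            MotionUnit(
                ordinal=len(units) + 1,
                start_idx=seg.start_idx,
                end_idx=seg.end_idx,
                deltas=deltas,
            )
        )
    return units


def build_action_vector(units: list[MotionUnit]) -> np.ndarray:
    """Concatenate the first two units' deltas into the 18-value vector.

    Raises :class:`NotReadyError` while fewer than two motion units exist:
    on a live stream the action call simply has to wait for the second
    unit to close.
    """
    if len(units) < 2:
        raise NotReadyError(
            f"need 2 motion units to build the action vector, have {len(units)}"
        )
    return np.concatenate([units[0].deltas, units[1].deltas])


def segments_to_records(trace: Trace, segments: list[Segment]) -> list[dict]:
    """JSON-friendly segment records with start/end times in seconds."""
    t = trace.t
    return [
        {
            "label": seg.label.value,
            "start_idx": seg.start_idx,
            "end_idx": seg.end_idx,
            "t_start": float(t[seg.start_idx]),
            "t_end": float(t[seg.end_idx]),
        }
        for seg in segments
    ]


def units_to_records(trace: Trace, units: list[MotionUnit]) -> list[dict]:
    """JSON-friendly motion-unit records with deltas keyed by part and axis."""
    t = trace.t
    return [
        {
            "ordinal": u.ordinal,
            "start_idx": u.start_idx,
            "end_idx": u.end_idx,
            "t_start": float(t[u.start_idx]),
            "t_end": float(t[u.end_idx]),
            "deltas": u.deltas_by_part(),
        }
        for u in units
    ]
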