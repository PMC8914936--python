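"""Grasp trigger: open/close commands on deceleration-to-static edges.

Reaching for an object ends with the arm coming to rest: the grasp (or
release) happens in the static state that follows a deceleration state.
The controller therefore emits a command exactly when the decoded state
changes from -1 (deceleration) to 0 (static); the command toggles the
effector posture, starting from an open hand, so commands alternate
close / open / close ...  A static state after acceleration, or renewed
acceleration after deceleration without an intervening static state,
emits nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_processing import slide_windows
from .state_grnn import (
    STATE_DECELERATION,
    STATE_STATIC,
    GrnnModel,
    decode_state,
    grnn_predict,
    state_features,
)
from .trace import Trace

COMMAND_CLOSE = "close"
COMMAND_OPEN = "open"


@dataclass(frozen=True)
class GraspCommand:
    t: float
    command: str


@dataclass
class GraspController:
    """Finite-state trigger over a stream of decoded motion states."""

    initially_open: bool = True
    prev_state: int | None = None
    hand_open: bool = field(init=False)
    command_log: list[GraspCommand] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hand_open = self.initially_open

    def update(self, state: int, t: float) -> str | None:
        """Feed one decoded state; returns the emitted command, if any."""
        if self.command_log and t < self.command_log[-1].t:
            raise ValueError("timestamps must be non-decreasing")
        command = None
        if self.prev_state == STATE_DECELERATION and state == STATE_STATIC:
            command = COMMAND_CLOSE if self.hand_open else COMMAND_OPEN
            self.hand_open = not self.hand_open
            self.command_log.append(GraspCommand(t=float(t), command=command))
        self.prev_state = int(state)
        return command


def run_stream(
    trace: Trace,
    model: GrnnModel,
    stride: int = 10,
    length: int = 10,
    part: str = "hand",
) -> tuple[pd.DataFrame, list[GraspCommand]]:
    """Decode per-window motion states and run the grasp trigger.

    Returns a frame with columns ``t`` (each window's last-sample time) and
    ``state`` (decoded label), plus the command log.
    """
    windows = slide_windows(trace, length=length, stride=stride, part=part)
    rows = np.stack([state_features(w.e_values) for w in windows])
    states = decode_state(grnn_predict(model, rows))
    controller = GraspController()
    times = [w.t_end for w in windows]
    for t, s in zip(times, states):
        controller.update(int(s), t)
    timeline = pd.DataFrame({"t": times, "state": states.astype(int)})
    return timeline, controller.command_log
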