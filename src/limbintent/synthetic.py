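"""Labeled synthetic IMU traces with the structure the pipeline assumes.

No public recording of the three dressing actions exists, so every stage
is exercised on generated traces: alternating *hold* phases (the arm at
rest, angles jittering well below the 0.3 deg static rule) and *move*
phases whose net per-channel angle changes hit scripted targets -- the
canonical scripts use the bundled template-library deltas for their first
two move phases, so a generated action is recoverable by the classifier.

The scripted net deltas are small (magnitudes below 2 deg), far too small
for a plain ramp at 50 Hz to ever produce the >1 deg adjacent-sample
change that defines a movement window.  Real reaching motions solve this
the same way the generator does: the hand sweeps far and comes back.  Each
move phase therefore superimposes, on top of the per-channel smoothstep
ramps to the net targets:

* a closed circular excursion of the hand's roll/pitch pair (radius
  ``excursion_deg``), traversed with smoothstep timing once the onset
  swing (below) has finished -- it returns exactly to its start, so net
  deltas are untouched, and its speed profile is unimodal (rise then
  fall), giving each move phase one acceleration run followed by one
  deceleration run of the hand's composite angular velocity E;
* a short antisymmetric jerk swing on the hand yaw angle at motion onset
  (amplitude ``onset_jerk_deg``, down-then-up over nine samples), so the
  movement rule fires within a few samples of the true onset even after
  moving-average filtering -- and because the swing is antisymmetric, the
  filtered yaw at the first movement-labeled sample sits at the hold value,
  keeping the measured unit deltas on target.  The jerk lives only in the
  angle channels; the velocity channels are the analytic derivative of the
  smooth profile, which keeps the analytic E reference unimodal per move.

Ground truth per sample: the generating phase (hold -> static segment,
move -> movement segment), the motion state (0 in holds; 1 while the
analytic hand E rises, -1 while it falls), and the exact net deltas of
every move phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .action_dtw import ReferenceTemplate, default_templates
from .errors import GenerationError
from .segmentation import (
    DEFAULT_MOVE_THRESH_DEG,
    DEFAULT_STATIC_THRESH_DEG,
    Segment,
    SegmentLabel,
)
from .signal_processing import slide_windows
from .state_grnn import FEATURE_COLUMNS, state_features
from .trace import (
    ANGLE_AXES,
    DEFAULT_RATE_HZ,
    GYRO_AXES,
    PARTS,
    Trace,
    channel_name,
)

HOLD = "hold"
MOVE = "move"

#: Default amplitude of the closed hand excursion during a move (degrees).
DEFAULT_EXCURSION_DEG = 8.0

#: Default half-amplitude of the onset jerk swing on hand yaw (degrees).
DEFAULT_ONSET_JERK_DEG = 4.0

#: Antisymmetric onset swing, samples 0..8 of a move phase (x amplitude).
_JERK_PROFILE = (0.0, -0.5, -1.0, -0.5, 0.0, 0.5, 1.0, 0.5, 0.0)
_MIN_MOVE_SAMPLES = 15


@dataclass(frozen=True)
class Phase:
    """One scripted phase: a hold, or a move with net angle targets.

    ``deltas`` maps each part to its (roll, pitch, yaw) net change in
    degrees; required for moves, absent for holds.
    """

    kind: str
    duration_s: float
    deltas: dict[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (HOLD, MOVE):
            raise ValueError(f"phase kind must be {HOLD!r} or {MOVE!r}")
        if self.duration_s <= 0:
            raise ValueError("phase duration must be positive")
        if self.kind == MOVE:
            if self.deltas is None or set(self.deltas) != set(PARTS):
                raise ValueError("a move phase needs deltas for all three parts")
        elif self.deltas is not None:
            raise ValueError("a hold phase takes no deltas")

    def delta_vector(self) -> np.ndarray:
        """The 9 net changes in fixed (part, axis) order."""
        assert self.deltas is not None
        return np.array([self.deltas[p][j] for p in PARTS for j in range(3)])


@dataclass(frozen=True)
class ActionScript:
    """Alternating hold/move phases, beginning and ending with a hold."""

    action: str
    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if len(self.phases) < 1:
            raise ValueError("script needs at least one phase")
        if self.phases[0].kind != HOLD or self.phases[-1].kind != HOLD:
            raise ValueError("scripts must begin and end with hold phases")
        for a, b in zip(self.phases, self.phases[1:]):
            if a.kind == b.kind:
                raise ValueError("holds and moves must alternate")

    @property
    def n_moves(self) -> int:
        return sum(1 for p in self.phases if p.kind == MOVE)

    @property
    def n_holds(self) -> int:
        return sum(1 for p in self.phases if p.kind == HOLD)

    @property
    def duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor-noise knobs for the generator.

    ``hold_jitter_deg`` is the per-sample angle noise during holds (its
    draws are clipped at 2.8 sigma so adjacent differences stay clear of
    the 0.3 deg static rule); ``move_overshoot`` multiplies each move's
    net deltas by ``1 + N(0, move_overshoot)`` per channel;
    ``velocity_noise`` (degrees/s) is added to every gyro channel.
    """

    hold_jitter_deg: float = 0.05
    move_overshoot: float = 0.05
    velocity_noise: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hold_jitter_deg", "move_overshoot", "velocity_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


ZERO_NOISE = NoiseSpec(hold_jitter_deg=0.0, move_overshoot=0.0,
                       velocity_noise=0.0, seed=0)


@dataclass
class GroundTruth:
    """Per-sample labels and per-move net deltas for a generated trace."""

    phase_of_sample: np.ndarray
    segment_labels: np.ndarray  # "static" / "movement" per sample
    states: np.ndarray  # 0 / 1 / -1 per sample
    unit_deltas: list[np.ndarray]  # actual 9-vector per move phase
    phase_bounds: list[tuple[int, int, str]]  # (start, end, kind) per phase
    e_analytic: np.ndarray  # noiseless hand composite angular velocity
    seed: int

    def segments(self) -> list[Segment]:
        """The scripted phases as static/movement segments."""
        return [
            Segment(
                SegmentLabel.STATIC if kind == HOLD else SegmentLabel.MOVEMENT,
                start,
                end,
            )
            for start, end, kind in self.phase_bounds
        ]

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "phase_bounds": [
                {"start_idx": int(s), "end_idx": int(e), "kind": k}
                for s, e, k in self.phase_bounds
            ],
            "states": self.states.tolist(),
            "unit_deltas": [d.tolist() for d in self.unit_deltas],
        }


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def _smoothstep_deriv(u: np.ndarray) -> np.ndarray:
    return 6.0 * u * (1.0 - u)


def _template_unit_deltas(action: str) -> tuple[dict, dict]:
    """(unit-1, unit-2) per-part delta dicts from the bundled library."""
    values = default_templates().templates[action].values

    def as_dict(v: np.ndarray) -> dict:
        return {p: tuple(float(x) for x in v[3 * i : 3 * i + 3])
                for i, p in enumerate(PARTS)}

    return as_dict(values[:9]), as_dict(values[9:])


def _scaled(deltas: dict, factor: float) -> dict:
    return {p: tuple(factor * x for x in v) for p, v in deltas.items()}


def canonical_script(action: str) -> ActionScript:
    """The bundled script for one action.

    The first two move phases hit the bundled template-library deltas for
    that action, so the generated action classifies back to its label.  The
    socks script has exactly five holds and four moves; shoes mirrors that
    structure; laces has an extra short adjustment move (six holds, five
    moves) and a shorter second move.  Later moves retrace the first two,
    returning the arm toward its resting posture.
    """
    u1, u2 = _template_unit_deltas(action)
    if action == "socks":
        phases = [
            Phase(HOLD, 2.0),
            Phase(MOVE, 1.2, u1),
            Phase(HOLD, 2.0),
            Phase(MOVE, 1.2, u2),
            Phase(HOLD, 2.0),
            Phase(MOVE, 1.2, _scaled(u2, -1.0)),
            Phase(HOLD, 2.0),
            Phase(MOVE, 1.2, _scaled(u1, -1.0)),
            Phase(HOLD, 2.0),
        ]
    elif action == "shoes":
        phases = [
            Phase(HOLD, 2.0),
            Phase(MOVE, 1.2, u1),
            Phase(HOLD, 2.0),
            Phase(MOVE, 1.2, u2),
            Phase(HOLD, 2.0),
            Phase(MOVE, 1.2, _scaled(u2, -1.0)),
            Phase(HOLD, 2.0),
            Phase(MOVE, 1.2, _scaled(u1, -1.0)),
            Phase(HOLD, 2.0),
        ]
    elif action == "laces":
        phases = [
            Phase(HOLD, 1.6),
            Phase(MOVE, 1.2, u1),
            Phase(HOLD, 1.6),
            Phase(MOVE, 1.0, u2),
            Phase(HOLD, 1.6),
            Phase(MOVE, 1.0, _scaled(u2, -1.0)),
            Phase(HOLD, 1.6),
            Phase(MOVE, 1.2, _scaled(u1, -1.0)),
            Phase(HOLD, 1.6),
            Phase(MOVE, 1.0, _scaled(u1, 0.5)),
            Phase(HOLD, 1.6),
        ]
    else:
        raise ValueError(f"no canonical script for action {action!r}")
    return ActionScript(action=action, phases=tuple(phases))


def grasp_script() -> ActionScript:
    """A single reach-and-grasp: hold, one move, hold."""
    deltas = {
        "upper_arm": (0.1, 0.5, -1.0),
        "lower_arm": (0.5, -0.5, 0.3),
        "hand": (-0.3, 0.5, -1.0),
    }
    return ActionScript(
        action="grasp",
        phases=(Phase(HOLD, 1.2), Phase(MOVE, 1.2, deltas), Phase(HOLD, 1.2)),
    )


def generate_action_trace(
    script: ActionScript,
    noise: NoiseSpec | None = None,
    rate_hz: float = DEFAULT_RATE_HZ,
    excursion_deg: float = DEFAULT_EXCURSION_DEG,
    onset_jerk_deg: float = DEFAULT_ONSET_JERK_DEG,
    static_thresh: float = DEFAULT_STATIC_THRESH_DEG,
    move_thresh: float = DEFAULT_MOVE_THRESH_DEG,
) -> tuple[Trace, GroundTruth]:
    """Generate one labeled trace from a script.

    Raises :class:`GenerationError`, naming the offending phase, if a move
    cannot exceed the movement threshold or a hold violates the static
    rule.
    """
    noise = noise if noise is not None else NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    dt = 1.0 / rate_hz

    angle_blocks: list[np.ndarray] = []  # (n_ph, 9) each
    vel_blocks: list[np.ndarray] = []
    phase_bounds: list[tuple[int, int, str]] = []
    states_blocks: list[np.ndarray] = []
    unit_deltas: list[np.ndarray] = []
    e_blocks: list[np.ndarray] = []

    current = np.zeros(9)  # resting posture: all angles at 0 deg
    cursor = 0
    prev_state = 0

    for pi, phase in enumerate(script.phases):
        n_ph = max(2, round(phase.duration_s * rate_hz))
        if phase.kind == HOLD:
            jitter = np.zeros((n_ph, 9))
            if noise.hold_jitter_deg > 0:
                raw = rng.normal(0.0, noise.hold_jitter_deg, size=(n_ph, 9))
                clip = 2.8 * noise.hold_jitter_deg
                jitter = np.clip(raw, -clip, clip)
            angles = current[None, :] + jitter
            max_diff = float(np.max(np.abs(np.diff(angles, axis=0))))
            if max_diff >= static_thresh:
                raise GenerationError(
                    f"phase {pi} (hold): jitter produced an adjacent angle "
                    f"change of {max_diff:.3f} deg, >= the static threshold "
                    f"{static_thresh} deg"
                )
            vel = np.zeros((n_ph, 9))
            e_phase = np.zeros(n_ph)
            states = np.full(n_ph, 0, dtype=int)
        else:
            if n_ph < _MIN_MOVE_SAMPLES:
                raise GenerationError(
                    f"phase {pi} (move): {n_ph} samples is too short; "
                    f"needs at least {_MIN_MOVE_SAMPLES}"
                )
            delta = phase.delta_vector()
            if noise.move_overshoot > 0:
                delta = delta * (1.0 + rng.normal(0.0, noise.move_overshoot, 9))
            u = np.arange(n_ph) / (n_ph - 1)
            s = _smoothstep(u)
            d_eff = (n_ph - 1) * dt
            sdot = _smoothstep_deriv(u) / d_eff  # d s / d t

            angles = current[None, :] + delta[None, :] * s[:, None]
            vel = delta[None, :] * sdot[:, None]

            # closed circular excursion of the hand roll/pitch pair; it is
            # delayed until the onset jerk swing has finished, so the hand
            # has zero excursion displacement at the detected segment start
            u0 = (len(_JERK_PROFILE) - 1) / (n_ph - 1)
            v = np.clip((u - u0) / (1.0 - u0), 0.0, 1.0)
            theta = 2.0 * math.pi * _smoothstep(v)
            v_dot = np.where((u > u0) & (u < 1.0), 1.0 / ((1.0 - u0) * d_eff), 0.0)
            theta_dot = 2.0 * math.pi * _smoothstep_deriv(v) * v_dot
            i_roll = PARTS.index("hand") * 3 + 0
            i_pitch = PARTS.index("hand") * 3 + 1
            i_yaw = PARTS.index("hand") * 3 + 2
            angles[:, i_roll] += excursion_deg * (np.cos(theta) - 1.0)
            angles[:, i_pitch] += excursion_deg * np.sin(theta)
            vel[:, i_roll] += -excursion_deg * np.sin(theta) * theta_dot
            vel[:, i_pitch] += excursion_deg * np.cos(theta) * theta_dot

            # analytic hand E before the onset jerk is applied to the angles
            hand_vel = vel[:, 3 * PARTS.index("hand") : 3 * PARTS.index("hand") + 3]
            e_phase = np.sqrt(np.sum(hand_vel**2, axis=1))

            # antisymmetric onset jerk swing on the yaw angle only
            for k, frac in enumerate(_JERK_PROFILE):
                angles[k, i_yaw] += onset_jerk_deg * frac

            max_diff = float(np.max(np.abs(np.diff(angles, axis=0))))
            if max_diff <= move_thresh:
                raise GenerationError(
                    f"phase {pi} (move): peak adjacent angle change "
                    f"{max_diff:.3f} deg never exceeds the movement "
                    f"threshold {move_thresh} deg; raise excursion_deg or "
                    "onset_jerk_deg, or shorten the phase"
                )

            states = np.empty(n_ph, dtype=int)
            e_prev = 0.0  # preceding hold is at rest
            state = prev_state
            for k in range(n_ph):
                d = e_phase[k] - e_prev
                if d > 1e-12:
                    state = 1
                elif d < -1e-12:
                    state = -1
                states[k] = state
                e_prev = e_phase[k]

            unit_deltas.append(delta)
            current = current + delta

        angle_blocks.append(angles)
        vel_blocks.append(vel)
        e_blocks.append(e_phase)
        states_blocks.append(states)
        phase_bounds.append((cursor, cursor + n_ph - 1, phase.kind))
        cursor += n_ph
        prev_state = int(states[-1])

    angles = np.vstack(angle_blocks)
    vel = np.vstack(vel_blocks)
    if noise.velocity_noise > 0:
        vel = vel + rng.normal(0.0, noise.velocity_noise, size=vel.shape)

    n = angles.shape[0]
    t = np.arange(n) * dt
    channels: dict[str, np.ndarray] = {}
    for i, part in enumerate(PARTS):
        for j, axis in enumerate(ANGLE_AXES):
            channels[channel_name(part, axis)] = angles[:, 3 * i + j]
        for j, axis in enumerate(GYRO_AXES):
            channels[channel_name(part, axis)] = vel[:, 3 * i + j]
    trace = Trace.from_arrays(t, channels, rate_hz=rate_hz)

    phase_of_sample = np.empty(n, dtype=int)
    segment_labels = np.empty(n, dtype=object)
    for pi, (start, end, kind) in enumerate(phase_bounds):
        phase_of_sample[start : end + 1] = pi
        segment_labels[start : end + 1] = (
            SegmentLabel.STATIC.value if kind == HOLD else SegmentLabel.MOVEMENT.value
        )

    truth = GroundTruth(
        phase_of_sample=phase_of_sample,
        segment_labels=segment_labels,
        states=np.concatenate(states_blocks),
        unit_deltas=unit_deltas,
        phase_bounds=phase_bounds,
        e_analytic=np.concatenate(e_blocks),
        seed=noise.seed,
    )
    return trace, truth


def generate_state_dataset(
    n: int,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rate_hz: float = DEFAULT_RATE_HZ,
    part: str = "hand",
    length: int = 10,
) -> pd.DataFrame:
    """A labeled feature table for state-model training.

    Windows are drawn from a pool of generated single-grasp traces
    (hold, reach, hold); each row holds the 4 window features computed from
    the *noisy* measured E plus the ground-truth state at the window's last
    sample.  Only windows lying fully inside one ground-truth state run are
    used -- a window straddling a state transition has no well-defined
    label.  Rows are sampled per class so the three states are balanced to
    within one row.

    Columns: ``var, diff, emax, emin, state``.
    """
    if n < 30:
        raise ValueError("need n >= 30 rows")
    noise = noise if noise is not None else NoiseSpec()
    rng = np.random.default_rng(seed)

    base = n // 3
    quotas = {0: n - 2 * base, 1: base, -1: base}
    pools: dict[int, list[np.ndarray]] = {0: [], 1: [], -1: []}

    script = grasp_script()
    attempts = 0
    while any(len(pools[c]) < q for c, q in quotas.items()):
        attempts += 1
        if attempts > 1000:  # pragma: no cover - defensive
            raise GenerationError("could not fill the state-class quotas")
        trace_seed = int(rng.integers(0, 2**31 - 1))
        trace, truth = generate_action_trace(
            script, replace(noise, seed=trace_seed), rate_hz=rate_hz
        )
        for w in slide_windows(trace, length=length, stride=1, part=part):
            run = truth.states[w.start : w.end + 1]
            if np.any(run != run[-1]):
                continue  # straddles a state transition; label ill-defined
            label = int(run[-1])
            if len(pools[label]) < 4 * quotas[label]:
                pools[label].append(state_features(w.e_values))

    rows = []
    labels = []
    for label, quota in quotas.items():
        pool = pools[label]
        take = rng.choice(len(pool), size=quota, replace=False)
        rows.extend(pool[i] for i in take)
        labels.extend([label] * quota)
    order = rng.permutation(len(rows))
    X = np.stack(rows)[order]
    y = np.asarray(labels, dtype=int)[order]
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    df["state"] = y
    return df


def perturb_template(
    template: ReferenceTemplate | np.ndarray,
    sigma_noise: float,
    seed: int,
) -> np.ndarray:
    """Element-wise Gaussian perturbation of a reference vector (seeded)."""
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be non-negative")
    values = template.values if isinstance(template, ReferenceTemplate) else template
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    return values + rng.normal(0.0, sigma_noise, size=values.shape)
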