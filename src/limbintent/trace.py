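"""Container and CSV I/O for three-part wearable IMU recordings.

A :class:`Trace` holds time-synchronized Euler angles (degrees) and gyro
rates (degrees/s) for the three instrumented segments of the upper limb --
upper arm, lower arm and hand -- sampled at a constant rate (50 Hz by
default, i.e. one record every 20 ms).

Internally a trace is a wide :class:`pandas.DataFrame`: a ``t`` column plus
one column per (part, channel) pair named ``"<part>.<channel>"``.  The
on-disk interchange format is the long CSV ``t,part,roll,pitch,yaw,wx,wy,wz``
with one row per (timestamp, part).  All angles are degrees and all angular
velocities degrees/s; no unit conversion is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Body parts, in the fixed order used for every 9- and 18-element vector.
PARTS: tuple[str, ...] = ("upper_arm", "lower_arm", "hand")

#: Euler-angle axes, fixed order.
ANGLE_AXES: tuple[str, ...] = ("roll", "pitch", "yaw")

#: Gyroscope axes, fixed order.
GYRO_AXES: tuple[str, ...] = ("wx", "wy", "wz")

#: Columns of the long (on-disk) CSV schema.
CSV_COLUMNS: tuple[str, ...] = ("t", "part") + ANGLE_AXES + GYRO_AXES

DEFAULT_RATE_HZ = 50.0


def channel_name(part: str, axis: str) -> str:
    """Wide-format column name for one sensor channel, e.g. ``"hand.yaw"``."""
    return f"{part}.{axis}"


#: The 9 angle channels in fixed (part, axis) order.
ANGLE_CHANNELS: tuple[str, ...] = tuple(
    channel_name(p, a) for p in PARTS for a in ANGLE_AXES
)

#: The 9 gyro channels in fixed (part, axis) order.
GYRO_CHANNELS: tuple[str, ...] = tuple(
    channel_name(p, a) for p in PARTS for a in GYRO_AXES
)

ALL_CHANNELS: tuple[str, ...] = ANGLE_CHANNELS + GYRO_CHANNELS


@dataclass
class Trace:
    """Time-synchronized six-channel samples for all three body parts.

    Parameters
    ----------
    data
        Wide DataFrame with a ``t`` column (seconds) and the 18 channel
        columns of :data:`ALL_CHANNELS`, one row per timestamp.
    rate_hz
        Sampling rate; timestamps must advance by ``1 / rate_hz``.
    """

    data: pd.DataFrame
    rate_hz: float = DEFAULT_RATE_HZ

    def __post_init__(self) -> None:
        missing = [c for c in ("t",) + ALL_CHANNELS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"trace is missing columns: {missing}")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        vals = self.data[list(("t",) + ALL_CHANNELS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("trace contains non-finite values")
        t = self.t
        if t.size and t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        if t.size > 1:
            dt = np.diff(t)
            step = 1.0 / self.rate_hz
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, step, rtol=1e-6, atol=1e-9):
                raise ValueError(
                    f"timestamps must advance by 1/rate_hz = {step:g} s"
                )
        self.data = self.data.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(dtype=float)

    @property
    def duration_s(self) -> float:
        t = self.t
        return float(t[-1] - t[0]) if t.size else 0.0

    def angle_matrix(self) -> np.ndarray:
        """All 9 Euler-angle channels as an ``(n, 9)`` array in fixed order."""
        return self.data[list(ANGLE_CHANNELS)].to_numpy(dtype=float)

    def angles(self, part: str) -> np.ndarray:
        """Euler angles of one part as an ``(n, 3)`` array (roll, pitch, yaw)."""
        _check_part(part)
        cols = [channel_name(part, a) for a in ANGLE_AXES]
        return self.data[cols].to_numpy(dtype=float)

    def gyro(self, part: str) -> np.ndarray:
        """Angular rates of one part as an ``(n, 3)`` array (wx, wy, wz)."""
        _check_part(part)
        cols = [channel_name(part, a) for a in GYRO_AXES]
        return self.data[cols].to_numpy(dtype=float)

    # -- construction / interchange ---------------------------------------

    @classmethod
    def from_arrays(
        cls,
        t: np.ndarray,
        channels: dict[str, np.ndarray],
        rate_hz: float = DEFAULT_RATE_HZ,
    ) -> "Trace":
        """Build a trace from a timestamp vector and per-channel arrays.

        ``channels`` maps wide column names (``"<part>.<axis>"``) to 1-D
        arrays of the same length as ``t``.
        """
        df = pd.DataFrame({"t": np.asarray(t, dtype=float)})
        for name in ALL_CHANNELS:
            if name not in channels:
                raise SchemaError(f"missing channel {name!r}")
            df[name] = np.asarray(channels[name], dtype=float)
        return cls(df, rate_hz=rate_hz)

    def to_long(self) -> pd.DataFrame:
        """Long-format frame matching the CSV schema (one row per t, part)."""
        frames = []
        for part in PARTS:
            block = pd.DataFrame({"t": self.t, "part": part})
            for axis in ANGLE_AXES + GYRO_AXES:
                block[axis] = self.data[channel_name(part, axis)].to_numpy()
            frames.append(block)
        long = pd.concat(frames, ignore_index=True)
        return long.sort_values(["t", "part"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame, rate_hz: float | None = None) -> "Trace":
        """Build a trace from the long schema, validating completeness."""
        missing = [c for c in CSV_COLUMNS if c not in long.columns]
        if missing:
            raise SchemaError(f"trace CSV is missing columns: {missing}")
        bad_parts = sorted(set(long["part"]) - set(PARTS))
        if bad_parts:
            raise SchemaError(f"unknown body parts in trace CSV: {bad_parts}")
        t_values = np.unique(long["t"].to_numpy(dtype=float))
        if rate_hz is None:
            if t_values.size < 2:
                rate_hz = DEFAULT_RATE_HZ
            else:
                rate_hz = 1.0 / float(np.median(np.diff(t_values)))
        channels: dict[str, np.ndarray] = {}
        for part in PARTS:
            block = long[long["part"] == part].sort_values("t", kind="stable")
            if len(block) != t_values.size:
                raise SchemaError(
                    f"part {part!r} does not cover every timestamp "
                    f"({len(block)} rows vs {t_values.size} timestamps)"
                )
            for axis in ANGLE_AXES + GYRO_AXES:
                channels[channel_name(part, axis)] = block[axis].to_numpy(dtype=float)
        return cls.from_arrays(t_values, channels, rate_hz=rate_hz)


def _check_part(part: str) -> None:
    if part not in PARTS:
        raise ValueError(f"unknown body part {part!r}; expected one of {PARTS}")


def read_trace_csv(path, rate_hz: float | None = None) -> Trace:
    """Read a long-format trace CSV (``t,part,roll,pitch,yaw,wx,wy,wz``)."""
    long = pd.read_csv(path)
    return Trace.from_long(long, rate_hz=rate_hz)


def write_trace_csv(trace: Trace, path) -> None:
    """Write a trace in the long CSV schema, 9 significant digits."""
    trace.to_long().to_csv(path, index=False, float_format="%.9g")
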