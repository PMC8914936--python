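"""Filtering, sliding windows, and the time-domain feature formulas.

The motion analysis works on the *composite angular velocity* of a body
part,

.. math:: E_i = \\sqrt{\\omega_{x,i}^2 + \\omega_{y,i}^2 + \\omega_{z,i}^2},

and summarizes a window of ``N`` consecutive values with its sample
variance ``VAR`` (``N-1`` denominator), the successive differences
``SKE_i = E_{i+1} - E_i`` (positive runs mean acceleration, negative runs
deceleration), and the max-minus-min range ``MN``.

Windows are FIFO slices of length 10 by default; a window's result is
attached to the timestamp of its *last* sample, so with stride 1 each new
sample yields one new result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .trace import ALL_CHANNELS, ANGLE_CHANNELS, Trace

DEFAULT_WINDOW_LENGTH = 10
DEFAULT_FILTER_WIDTH = 5


def moving_average_filter(series: Iterable[float], width: int = DEFAULT_FILTER_WIDTH) -> np.ndarray:
    """Centered moving-average filter with edge truncation.

    Element ``i`` of the output is the mean of the raw values inside the
    centered window of ``width`` samples, keeping only the values that fall
    within the series at the edges (so the first and last elements average
    over fewer points).  ``width`` must be odd; width 1 is the identity.
    """
    x = np.asarray(list(series) if not isinstance(series, np.ndarray) else series,
                   dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if width < 1 or width % 2 == 0:
        raise ValueError(f"filter width must be a positive odd integer, got {width}")
    if width == 1:
        return x.copy()
    return (
        pd.Series(x).rolling(window=width, center=True, min_periods=1).mean().to_numpy()
    )


def composite_angular_velocity(wx, wy, wz):
    """Root-sum-of-squares of the three gyro components (degrees/s).

    Accepts scalars or equally shaped arrays; the result is always >= 0.
    """
    wx = np.asarray(wx, dtype=float)
    wy = np.asarray(wy, dtype=float)
    wz = np.asarray(wz, dtype=float)
    if not (np.all(np.isfinite(wx)) and np.all(np.isfinite(wy)) and np.all(np.isfinite(wz))):
        raise ValueError("angular velocities must be finite")
    e = np.sqrt(wx * wx + wy * wy + wz * wz)
    return float(e) if e.ndim == 0 else e


def window_variance(e_values: Iterable[float]) -> float:
    """Sample variance of the window's E values (``N-1`` denominator)."""
    e = np.asarray(e_values, dtype=float)
    if e.size < 2:
        raise ValueError("variance needs at least 2 values")
    return float(np.var(e, ddof=1))


def window_differences(e_values: Iterable[float]) -> np.ndarray:
    """The ``N-1`` successive differences ``E[i+1] - E[i]``."""
    e = np.asarray(e_values, dtype=float)
    if e.size < 2:
        raise ValueError("differences need at least 2 values")
    return np.diff(e)


def window_range(e_values: Iterable[float]) -> float:
    """Max-minus-min range of the window's E values."""
    e = np.asarray(e_values, dtype=float)
    if e.size == 0:
        raise ValueError("range needs a non-empty sequence")
    return float(np.max(e) - np.min(e))


@dataclass(frozen=True)
class FeatureSet:
    """Window summary: variance, successive differences, range and extrema."""

    var: float
    ske: np.ndarray
    mn: float
    e_max: float
    e_min: float

    @classmethod
    def from_e_values(cls, e_values: Iterable[float]) -> "FeatureSet":
        e = np.asarray(e_values, dtype=float)
        return cls(
            var=window_variance(e),
            ske=window_differences(e),
            mn=window_range(e),
            e_max=float(np.max(e)),
            e_min=float(np.min(e)),
        )


def filter_trace(
    trace: Trace,
    width: int = DEFAULT_FILTER_WIDTH,
    include_velocities: bool = True,
) -> Trace:
    """Return a new trace with every channel moving-average filtered.

    Angle channels are always filtered; gyro channels are filtered too
    unless ``include_velocities`` is False.
    """
    if width == 1:
        return Trace(trace.data.copy(), rate_hz=trace.rate_hz)
    cols = ALL_CHANNELS if include_velocities else ANGLE_CHANNELS
    data = trace.data.copy()
    for col in cols:
        data[col] = moving_average_filter(data[col].to_numpy(), width)
    return Trace(data, rate_hz=trace.rate_hz)


@dataclass(frozen=True)
class Window:
    """A FIFO slice of a trace with the composite E series of one part.

    ``start``/``end`` are inclusive 0-based sample indices; the window's
    result timestamp is ``t_end`` (the last sample's time).
    """

    trace: Trace
    start: int
    end: int
    part: str
    e_values: np.ndarray

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("a window needs at least 2 samples")
        if self.e_values.shape != (self.length,):
            raise ValueError("e_values must have exactly one entry per sample")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def e_mean(self) -> float:
        return float(np.mean(self.e_values))

    @property
    def t_end(self) -> float:
        return float(self.trace.t[self.end])

    def angle_slice(self) -> np.ndarray:
        """The window's 9 angle channels as an ``(N, 9)`` array."""
        return self.trace.angle_matrix()[self.start : self.end + 1]

    def features(self) -> FeatureSet:
        return FeatureSet.from_e_values(self.e_values)


def part_e_series(trace: Trace, part: str) -> np.ndarray:
    """Composite angular velocity of one part for every sample of a trace."""
    w = trace.gyro(part)
    return composite_angular_velocity(w[:, 0], w[:, 1], w[:, 2])


def slide_windows(
    trace: Trace,
    length: int = DEFAULT_WINDOW_LENGTH,
    stride: int = 1,
    part: str = "hand",
) -> list[Window]:
    """Contiguous FIFO windows over a trace.

    With stride 1 consecutive windows overlap by ``length - 1`` samples
    (one sample discarded, one added per step).  Each window's result
    belongs to its last sample.
    """
    if length < 2:
        raise ValueError("window length must be >= 2")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = trace.n_samples
    if n < length:
        raise ValueError(f"trace has {n} samples, need at least {length}")
    e_full = part_e_series(trace, part)
    windows = []
    for start in range(0, n - length + 1, stride):
        end = start + length - 1
        windows.append(
            Window(trace=trace, start=start, end=end, part=part,
                   e_values=e_full[start : end + 1])
        )
    return windows
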