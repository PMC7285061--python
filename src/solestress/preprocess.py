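"""Filtering, windowing and task trimming.

The pipeline's unit of analysis is the 10 s non-overlapping window: at the
nominal 50 Hz foot-device rate a full window holds 500 samples. Pressure
channels are smoothed with a trailing 1 s moving average before any
summation; accelerometer channels are used raw (their spectral features
need the unsmoothed signal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SensorStream

__all__ = [
    "Window",
    "SegmentTooShortError",
    "moving_average",
    "segment_windows",
    "trim_task",
]

#: minimum fraction of the nominal sample count a window must contain
MIN_WINDOW_FILL = 0.9


class SegmentTooShortError(ValueError):
    """A task segment too short to survive start/end trimming."""


@dataclass(frozen=True)
class Window:
    """A half-open time interval [start_s, end_s) with its sample slice."""

    start_s: float
    end_s: float
    i0: int
    i1: int

    @property
    def n_samples(self) -> int:
        return self.i1 - self.i0

    def samples(self, stream: SensorStream) -> np.ndarray:
        return stream.values[self.i0 : self.i1]


def moving_average(stream: SensorStream, span_s: float = 1.0) -> SensorStream:
    """Trailing (causal) moving average per channel.

    Each output sample is the mean of the trailing ``span_s`` of input
    samples; at the stream start the average runs over the shorter
    available prefix. Sample count and timestamps are unchanged.
    """
    if span_s <= 0:
        raise ValueError("span_s must be positive")
    n = max(1, round(span_s * stream.rate_hz))
    smoothed = (
        pd.DataFrame(stream.values).rolling(n, min_periods=1).mean().to_numpy()
    )
    return SensorStream(stream.t.copy(), smoothed, stream.rate_hz, stream.role)


def segment_windows(
    stream: SensorStream,
    length_s: float = 10.0,
    min_fill: float = MIN_WINDOW_FILL,
) -> list[Window]:
    """Consecutive non-overlapping windows anchored at the stream start.

    The trailing partial window is dropped, as is any window holding
    fewer than ``min_fill`` of its nominal ``length_s * rate_hz`` samples.
    """
    if length_s <= 0:
        raise ValueError("length_s must be positive")
    n_win = math.floor(stream.duration_s / length_s + 1e-9)
    t0 = stream.t[0]
    min_count = min_fill * length_s * stream.rate_hz
    out: list[Window] = []
    for k in range(n_win):
        ws = t0 + k * length_s
        we = t0 + (k + 1) * length_s
        i0, i1 = np.searchsorted(stream.t, [ws, we])
        if i1 - i0 >= min_count:
            out.append(Window(float(ws), float(we), int(i0), int(i1)))
    return out


def trim_task(
    segment: tuple[float, float], trim_s: float = 60.0
) -> tuple[float, float]:
    """Drop the first and last ``trim_s`` seconds of a task segment.

    The head of a task is contaminated by accustomisation and the tail by
    exhaustion, so both margins are excluded before training. Segments not
    strictly longer than ``2 * trim_s`` have nothing left and are rejected.
    """
    start_s, end_s = segment
    if end_s - start_s <= 2 * trim_s:
        raise SegmentTooShortError(
            f"segment [{start_s}, {end_s}] shorter than 2 x {trim_s}s trim"
        )
    return (start_s + trim_s, end_s - trim_s)
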