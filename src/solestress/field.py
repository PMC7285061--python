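"""Field-mode pipeline: posture segmentation, sitting-gated stress ratios.

In the field the stress model only applies while the wearer sits, so
wrist accelerometry (32 Hz) is segmented into 5 s windows and classified
by Acceleration Vector Change (AVC):

    AVC = sum_i | ||v_{i+1}|| - ||v_i|| | / T      [m s^-3]

with v the 3-axis acceleration vector in m s^-2 and T the window length.
Thresholds: walking AVC >= 2, standing AVC < 0.1, sitting 0.1 <= AVC < 0.2.
The band 0.2 <= AVC < 2 falls in none of the printed classes and maps to
an explicit ``unknown`` label that never enters the sitting mask.

Foot-device 10 s windows fully inside the sitting mask are classified by
the trained stress model, and each hour summarises as the stress ratio

    R_S = n_sitting_windows(stressed) / n_sitting_windows(total)

which is then correlated (Pearson) against the hourly self-reported
stress level (SRSL, 1-7 Likert).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import SpectralConfig, window_features
from .io import InsoleLayout, SensorStream
from .modeling import TrainedModel, predict
from .preprocess import moving_average, segment_windows

__all__ = [
    "PostureThresholds",
    "PostureWindow",
    "FieldHour",
    "FieldCorrelation",
    "GRAVITY_MS2",
    "avc",
    "classify_posture",
    "posture_windows",
    "sitting_mask",
    "gate_windows",
    "stress_ratio",
    "analyze_field_day",
    "correlate_field",
    "eda_window_stats",
]

logger = logging.getLogger(__name__)

GRAVITY_MS2 = 9.80665  # accel streams carry g; AVC is defined on m s^-2


@dataclass(frozen=True)
class PostureThresholds:
    """AVC decision bands in m s^-3."""

    walking_min: float = 2.0
    standing_max: float = 0.1
    sitting_max: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.standing_max < self.sitting_max < self.walking_min:
            raise ValueError("thresholds must satisfy standing < sitting < walking")


@dataclass(frozen=True)
class PostureWindow:
    start_s: float
    end_s: float
    avc: float
    label: str  # walking | standing | sitting | unknown


@dataclass
class FieldHour:
    hour: int
    n_sitting_windows: int
    n_stressed_windows: int
    stress_ratio: float  # nan when undefined
    srsl: float | None = None
    partial: bool = False

    @property
    def defined(self) -> bool:
        return self.n_sitting_windows > 0


@dataclass
class FieldCorrelation:
    r: float
    p: float
    n_hours: int
    flagged: bool = False
    reason: str = ""


def avc(samples: np.ndarray, duration_s: float) -> float:
    """Acceleration Vector Change of a window (input in g, output m s^-3)."""
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 2:
        raise ValueError("AVC needs at least 2 samples")
    mag = np.linalg.norm(samples, axis=1) * GRAVITY_MS2
    return float(np.abs(np.diff(mag)).sum() / duration_s)


def classify_posture(value: float, thresholds: PostureThresholds = PostureThresholds()) -> str:
    if value >= thresholds.walking_min:
        return "walking"
    if value < thresholds.standing_max:
        return "standing"
    if value < thresholds.sitting_max:
        return "sitting"
    return "unknown"  # the printed bands leave [sitting_max, walking_min) unassigned


def posture_windows(
    wrist: SensorStream,
    window_s: float = 5.0,
    thresholds: PostureThresholds = PostureThresholds(),
) -> list[PostureWindow]:
    out = []
    for win in segment_windows(wrist, window_s):
        value = avc(win.samples(wrist), window_s)
        out.append(
            PostureWindow(win.start_s, win.end_s, value, classify_posture(value, thresholds))
        )
    return out


def sitting_mask(
    wrist: SensorStream,
    window_s: float = 5.0,
    thresholds: PostureThresholds = PostureThresholds(),
) -> list[tuple[float, float]]:
    """Maximal intervals of consecutive sitting-labelled 5 s windows."""
    intervals: list[tuple[float, float]] = []
    for pw in posture_windows(wrist, window_s, thresholds):
        if pw.label != "sitting":
            continue
        if intervals and abs(intervals[-1][1] - pw.start_s) < 1e-9:
            intervals[-1] = (intervals[-1][0], pw.end_s)
        else:
            intervals.append((pw.start_s, pw.end_s))
    return intervals


def gate_windows(windows, mask, full_containment: bool = True):
    """Foot windows admitted by the sitting mask.

    A window counts as sitting iff its interval is fully inside one mask
    interval (conservative default); ``full_containment=False`` relaxes
    this to any overlap.
    """
    kept = []
    for w in windows:
        for s, e in mask:
            if full_containment:
                if s - 1e-9 <= w.start_s and w.end_s <= e + 1e-9:
                    kept.append(w)
                    break
            elif w.start_s < e and s < w.end_s:
                kept.append(w)
                break
    return kept


def stress_ratio(n_stressed: int, n_total: int) -> float:
    """R_S; nan (undefined) when the hour has no sitting windows."""
    if n_total == 0:
        logger.warning("hour with zero sitting windows: R_S undefined")
        return float("nan")
    if not 0 <= n_stressed <= n_total:
        raise ValueError("stressed count must lie in [0, total]")
    return n_stressed / n_total


def analyze_field_day(
    pressure: SensorStream,
    ankle: SensorStream,
    wrist: SensorStream,
    model: TrainedModel,
    layout: InsoleLayout,
    srsl: list[float] | None = None,
    hour_s: float = 3600.0,
    window_s: float = 10.0,
    posture_window_s: float = 5.0,
    thresholds: PostureThresholds = PostureThresholds(),
    ma_span_s: float = 1.0,
    rear_weight: float = 3.0,
    spectral: SpectralConfig = SpectralConfig(),
) -> tuple[list[FieldHour], pd.DataFrame]:
    """Hourly stress ratios of one field day.

    Returns the FieldHour list plus the per-window classification frame.
    Hours are anchored at the foot-stream start; a trailing partial hour
    is reported but flagged.
    """
    mask = sitting_mask(wrist, posture_window_s, thresholds)
    filtered = moving_average(pressure, ma_span_s)
    foot_windows = segment_windows(filtered, window_s)
    sitting_windows = gate_windows(foot_windows, mask)
    if not sitting_windows:
        logger.warning("no foot windows inside the sitting mask")
    rows = []
    for win in sitting_windows:
        a0, a1 = np.searchsorted(ankle.t, [win.start_s, win.end_s])
        if a1 - a0 < 0.9 * window_s * ankle.rate_hz:
            continue
        feats = window_features(
            win.samples(filtered),
            ankle.values[a0:a1],
            layout,
            ankle.rate_hz,
            rear_weight=rear_weight,
            spectral=spectral,
        )
        rows.append({"window_start_s": win.start_s, **feats})
    windows_df = pd.DataFrame(rows)
    t0 = pressure.t[0]
    if len(windows_df):
        labels, scores = predict(model, windows_df)
        windows_df["predicted"] = labels
        windows_df["score"] = scores
        windows_df["hour"] = ((windows_df["window_start_s"] - t0) // hour_s).astype(int)
    n_hours = int(np.ceil(pressure.duration_s / hour_s - 1e-9))
    hours: list[FieldHour] = []
    for h in range(n_hours):
        if len(windows_df):
            sub = windows_df[windows_df["hour"] == h]
            n_total = len(sub)
            n_stressed = int((sub["predicted"] == "stress").sum()) if n_total else 0
        else:
            n_total = n_stressed = 0
        partial = (h + 1) * hour_s > pressure.duration_s + 1e-6
        hours.append(
            FieldHour(
                hour=h,
                n_sitting_windows=n_total,
                n_stressed_windows=n_stressed,
                stress_ratio=stress_ratio(n_stressed, n_total),
                srsl=srsl[h] if srsl is not None and h < len(srsl) else None,
                partial=partial,
            )
        )
    return hours, windows_df


def correlate_field(hours: list[FieldHour]) -> FieldCorrelation:
    """Pearson correlation between hourly SRSL and R_S."""
    pairs = [
        (h.srsl, h.stress_ratio)
        for h in hours
        if h.defined and h.srsl is not None and np.isfinite(h.stress_ratio)
    ]
    n = len(pairs)
    if n < 3:
        return FieldCorrelation(np.nan, np.nan, n, True, "fewer than 3 valid hours")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return FieldCorrelation(np.nan, np.nan, n, True, "zero variance in SRSL or R_S")
    r, p = stats.pearsonr(x, y)
    return FieldCorrelation(float(r), float(p), n)


def eda_window_stats(eda: SensorStream, window_s: float = 10.0) -> pd.DataFrame:
    """Per-window mean and least-squares slope of an EDA stream.

    A lab-validation utility: electrodermal activity rises under arousal,
    so a positive mean slope over a task corroborates the stress label.
    """
    rows = []
    for win in segment_windows(eda, window_s, min_fill=0.0):
        if win.n_samples < 2:
            logger.warning("EDA window at %.1fs skipped: <2 samples", win.start_s)
            continue
        t = eda.t[win.i0 : win.i1] - win.start_s
        v = eda.values[win.i0 : win.i1, 0]
        slope, intercept = np.polyfit(t, v, 1)
        rows.append(
            {
                "window_start_s": win.start_s,
                "mean": float(v.mean()),
                "slope_per_s": float(slope),
            }
        )
    return pd.DataFrame(rows, columns=["window_start_s", "mean", "slope_per_s"])
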