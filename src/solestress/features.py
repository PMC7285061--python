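"""The ten per-window stress features.

Four behavioural signatures of seated acute stress drive the feature set:

* **A — foot pressure.** Stress shifts load onto the forefoot. A1/A2/A3 are
  the window means of the summed forefoot (sensors 1-12), rearfoot
  (13-16) and total pressure.
* **B — centre of pressure.** A weighted planar average of sensor
  coordinates, with rearfoot sensors up-weighted by a factor
  ``rear_weight`` (default 3):

      XCoP = (sum_ff P_i x_i + w * sum_rf P_i x_i) / (P_F + w * P_R)

  B1 is XCoP (medio-lateral), B2 YCoP (anterior-posterior).
* **C — leg posture.** Per-axis window means of the ankle accelerometer
  (units g). Gravity is deliberately not removed: its projection onto the
  axes encodes the knee/leg angle.
* **D — foot tapping.** Spectral features of V3D, the axis-inverted 3D
  norm. Inverting one axis (a_inv = 2*max(a) - a) before taking the norm
  prevents low-amplitude oscillations riding on a large gravity offset
  from cancelling; of the three one-axis-inverted norms the one with the
  largest peak-to-peak is kept. D1 is the median (half-cumulative-power)
  frequency and D2 the dominant (peak-power) frequency of its
  periodogram, searched above ``min_freq_hz``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .io import (
    FEATURE_COLUMNS,
    InsoleLayout,
    SensorStream,
    SessionMeta,
)
from .preprocess import (
    SegmentTooShortError,
    Window,
    moving_average,
    segment_windows,
    trim_task,
)

__all__ = [
    "SpectralConfig",
    "CopUndefinedError",
    "forefoot_pressure",
    "rearfoot_pressure",
    "total_pressure",
    "centre_of_pressure",
    "accel_means",
    "invert_axis",
    "select_v3d",
    "spectral_features",
    "window_features",
    "extract_features",
]

logger = logging.getLogger(__name__)


class CopUndefinedError(ValueError):
    """Centre of pressure undefined (zero total weighted pressure)."""


@dataclass(frozen=True)
class SpectralConfig:
    """Spectral estimation settings for the tapping features.

    The series mean is removed and a rectangular window used; the peak and
    half-power searches run over bins at or above ``min_freq_hz``
    (default 0.5 Hz) so that postural drift near DC cannot masquerade as
    a tapping frequency.
    """

    min_freq_hz: float = 0.5

    def validate(self, rate_hz: float) -> None:
        if not 0 <= self.min_freq_hz < rate_hz / 2:
            raise ValueError("min_freq_hz must lie in [0, nyquist)")


# ---------------------------------------------------------------------------
# A: pressure sums


def forefoot_pressure(samples: np.ndarray, layout: InsoleLayout) -> float:
    """A1: window mean of the summed 12 forefoot channels."""
    return float(samples[:, layout.forefoot].sum(axis=1).mean())


def rearfoot_pressure(samples: np.ndarray, layout: InsoleLayout) -> float:
    """A2: window mean of the summed 4 rearfoot channels."""
    return float(samples[:, layout.rearfoot].sum(axis=1).mean())


def total_pressure(samples: np.ndarray, layout: InsoleLayout) -> float:
    """A3: window mean of the summed 16 channels (= A1 + A2)."""
    return forefoot_pressure(samples, layout) + rearfoot_pressure(samples, layout)


# ---------------------------------------------------------------------------
# B: centre of pressure


def centre_of_pressure(
    samples: np.ndarray,
    layout: InsoleLayout,
    rear_weight: float = 3.0,
    per_sample: bool = False,
) -> tuple[float, float]:
    """(B1, B2) = (XCoP, YCoP) of a pressure window.

    By default the CoP is computed from the window-mean channel values;
    ``per_sample=True`` instead computes a CoP per sample and averages
    those (the two orders differ for time-varying load).
    """
    w = np.ones(samples.shape[1])
    w[layout.rearfoot] = rear_weight

    def _cop(p: np.ndarray) -> tuple[float, float]:
        wp = w * p
        denom = wp.sum()
        if denom <= 0:
            raise CopUndefinedError("zero total weighted pressure in window")
        return float((wp * layout.x).sum() / denom), float((wp * layout.y).sum() / denom)

    if per_sample:
        cops = np.array([_cop(row) for row in samples])
        return float(cops[:, 0].mean()), float(cops[:, 1].mean())
    return _cop(samples.mean(axis=0))


# ---------------------------------------------------------------------------
# C: posture means


def accel_means(samples: np.ndarray) -> tuple[float, float, float]:
    """(C1, C2, C3): per-axis arithmetic means of a raw accel window."""
    m = samples.mean(axis=0)
    return float(m[0]), float(m[1]), float(m[2])


# ---------------------------------------------------------------------------
# D: tapping spectrum


def invert_axis(samples: np.ndarray) -> np.ndarray:
    """Axis inversion a_inv = 2*max(a) - a (max over the window)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot invert an empty series")
    return 2.0 * samples.max() - samples


def select_v3d(samples: np.ndarray) -> np.ndarray:
    """The inverted-axis 3D norm with maximal peak-to-peak amplitude.

    One candidate norm per axis: that axis inverted, the other two
    unmodified. Ties break in axis order X, Y, Z.
    """
    best = None
    best_ptp = -np.inf
    for axis in range(3):
        comp = samples.astype(float).copy()
        comp[:, axis] = invert_axis(comp[:, axis])
        norm = np.sqrt((comp**2).sum(axis=1))
        ptp = norm.max() - norm.min()
        if ptp > best_ptp:
            best, best_ptp = norm, ptp
    return best


def spectral_features(
    v3d: np.ndarray,
    rate_hz: float,
    cfg: SpectralConfig = SpectralConfig(),
) -> tuple[float, float, bool]:
    """(D1, D2, flagged): median and dominant frequency of a V3D series.

    Mean-removed rectangular-window periodogram. D2 is the frequency of
    the maximum-power bin at or above ``min_freq_hz`` (power ties break
    toward the lower frequency); D1 is the smallest such frequency at
    which the cumulative power reaches half the total power above the
    floor. A window with no spectral content (constant after detrending)
    returns (0, 0, flagged=True) by convention.
    """
    cfg.validate(rate_hz)
    v3d = np.asarray(v3d, dtype=float)
    if len(v3d) < 2 * rate_hz:
        raise ValueError("spectral features need at least 2 s of samples")
    freqs, psd = periodogram(v3d, fs=rate_hz, window="boxcar", detrend="constant")
    mask = freqs >= cfg.min_freq_hz
    f, p = freqs[mask], psd[mask]
    total = p.sum()
    if total <= 0 or not np.isfinite(total):
        return 0.0, 0.0, True
    dominant = float(f[int(np.argmax(p))])
    csum = np.cumsum(p)
    median = float(f[int(np.searchsorted(csum, total / 2.0))])
    return median, dominant, False


# ---------------------------------------------------------------------------
# composite extraction


def window_features(
    pressure_samples: np.ndarray,
    accel_samples: np.ndarray,
    layout: InsoleLayout,
    rate_hz: float,
    rear_weight: float = 3.0,
    spectral: SpectralConfig = SpectralConfig(),
    cop_per_sample: bool = False,
) -> dict[str, float]:
    """All ten features of one aligned (pressure, accel) window pair."""
    a1 = forefoot_pressure(pressure_samples, layout)
    a2 = rearfoot_pressure(pressure_samples, layout)
    b1, b2 = centre_of_pressure(
        pressure_samples, layout, rear_weight=rear_weight, per_sample=cop_per_sample
    )
    c1, c2, c3 = accel_means(accel_samples)
    d1, d2, flagged = spectral_features(select_v3d(accel_samples), rate_hz, spectral)
    if flagged:
        logger.warning("degenerate (constant) V3D window; D1 = D2 = 0")
    return {
        "A1": a1, "A2": a2, "A3": a1 + a2,
        "B1": b1, "B2": b2,
        "C1": c1, "C2": c2, "C3": c3,
        "D1": d1, "D2": d2,
    }


def _covers(stream: SensorStream, start_s: float, end_s: float) -> bool:
    tol = 1.0 / stream.rate_hz
    return stream.t[0] <= start_s + tol and stream.t[-1] + tol >= end_s


def extract_features(
    pressure: SensorStream,
    ankle: SensorStream,
    meta: SessionMeta,
    layout: InsoleLayout,
    mode: str = "training",
    window_s: float = 10.0,
    trim_s: float = 60.0,
    ma_span_s: float = 1.0,
    rear_weight: float = 3.0,
    spectral: SpectralConfig = SpectralConfig(),
    cop_per_sample: bool = False,
) -> pd.DataFrame:
    """One feature row per emitted 10 s window of every usable segment.

    In ``training`` mode only stress/relax segments are used and each is
    trimmed by ``trim_s`` at both ends; segments too short to trim are
    excluded. In ``inference`` mode all segments are used untrimmed.
    Windows whose CoP is undefined or whose accel coverage falls below
    the completeness threshold are dropped with a logged reason.
    """
    if mode not in ("training", "inference"):
        raise ValueError(f"mode must be 'training' or 'inference', got {mode!r}")
    filtered = moving_average(pressure, ma_span_s)
    rows: list[dict] = []
    for seg in meta.segments:
        if mode == "training":
            if seg.condition not in ("stress", "relax"):
                logger.info("segment %s: unlabelled, skipped in training mode", seg.task_id)
                continue
            try:
                start_s, end_s = trim_task((seg.start_s, seg.end_s), trim_s)
            except SegmentTooShortError as exc:
                logger.warning("segment %s excluded: %s", seg.task_id, exc)
                continue
        else:
            start_s, end_s = seg.start_s, seg.end_s
        if not (_covers(filtered, start_s, end_s) and _covers(ankle, start_s, end_s)):
            logger.warning("segment %s skipped: stream coverage missing", seg.task_id)
            continue
        p_sub = filtered.slice_time(start_s, end_s)
        for win in segment_windows(p_sub, window_s):
            a0, a1_idx = np.searchsorted(ankle.t, [win.start_s, win.end_s])
            if a1_idx - a0 < 0.9 * window_s * ankle.rate_hz:
                logger.warning(
                    "window at %.1fs dropped: accel coverage below threshold",
                    win.start_s,
                )
                continue
            try:
                feats = window_features(
                    win.samples(p_sub),
                    ankle.values[a0:a1_idx],
                    layout,
                    ankle.rate_hz,
                    rear_weight=rear_weight,
                    spectral=spectral,
                    cop_per_sample=cop_per_sample,
                )
            except CopUndefinedError as exc:
                logger.warning("window at %.1fs dropped: %s", win.start_s, exc)
                continue
            rows.append(
                {
                    "participant_id": meta.participant_id,
                    "task_id": seg.task_id,
                    "window_start_s": win.start_s,
                    "label": seg.condition,
                    **feats,
                }
            )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
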