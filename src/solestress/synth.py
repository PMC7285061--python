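"""Synthetic session and field-day generator with planted ground truth.

Because no public recording of seated-stress insole/ankle data exists,
this module *is* the study-conditions bench: it emits streams that pass
every validator and carry the four behavioural stress signatures —

1. forefoot loading (multiplicative forefoot pressure gain),
2. anterior centre-of-pressure shift,
3. leg-posture change (rotation of the mean gravity projection),
4. intermittent foot tapping (a 3-5 Hz low-amplitude oscillation on one
   ankle axis, present in a fraction of stressed windows),

each individually switchable, plus per-user heterogeneity (baseline load,
load split, resting leg angle, tapping propensity) so that
leave-one-user-out validation is a meaningful generalisation test.

Effect magnitudes are generator design choices tuned for clear
separability; they are NOT measurements from any participant study.
All randomness flows from a single integer seed through numpy's
``default_rng`` (PCG64), so outputs are bit-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import extract_features
from .field import PostureThresholds, GRAVITY_MS2
from .io import InsoleLayout, Segment, SensorStream, SessionMeta, default_layout
from .modeling import GroundTruthRule, label_windows

__all__ = [
    "StressProfile",
    "SyntheticTruth",
    "default_task_plan",
    "generate_session",
    "generate_field_day",
    "generate_eda",
    "build_lab_dataset",
]


@dataclass(frozen=True)
class StressProfile:
    """Planted stress-signature magnitudes.

    forefoot_gain: multiplicative forefoot pressure factor under stress.
    cop_shift_mm: anterior CoP displacement target (capped at the
        geometrically attainable maximum of the layout; the realized
        value is recorded in the truth record).
    posture_delta_g: reduction of the mean Z-axis gravity projection
        under stress (the leg pulls back under the chair).
    tap_freq_hz / tap_amp_g / tap_prob: tapping frequency, amplitude and
        the fraction of stressed windows containing a tapping burst.
    pressure_noise_sd / accel_noise_sd: white-noise SDs per channel
        (raw pressure units and g).
    """

    forefoot_gain: float = 1.5
    cop_shift_mm: float = 15.0
    posture_delta_g: float = 0.3
    tap_freq_hz: float = 4.0
    tap_amp_g: float = 0.05
    tap_prob: float = 0.7
    pressure_noise_sd: float = 0.5
    accel_noise_sd: float = 0.003

    def __post_init__(self) -> None:
        if self.forefoot_gain <= 0:
            raise ValueError("forefoot_gain must be > 0")
        if not 0 <= self.tap_prob <= 1:
            raise ValueError("tap_prob must lie in [0, 1]")
        if self.tap_freq_hz <= 0 or self.tap_amp_g < 0:
            raise ValueError("tapping parameters must be non-negative")
        if self.pressure_noise_sd < 0 or self.accel_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @classmethod
    def null(cls, **overrides) -> "StressProfile":
        """All signatures off: stress and relax windows are exchangeable.

        Keyword overrides re-enable individual signatures for ablations.
        """
        base = cls(
            forefoot_gain=1.0, cop_shift_mm=0.0, posture_delta_g=0.0, tap_prob=0.0
        )
        return replace(base, **overrides) if overrides else base

    def scaled(self, s: float) -> "StressProfile":
        """Interpolate every effect between null (s=0) and this profile (s=1)."""
        return replace(
            self,
            forefoot_gain=1.0 + (self.forefoot_gain - 1.0) * s,
            cop_shift_mm=self.cop_shift_mm * s,
            posture_delta_g=self.posture_delta_g * s,
            tap_prob=self.tap_prob * s,
        )


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping aligned one-to-one with emitted windows."""

    windows: pd.DataFrame  # participant_id, task_id, window_start_s, condition, tapping
    posture: pd.DataFrame | None = None  # start_s, label (5 s wrist windows)
    hourly: pd.DataFrame | None = None  # hour, intensity, srsl
    sitting_fraction: float | None = None
    realized_cop_shift_mm: float | None = None

    def to_dict(self) -> dict:
        doc: dict = {"windows": self.windows.to_dict(orient="records")}
        if self.posture is not None:
            doc["posture"] = self.posture.to_dict(orient="records")
        if self.hourly is not None:
            doc["hourly"] = self.hourly.to_dict(orient="records")
        if self.sitting_fraction is not None:
            doc["sitting_fraction"] = float(self.sitting_fraction)
        if self.realized_cop_shift_mm is not None:
            doc["realized_cop_shift_mm"] = float(self.realized_cop_shift_mm)
        return doc


def default_task_plan(n_tasks: int = 10, task_s: float = 320.0) -> list[tuple[float, str]]:
    """Alternating stress/relax tasks, stress first.

    The default 320 s length leaves 200 s (20 windows) per task after the
    60 s head/tail trim, i.e. 200 labelled windows per participant.
    """
    return [(task_s, "stress" if i % 2 == 0 else "relax") for i in range(n_tasks)]


def _cop_y(p: np.ndarray, layout: InsoleLayout, rear_weight: float) -> float:
    w = np.ones(len(p))
    w[layout.rearfoot] = rear_weight
    return float((w * p * layout.y).sum() / (w * p).sum())


def _apply_cop_shift(
    p: np.ndarray, layout: InsoleLayout, shift_mm: float, rear_weight: float = 3.0
) -> tuple[np.ndarray, float]:
    """Shift CoP anteriorly by moving pressure to each region's front row.

    The transfer preserves the forefoot and rearfoot sums exactly, so the
    forefoot-gain signature stays uncontaminated. CoP_y is linear in the
    transferred fraction, so the fraction realising ``shift_mm`` is exact;
    an unattainable target is capped at the full-transfer maximum.
    """
    if shift_mm <= 0:
        return p.copy(), 0.0
    p_full = p.copy()
    for region in (layout.forefoot, layout.rearfoot):
        y = layout.y[region]
        front = y == y.max()
        q = p[region].copy()
        moved = q[~front].sum()
        q[~front] = 0.0
        q[front] += moved / front.sum()
        p_full[region] = q
    max_shift = _cop_y(p_full, layout, rear_weight) - _cop_y(p, layout, rear_weight)
    if max_shift <= 0:
        return p.copy(), 0.0
    beta = min(1.0, shift_mm / max_shift)
    return (1 - beta) * p + beta * p_full, beta * max_shift


def _user_params(rng: np.random.Generator, profile: StressProfile) -> dict:
    ax0 = rng.normal(0.15, 0.03)
    ay0 = rng.normal(0.15, 0.03)
    return {
        "base_total": max(50.0, rng.normal(200.0, 15.0)),
        "ff_frac": rng.uniform(0.55, 0.65),
        "accel_rest": np.array([ax0, ay0, math.sqrt(max(1 - ax0**2 - ay0**2, 0.25))]),
        "tap_freq": float(np.clip(rng.normal(profile.tap_freq_hz, 0.3),
                                  max(1.0, profile.tap_freq_hz - 1.0),
                                  profile.tap_freq_hz + 1.0)),
        # power jitter: per-user propensity varies but 0 and 1 stay exact,
        # so switching the tapping signature fully off/on is deterministic
        "tap_prob": float(profile.tap_prob ** rng.uniform(0.7, 1.4)),
    }


def _baselines(
    user: dict, profile: StressProfile, layout: InsoleLayout
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """(p_relax, p_stress, a_relax, a_stress, realized_cop_shift)."""
    p_relax = np.concatenate(
        [
            np.full(12, user["base_total"] * user["ff_frac"] / 12.0),
            np.full(4, user["base_total"] * (1 - user["ff_frac"]) / 4.0),
        ]
    )
    p_stress = p_relax.copy()
    p_stress[layout.forefoot] *= profile.forefoot_gain
    p_stress, realized = _apply_cop_shift(p_stress, layout, profile.cop_shift_mm)
    a_relax = user["accel_rest"].copy()
    a_stress = a_relax.copy()
    a_stress[2] -= profile.posture_delta_g
    a_stress[0] += 0.5 * profile.posture_delta_g
    return p_relax, p_stress, a_relax, a_stress, realized


def generate_session(
    seed: int,
    profile: StressProfile | None = None,
    task_plan: list[tuple[float, str]] | None = None,
    participant_id: str = "P01",
    rate_hz: float = 50.0,
    layout: InsoleLayout | None = None,
    window_s: float = 10.0,
) -> tuple[SensorStream, SensorStream, SessionMeta, SyntheticTruth]:
    """One seated lab session: insole + ankle streams, metadata, truth.

    Stress segments carry the profile's pressure/posture signatures for
    their full duration; tapping bursts are drawn per 10 s window with
    probability ``tap_prob``. Self-reports are consistent with the task
    condition (stress tasks rated 5-7, relaxation 1-3) so the labelling
    rule retains every task.
    """
    profile = profile or StressProfile()
    layout = layout or default_layout()
    task_plan = task_plan or default_task_plan()
    if profile.tap_freq_hz >= rate_hz / 2:
        raise ValueError("tap_freq_hz must be below the Nyquist frequency")
    rng = np.random.default_rng(seed)
    user = _user_params(rng, profile)
    p_relax, p_stress, a_relax, a_stress, realized = _baselines(user, profile, layout)

    total_s = sum(d for d, _ in task_plan)
    n = round(total_s * rate_hz)
    t = np.arange(n) / rate_hz
    pressure = np.empty((n, 16))
    accel = np.empty((n, 3))
    segments: list[Segment] = []
    ratings: dict[str, dict[str, float]] = {}
    truth_rows = []
    cursor = 0.0
    for i, (dur, cond) in enumerate(task_plan):
        task_id = f"T{i + 1:02d}"
        segments.append(Segment(task_id, cursor, cursor + dur, cond))
        if cond == "stress":
            rating = int(rng.integers(5, 8))
        elif cond == "relax":
            rating = int(rng.integers(1, 4))
        else:
            rating = 4
        ratings[task_id] = {"stress": rating, "energy": int(rng.integers(1, 8))}
        i0, i1 = round(cursor * rate_hz), round((cursor + dur) * rate_hz)
        stressed = cond == "stress"
        pressure[i0:i1] = p_stress if stressed else p_relax
        accel[i0:i1] = a_stress if stressed else a_relax
        for k in range(math.floor(dur / window_s + 1e-9)):
            ws = cursor + k * window_s
            tapping = stressed and rng.random() < user["tap_prob"]
            if tapping:
                j0, j1 = round(ws * rate_hz), round((ws + window_s) * rate_hz)
                phase = rng.uniform(0, 2 * np.pi)
                accel[j0:j1, 0] += profile.tap_amp_g * np.sin(
                    2 * np.pi * user["tap_freq"] * t[j0:j1] + phase
                )
            truth_rows.append(
                {
                    "participant_id": participant_id,
                    "task_id": task_id,
                    "window_start_s": ws,
                    "condition": cond,
                    "tapping": tapping,
                }
            )
        cursor += dur
    pressure += rng.normal(0, profile.pressure_noise_sd, pressure.shape)
    np.clip(pressure, 0, None, out=pressure)
    accel += rng.normal(0, profile.accel_noise_sd, accel.shape)

    insole = SensorStream(t, pressure, rate_hz, "insole_pressure")
    ankle = SensorStream(t.copy(), accel, rate_hz, "ankle_accel")
    meta = SessionMeta(participant_id, segments, ratings)
    truth = SyntheticTruth(
        windows=pd.DataFrame(truth_rows),
        realized_cop_shift_mm=realized,
    )
    return insole, ankle, meta, truth


def generate_eda(
    seed: int,
    task_plan: list[tuple[float, str]] | None = None,
    rate_hz: float = 4.0,
    base_us: float = 2.0,
    stress_slope: float = 0.01,
    relax_slope: float = -0.005,
    noise_sd: float = 0.02,
) -> SensorStream:
    """A 4 Hz EDA stream rising during stress tasks, decaying during relax.

    Trend-sign realism only: no skin-conductance response shapes or
    artefacts are modelled.
    """
    task_plan = task_plan or default_task_plan()
    rng = np.random.default_rng(seed)
    total_s = sum(d for d, _ in task_plan)
    n = round(total_s * rate_hz)
    t = np.arange(n) / rate_hz
    slope = np.zeros(n)
    cursor = 0.0
    for dur, cond in task_plan:
        i0, i1 = round(cursor * rate_hz), round((cursor + dur) * rate_hz)
        slope[i0:i1] = stress_slope if cond == "stress" else relax_slope
        cursor += dur
    level = base_us + np.cumsum(slope) / rate_hz
    level = np.maximum(level, 0.05) + rng.normal(0, noise_sd, n)
    return SensorStream(t, level[:, None], rate_hz, "eda")


def _bout_schedule(
    rng: np.random.Generator, total_s: float, sitting_fraction: float
) -> list[tuple[float, float, str]]:
    """Alternating (start, duration, label) bouts in 10 s multiples."""
    bouts: list[tuple[float, float, str]] = []
    cursor = 0.0
    while cursor < total_s - 1e-9:
        d_sit = 10.0 * rng.integers(12, 49)  # 2-8 min seated bouts
        d_sit = min(d_sit, total_s - cursor)
        bouts.append((cursor, d_sit, "sitting"))
        cursor += d_sit
        if cursor >= total_s - 1e-9 or sitting_fraction >= 1.0:
            continue
        d_non = d_sit * (1 - sitting_fraction) / sitting_fraction
        d_non = 10.0 * max(1, round(d_non * rng.uniform(0.85, 1.15) / 10.0))
        d_non = min(d_non, total_s - cursor)
        if d_non > 0:
            label = "walking" if rng.random() < 0.5 else "standing"
            bouts.append((cursor, d_non, label))
            cursor += d_non
    return bouts


def generate_field_day(
    seed: int,
    hourly_intensities: list[float] | None = None,
    sitting_fraction: float = 0.795,
    profile: StressProfile | None = None,
    hour_s: float = 3600.0,
    rate_foot: float = 50.0,
    rate_wrist: float = 32.0,
    layout: InsoleLayout | None = None,
    window_s: float = 10.0,
    posture_window_s: float = 5.0,
    srsl_jitter: int = 1,
    thresholds: PostureThresholds = PostureThresholds(),
) -> tuple[SensorStream, SensorStream, SensorStream, list[int], SyntheticTruth]:
    """One office field day (default 8 h) with hourly stress intensities.

    Returns (insole, ankle, wrist, srsl, truth). Posture alternates
    seated bouts with standing/walking bouts sized to hit
    ``sitting_fraction``; within seated time each 10 s foot window is
    stressed with probability equal to its hour's intensity. The hourly
    self-report is ``1 + round(6 * intensity)`` plus an integer jitter of
    at most ``srsl_jitter`` Likert steps, clipped to [1, 7].

    Wrist windows carry planted AVC values drawn inside the printed
    posture bands (sitting 0.11-0.19, standing 0.01-0.08, walking
    2.2-4.0 m s^-3) as a square-wave modulation of the acceleration
    magnitude; broadband noise is deliberately omitted from the wrist
    channel because the sitting band is only 0.1 m s^-3 wide.
    """
    profile = profile or StressProfile()
    layout = layout or default_layout()
    if hourly_intensities is None:
        hourly_intensities = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
    if any(not 0 <= v <= 1 for v in hourly_intensities):
        raise ValueError("hourly intensities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_hours = len(hourly_intensities)
    total_s = n_hours * hour_s

    bouts = _bout_schedule(rng, total_s, sitting_fraction)
    sitting_s = sum(d for _, d, lab in bouts if lab == "sitting")

    # wrist stream: per-5s planted AVC inside the correct band
    n_w = round(total_s * rate_wrist)
    t_w = np.arange(n_w) / rate_wrist
    mag = np.ones(n_w)
    posture_rows = []
    avc_bands = {"sitting": (0.11, 0.19), "standing": (0.01, 0.08), "walking": (2.2, 4.0)}
    parity = np.where(np.arange(n_w) % 2 == 0, 0.5, -0.5)
    for start, dur, lab in bouts:
        for ws in np.arange(start, start + dur - 1e-9, posture_window_s):
            lo, hi = avc_bands[lab]
            target = rng.uniform(lo, hi)
            j0, j1 = round(ws * rate_wrist), round((ws + posture_window_s) * rate_wrist)
            steps = max(1, j1 - j0 - 1)
            delta = target * posture_window_s / (steps * GRAVITY_MS2)
            mag[j0:j1] = 1.0 + parity[j0:j1] * delta
            posture_rows.append({"start_s": float(ws), "label": lab})
    wrist_values = np.zeros((n_w, 3))
    wrist_values[:, 2] = mag
    wrist = SensorStream(t_w, wrist_values, rate_wrist, "wrist_accel")

    # foot streams
    user = _user_params(rng, profile)
    p_relax, p_stress, a_relax, a_stress, realized = _baselines(user, profile, layout)
    n_f = round(total_s * rate_foot)
    t_f = np.arange(n_f) / rate_foot
    pressure = np.tile(p_relax, (n_f, 1))
    accel = np.tile(a_relax, (n_f, 1))

    def bout_of(ws: float, we: float) -> str | None:
        for start, dur, lab in bouts:
            if start - 1e-9 <= ws and we <= start + dur + 1e-9:
                return lab
        return None

    truth_rows = []
    for ws in np.arange(0.0, total_s - 1e-9, window_s):
        we = ws + window_s
        lab = bout_of(ws, we)
        sitting = lab == "sitting"
        hour = int(ws // hour_s)
        stressed = bool(sitting and rng.random() < hourly_intensities[hour])
        tapping = bool(stressed and rng.random() < user["tap_prob"])
        j0, j1 = round(ws * rate_foot), round(we * rate_foot)
        if stressed:
            pressure[j0:j1] = p_stress
            accel[j0:j1] = a_stress
            if tapping:
                phase = rng.uniform(0, 2 * np.pi)
                accel[j0:j1, 0] += profile.tap_amp_g * np.sin(
                    2 * np.pi * user["tap_freq"] * t_f[j0:j1] + phase
                )
        elif lab == "walking":
            accel[j0:j1, 0] += 0.2 * np.sin(2 * np.pi * 1.5 * t_f[j0:j1])
            pressure[j0:j1] *= 0.5
        truth_rows.append(
            {
                "window_start_s": float(ws),
                "sitting": sitting,
                "hour": hour,
                "condition": "stress" if stressed else "relax",
                "tapping": tapping,
            }
        )
    pressure += rng.normal(0, profile.pressure_noise_sd, pressure.shape)
    np.clip(pressure, 0, None, out=pressure)
    accel += rng.normal(0, profile.accel_noise_sd, accel.shape)
    insole = SensorStream(t_f, pressure, rate_foot, "insole_pressure")
    ankle = SensorStream(t_f.copy(), accel, rate_foot, "ankle_accel")

    srsl = []
    hourly_rows = []
    for h, intensity in enumerate(hourly_intensities):
        jitter = int(rng.integers(-srsl_jitter, srsl_jitter + 1)) if srsl_jitter else 0
        level = int(np.clip(1 + round(6 * intensity) + jitter, 1, 7))
        srsl.append(level)
        hourly_rows.append({"hour": h, "intensity": float(intensity), "srsl": level})

    truth = SyntheticTruth(
        windows=pd.DataFrame(truth_rows),
        posture=pd.DataFrame(posture_rows),
        hourly=pd.DataFrame(hourly_rows),
        sitting_fraction=sitting_s / total_s,
        realized_cop_shift_mm=realized,
    )
    return insole, ankle, wrist, srsl, truth


def build_lab_dataset(
    n_users: int = 5,
    seed: int = 0,
    profile: StressProfile | None = None,
    task_plan: list[tuple[float, str]] | None = None,
    layout: InsoleLayout | None = None,
    rule: GroundTruthRule = GroundTruthRule(),
) -> pd.DataFrame:
    """Generate n_users sessions, extract features, apply the labelling rule
    and return the combined labelled feature table (the LOUO input)."""
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    user_seeds = rng.integers(0, 2**31 - 1, size=n_users)
    tables = []
    for i, user_seed in enumerate(user_seeds):
        pid = f"P{i + 1:02d}"
        insole, ankle, meta, _ = generate_session(
            int(user_seed), profile=profile, task_plan=task_plan,
            participant_id=pid, layout=layout,
        )
        table = extract_features(insole, ankle, meta, layout, mode="training")
        tables.append(label_windows(table, meta, rule))
    return pd.concat(tables, ignore_index=True)
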