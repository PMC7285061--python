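"""Readers/writers for streams, layouts, session metadata and feature tables.

All artifacts are plain text (CSV / YAML / JSON) so that runs are diffable
and reproducible. Numeric round-trips are lossless to 12 significant digits.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "StreamValidationError",
    "ParseError",
    "InsoleLayout",
    "SensorStream",
    "Segment",
    "SessionMeta",
    "ROLE_CHANNELS",
    "FEATURE_NAMES",
    "FEATURE_COLUMNS",
    "read_stream",
    "write_stream",
    "read_layout",
    "default_layout",
    "read_session_meta",
    "write_session_meta",
    "read_feature_table",
    "write_feature_table",
    "validate_feature_table",
]

FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """An artifact has the wrong shape (columns, counts, ids)."""


class StreamValidationError(ValueError):
    """A stream violates a sampling or value invariant."""


class ParseError(ValueError):
    """An artifact could not be parsed at all."""


# channel count and CSV column names by stream role
ROLE_CHANNELS = {
    "insole_pressure": [f"p{i}" for i in range(1, 17)],
    "ankle_accel": ["ax", "ay", "az"],
    "wrist_accel": ["ax", "ay", "az"],
    "eda": ["eda"],
}

FEATURE_NAMES = ["A1", "A2", "A3", "B1", "B2", "C1", "C2", "C3", "D1", "D2"]
FEATURE_COLUMNS = ["participant_id", "task_id", "window_start_s", "label"] + FEATURE_NAMES

N_FOREFOOT = 12
N_REARFOOT = 4
N_SENSORS = N_FOREFOOT + N_REARFOOT


@dataclass(frozen=True)
class InsoleLayout:
    """Planar sensor coordinates of the 16-sensor insole.

    Sensors are stored in sensor-id order: ids 1..12 form the forefoot
    array, ids 13..16 the rearfoot (heel) array. Coordinates are in mm,
    x medio-lateral and y anterior-posterior (increasing toward the toes).
    """

    x: np.ndarray  # shape (16,)
    y: np.ndarray  # shape (16,)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != (N_SENSORS,) or y.shape != (N_SENSORS,):
            raise SchemaError(f"layout must have exactly {N_SENSORS} sensors")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise SchemaError("layout coordinates must be finite")
        xy = np.column_stack([x, y])
        if len(np.unique(xy, axis=0)) != N_SENSORS:
            raise SchemaError("two sensors share identical (x, y) coordinates")

    @property
    def forefoot(self) -> slice:
        return slice(0, N_FOREFOOT)

    @property
    def rearfoot(self) -> slice:
        return slice(N_FOREFOOT, N_SENSORS)


@dataclass
class SensorStream:
    """A uniformly sampled multichannel time series.

    timestamps are seconds, strictly increasing; ``values`` is a
    samples x n_channels matrix. ``rate_hz`` is the nominal rate —
    timestamps are authoritative, and streams whose median inter-sample
    gap deviates more than 10% from 1/rate_hz are rejected.
    """

    t: np.ndarray
    values: np.ndarray
    rate_hz: float
    role: str

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.role not in ROLE_CHANNELS:
            raise SchemaError(f"unknown stream role {self.role!r}")
        n_expected = len(ROLE_CHANNELS[self.role])
        if self.values.shape[1] != n_expected:
            raise SchemaError(
                f"role {self.role!r} expects {n_expected} channels, "
                f"got {self.values.shape[1]}"
            )
        if self.t.ndim != 1 or len(self.t) != len(self.values):
            raise SchemaError("timestamps and samples must have equal length")
        if len(self.t) < 2:
            raise StreamValidationError("stream needs at least 2 samples")
        gaps = np.diff(self.t)
        if not (gaps > 0).all():
            raise StreamValidationError("timestamps must be strictly increasing")
        nominal = 1.0 / self.rate_hz
        if abs(np.median(gaps) - nominal) > 0.1 * nominal:
            raise StreamValidationError(
                f"median inter-sample gap {np.median(gaps):.6g}s deviates more "
                f"than 10% from nominal {nominal:.6g}s"
            )
        if self.role == "insole_pressure" and (self.values < 0).any():
            raise StreamValidationError("pressure values must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        """Span covered by the samples, counting each sample's nominal dwell."""
        return float(self.t[-1] - self.t[0]) + 1.0 / self.rate_hz

    def slice_time(self, start_s: float, end_s: float) -> "SensorStream":
        """Sub-stream of samples with start_s <= t < end_s."""
        i0, i1 = np.searchsorted(self.t, [start_s, end_s])
        return SensorStream(self.t[i0:i1], self.values[i0:i1], self.rate_hz, self.role)


@dataclass(frozen=True)
class Segment:
    task_id: str
    start_s: float
    end_s: float
    condition: str  # stress | relax | unlabelled


@dataclass
class SessionMeta:
    participant_id: str
    segments: list[Segment]
    ratings: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for seg in self.segments:
            if seg.end_s <= seg.start_s:
                raise SchemaError(f"segment {seg.task_id}: end_s <= start_s")
            if seg.start_s < prev_end:
                raise SchemaError(f"segment {seg.task_id} overlaps its predecessor")
            if seg.condition not in ("stress", "relax", "unlabelled"):
                raise SchemaError(f"segment {seg.task_id}: bad condition {seg.condition!r}")
            prev_end = seg.end_s

    def condition_of(self, task_id: str) -> str | None:
        for seg in self.segments:
            if seg.task_id == task_id:
                return seg.condition
        return None

    def stress_rating(self, task_id: str) -> float | None:
        r = self.ratings.get(task_id)
        if r is None:
            return None
        return r.get("stress")


# ---------------------------------------------------------------------------
# streams


def read_stream(path: str | Path, role: str, rate_hz: float) -> SensorStream:
    """Read a `t,<c1>,...,<cn>` CSV into a validated SensorStream."""
    path = Path(path)
    if role not in ROLE_CHANNELS:
        raise SchemaError(f"unknown stream role {role!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed CSV: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    expected = ["t"] + ROLE_CHANNELS[role]
    if len(df.columns) != len(expected) or df.columns[0] != "t":
        raise SchemaError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    if not all(df.dtypes.apply(lambda d: np.issubdtype(d, np.number))):
        bad = [c for c, d in df.dtypes.items() if not np.issubdtype(d, np.number)]
        raise ParseError(f"{path}: non-numeric values in columns {bad}")
    try:
        return SensorStream(
            df["t"].to_numpy(float), df.iloc[:, 1:].to_numpy(float), rate_hz, role
        )
    except (SchemaError, StreamValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_stream(stream: SensorStream, path: str | Path) -> None:
    df = pd.DataFrame(stream.values, columns=ROLE_CHANNELS[stream.role])
    df.insert(0, "t", stream.t)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# layout


def _layout_from_entries(entries: Sequence[dict], source: str) -> InsoleLayout:
    if len(entries) != N_SENSORS:
        raise SchemaError(f"{source}: expected {N_SENSORS} sensors, got {len(entries)}")
    by_id: dict[int, dict] = {}
    for e in entries:
        sid = int(e["id"])
        if sid in by_id:
            raise SchemaError(f"{source}: duplicate sensor id {sid}")
        by_id[sid] = e
    if sorted(by_id) != list(range(1, N_SENSORS + 1)):
        raise SchemaError(f"{source}: sensor ids must be exactly 1..{N_SENSORS}")
    x = np.empty(N_SENSORS)
    y = np.empty(N_SENSORS)
    for sid in range(1, N_SENSORS + 1):
        e = by_id[sid]
        expected_region = "forefoot" if sid <= N_FOREFOOT else "rearfoot"
        region = e.get("region", expected_region)
        if region != expected_region:
            raise SchemaError(
                f"{source}: sensor {sid} tagged {region!r}, "
                f"ids 1..{N_FOREFOOT} are forefoot and "
                f"{N_FOREFOOT + 1}..{N_SENSORS} rearfoot"
            )
        x[sid - 1] = float(e["x"])
        y[sid - 1] = float(e["y"])
    return InsoleLayout(x, y)


def read_layout(path: str | Path) -> InsoleLayout:
    path = Path(path)
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(doc, dict) or "sensors" not in doc:
        raise SchemaError(f"{path}: layout file must contain a 'sensors' list")
    return _layout_from_entries(doc["sensors"], str(path))


def default_layout() -> InsoleLayout:
    """The bundled synthetic stand-in layout (see data/default_layout.yaml)."""
    ref = importlib.resources.files("solestress.data") / "default_layout.yaml"
    doc = yaml.safe_load(ref.read_text())
    return _layout_from_entries(doc["sensors"], "default_layout.yaml")


# ---------------------------------------------------------------------------
# session metadata


def read_session_meta(path: str | Path) -> SessionMeta:
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            doc = json.load(fh)
        else:
            doc = yaml.safe_load(fh)
    try:
        segments = [
            Segment(
                task_id=str(s["task_id"]),
                start_s=float(s["start_s"]),
                end_s=float(s["end_s"]),
                condition=str(s.get("condition", "unlabelled")),
            )
            for s in doc["segments"]
        ]
        return SessionMeta(
            participant_id=str(doc["participant_id"]),
            segments=segments,
            ratings={str(k): dict(v) for k, v in (doc.get("ratings") or {}).items()},
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed session metadata: {exc}") from exc


def write_session_meta(meta: SessionMeta, path: str | Path) -> None:
    doc = {
        "participant_id": meta.participant_id,
        "segments": [
            {
                "task_id": s.task_id,
                "start_s": float(s.start_s),
                "end_s": float(s.end_s),
                "condition": s.condition,
            }
            for s in meta.segments
        ],
        "ratings": {k: {kk: float(vv) for kk, vv in v.items()} for k, v in meta.ratings.items()},
    }
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# feature tables


def validate_feature_table(table: pd.DataFrame) -> None:
    if list(table.columns) != FEATURE_COLUMNS:
        raise SchemaError(
            f"feature table columns must be {FEATURE_COLUMNS}, got {list(table.columns)}"
        )
    if len(table) == 0:
        return
    feats = table[FEATURE_NAMES]
    if feats.isna().any().any():
        raise SchemaError("feature table contains NaNs")
    if (table[["D1", "D2"]] < 0).any().any():
        raise SchemaError("spectral features must be non-negative frequencies")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_feature_table(table)
    try:
        table.to_csv(path, index=False, float_format=FLOAT_FMT)
    except OSError as exc:
        raise OSError(f"cannot write feature table to {path}: {exc}") from exc


def read_feature_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            dtype={"participant_id": str, "task_id": str, "label": str},
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed CSV: {exc}") from exc
    if len(df) == 0 and list(df.columns) == FEATURE_COLUMNS:
        return df
    for col in ["window_start_s"] + FEATURE_NAMES:
        if col in df.columns:
            df[col] = df[col].astype(float)
    validate_feature_table(df)
    return df
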