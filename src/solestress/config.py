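"""Run configuration: every tunable constant of the pipeline in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .field import PostureThresholds

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline constants.

    window_s: analysis window (10 s; 500 samples at the 50 Hz foot rate).
    trim_s: head/tail seconds excluded from each task before training.
    ma_span_s: trailing moving-average span applied to pressure channels.
    rear_weight: rearfoot up-weighting in the CoP average.
    min_freq_hz: lower bound of the spectral peak/median search.
    posture_*: AVC thresholds (m s^-3) and the wrist posture window.
    """

    window_s: float = 10.0
    trim_s: float = 60.0
    ma_span_s: float = 1.0
    rear_weight: float = 3.0
    min_freq_hz: float = 0.5
    posture_walking_min: float = 2.0
    posture_standing_max: float = 0.1
    posture_sitting_max: float = 0.2
    posture_window_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_s", "trim_s", "ma_span_s", "posture_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # constructing the thresholds validates their ordering
        self.posture_thresholds()

    def posture_thresholds(self) -> PostureThresholds:
        return PostureThresholds(
            walking_min=self.posture_walking_min,
            standing_max=self.posture_standing_max,
            sitting_max=self.posture_sitting_max,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides win over file values."""
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)
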