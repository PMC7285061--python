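"""Ground-truth labelling, LDA stress models and leave-one-user-out validation.

The classifier is a two-class linear discriminant with pooled within-class
covariance. Features are z-scored with training-set statistics before the
fit (the ten features mix raw pressure units, millimetres, g and Hz);
priors are empirical; an exact posterior tie classifies as relax.

Validation is leave-one-user-out (LOUO): one fold per participant, trained
on everybody else. Every fold asserts train/test participant disjointness
from row provenance before fitting — a corrupted fold raises rather than
silently leaking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import FEATURE_NAMES, SessionMeta

__all__ = [
    "GroundTruthRule",
    "TrainedModel",
    "EvaluationReport",
    "SeparationResult",
    "LeakageError",
    "label_windows",
    "fit_lda",
    "predict",
    "assert_no_leakage",
    "leave_one_user_out",
    "separation_test",
    "model_grid",
    "STANDARD_SUBSETS",
]

logger = logging.getLogger(__name__)

CLASSES = ("stress", "relax")


class LeakageError(AssertionError):
    """Held-out participant's rows found in a training fold."""


@dataclass(frozen=True)
class GroundTruthRule:
    """Keep only unambiguous task blocks.

    A stress task counts as ground-truth stress only if the participant's
    own stress rating exceeds ``threshold``; a relaxation task counts only
    if the rating falls below it. A rating exactly at the threshold is
    ambiguous and always excluded.
    """

    threshold: float = 4.0

    def keeps(self, condition: str, rating: float) -> bool:
        if condition == "stress":
            return rating > self.threshold
        if condition == "relax":
            return rating < self.threshold
        return False


def label_windows(
    table: pd.DataFrame,
    meta: SessionMeta | dict[str, SessionMeta],
    rule: GroundTruthRule = GroundTruthRule(),
) -> pd.DataFrame:
    """Drop windows from ambiguous or unrated (participant, task) blocks.

    ``meta`` is one SessionMeta or a dict keyed by participant_id for
    multi-participant tables.
    """
    metas = meta if isinstance(meta, dict) else {meta.participant_id: meta}
    keep = np.zeros(len(table), dtype=bool)
    for (pid, task), idx in table.groupby(["participant_id", "task_id"]).groups.items():
        m = metas.get(pid)
        if m is None:
            logger.warning("participant %s: no session metadata, excluded", pid)
            continue
        condition = m.condition_of(task)
        rating = m.stress_rating(task)
        if condition is None or condition == "unlabelled":
            continue
        if rating is None:
            logger.warning("task %s/%s: missing stress rating, excluded", pid, task)
            continue
        keep[table.index.get_indexer(idx)] = rule.keeps(condition, rating)
    out = table[keep].reset_index(drop=True)
    bad = set(out["label"]) - set(CLASSES)
    if bad:
        raise ValueError(f"labelled table contains non-binary labels {bad}")
    return out


@dataclass
class TrainedModel:
    """A fitted two-class LDA over a named feature subset, JSON-serialisable."""

    feature_subset: list[str]
    classes: tuple[str, str]
    class_means: np.ndarray  # (2, k) in standardised space
    covariance: np.ndarray  # (k, k) pooled within-class
    priors: np.ndarray  # (2,)
    scaler_mean: np.ndarray  # (k,)
    scaler_scale: np.ndarray  # (k,)
    ridge_applied: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "feature_subset": list(self.feature_subset),
            "classes": list(self.classes),
            "class_means": self.class_means.tolist(),
            "covariance": self.covariance.tolist(),
            "priors": self.priors.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "ridge_applied": bool(self.ridge_applied),
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedModel":
        p = Path(source)
        doc = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            feature_subset=list(doc["feature_subset"]),
            classes=tuple(doc["classes"]),
            class_means=np.array(doc["class_means"], dtype=float),
            covariance=np.array(doc["covariance"], dtype=float),
            priors=np.array(doc["priors"], dtype=float),
            scaler_mean=np.array(doc["scaler_mean"], dtype=float),
            scaler_scale=np.array(doc["scaler_scale"], dtype=float),
            ridge_applied=bool(doc.get("ridge_applied", False)),
        )


def _validate_subset(feature_subset: list[str]) -> list[str]:
    subset = list(feature_subset)
    if len(subset) != len(set(subset)):
        raise ValueError(f"duplicate features in subset {subset}")
    unknown = set(subset) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")
    return subset


def fit_lda(
    table: pd.DataFrame,
    feature_subset: list[str],
    standardize: bool = True,
    ridge: float = 1e-6,
) -> TrainedModel:
    """Fit pooled-covariance LDA on the labelled rows of a feature table."""
    subset = _validate_subset(feature_subset)
    X = table[subset].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    k = X.shape[1]
    counts = np.array([(y == c).sum() for c in CLASSES])
    if (counts < 2).any():
        raise ValueError(f"need >= 2 rows per class, got {dict(zip(CLASSES, counts))}")
    if standardize:
        mu = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mu = np.zeros(k)
        scale = np.ones(k)
    Xz = (X - mu) / scale
    means = np.vstack([Xz[y == c].mean(axis=0) for c in CLASSES])
    scatter = np.zeros((k, k))
    for i, c in enumerate(CLASSES):
        d = Xz[y == c] - means[i]
        scatter += d.T @ d
    cov = scatter / (len(y) - 2)
    ridge_applied = False
    try:
        np.linalg.cholesky(cov)
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
    except np.linalg.LinAlgError:
        lam = ridge * np.trace(cov) / k if np.trace(cov) > 0 else ridge
        cov = cov + lam * np.eye(k)
        ridge_applied = True
        logger.warning("singular pooled covariance; ridge %.3g applied", lam)
    return TrainedModel(
        feature_subset=subset,
        classes=CLASSES,
        class_means=means,
        covariance=cov,
        priors=counts / counts.sum(),
        scaler_mean=mu,
        scaler_scale=scale,
        ridge_applied=ridge_applied,
    )


def predict(
    model: TrainedModel, rows: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, scores) for each row; score > 0 means stress.

    The score is the stress-minus-relax linear discriminant difference
    (log posterior-odds up to a constant); an exact tie predicts relax.
    """
    missing = [f for f in model.feature_subset if f not in rows.columns]
    if missing:
        raise ValueError(f"rows are missing model features {missing}")
    X = rows[model.feature_subset].to_numpy(dtype=float)
    Xz = (X - model.scaler_mean) / model.scaler_scale
    inv = np.linalg.inv(model.covariance)
    deltas = []
    for i in range(2):
        m = model.class_means[i]
        w = inv @ m
        deltas.append(Xz @ w - 0.5 * m @ w + np.log(model.priors[i]))
    scores = deltas[0] - deltas[1]
    labels = np.where(scores > 0, model.classes[0], model.classes[1])
    return labels, scores


def assert_no_leakage(train: pd.DataFrame, test: pd.DataFrame) -> None:
    """Raise LeakageError if any participant appears in both partitions."""
    overlap = set(train["participant_id"]) & set(test["participant_id"])
    if overlap:
        raise LeakageError(
            f"participants {sorted(overlap)} present in both train and test"
        )


@dataclass
class SeparationResult:
    """Paired t-test of per-user predicted-stress fractions by condition."""

    t: float
    p: float
    n_users: int
    flagged: bool = False
    reason: str = ""


def separation_test(predictions: pd.DataFrame) -> SeparationResult:
    """Separation sharpness between stress and relaxation tasks.

    ``predictions`` needs columns participant_id, label (true condition)
    and predicted. For each user with rows under both conditions, the
    fraction of windows predicted stressed is computed per condition and
    the paired fractions compared with a two-sided paired t-test.
    """
    pairs = []
    for pid, grp in predictions.groupby("participant_id"):
        fracs = {}
        for cond in CLASSES:
            sub = grp[grp["label"] == cond]
            if len(sub):
                fracs[cond] = float((sub["predicted"] == "stress").mean())
        if len(fracs) == 2:
            pairs.append((fracs["stress"], fracs["relax"]))
    n = len(pairs)
    if n < 3:
        return SeparationResult(np.nan, np.nan, n, True, "fewer than 3 paired users")
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    d = a - b
    if np.all(d == 0):
        return SeparationResult(0.0, 1.0, n)  # zero differences everywhere
    if np.ptp(d) == 0:
        # constant nonzero difference: zero variance, the t statistic diverges
        return SeparationResult(float(np.sign(d[0]) * np.inf), 0.0, n)
    t, p = stats.ttest_rel(a, b)
    return SeparationResult(float(t), float(p), n)


@dataclass
class EvaluationReport:
    """LOUO evaluation summary for one feature subset."""

    feature_subset: list[str]
    per_user_accuracy: dict[str, float]  # percent
    mean_accuracy: float  # percent, mean over users
    sd_accuracy: float  # percent, SD over users (ddof=1)
    accuracy_curve: list[float]  # percent, by window index within task
    separation: SeparationResult
    predictions: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "feature_subset": list(self.feature_subset),
            "per_user_accuracy": {k: float(v) for k, v in self.per_user_accuracy.items()},
            "mean_accuracy": float(self.mean_accuracy),
            "sd_accuracy": float(self.sd_accuracy),
            "accuracy_curve": [float(v) for v in self.accuracy_curve],
            "separation": {
                "t": None if np.isnan(self.separation.t) else float(self.separation.t),
                "p": None if np.isnan(self.separation.p) else float(self.separation.p),
                "n_users": self.separation.n_users,
                "flagged": self.separation.flagged,
                "reason": self.separation.reason,
            },
        }


def leave_one_user_out(
    table: pd.DataFrame,
    feature_subset: list[str],
    standardize: bool = True,
) -> EvaluationReport:
    """One fold per participant; accuracy is the % of correctly classified
    10 s windows, averaged over users; the curve indexes windows by their
    position within each task."""
    subset = _validate_subset(feature_subset)
    users = sorted(table["participant_id"].unique())
    if len(users) < 3:
        raise ValueError(f"LOUO needs >= 3 users, got {len(users)}")
    pred_frames = []
    per_user: dict[str, float] = {}
    for user in users:
        test = table[table["participant_id"] == user]
        train = table[table["participant_id"] != user]
        if len(test) == 0:
            logger.warning("user %s has zero rows; skipped", user)
            continue
        assert_no_leakage(train, test)
        model = fit_lda(train, subset, standardize=standardize)
        labels, scores = predict(model, test)
        fold = test.copy()
        fold["predicted"] = labels
        fold["score"] = scores
        fold["correct"] = fold["predicted"] == fold["label"]
        per_user[user] = 100.0 * float(fold["correct"].mean())
        pred_frames.append(fold)
    predictions = pd.concat(pred_frames, ignore_index=True)
    # window index within each (participant, task), in time order
    predictions["window_index"] = (
        predictions.sort_values("window_start_s")
        .groupby(["participant_id", "task_id"])
        .cumcount()
        .reindex(predictions.index)
    )
    curve = (
        100.0 * predictions.groupby("window_index")["correct"].mean()
    ).sort_index()
    accs = np.array(list(per_user.values()))
    return EvaluationReport(
        feature_subset=subset,
        per_user_accuracy=per_user,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        accuracy_curve=list(curve.to_numpy()),
        separation=separation_test(predictions),
        predictions=predictions,
    )


#: the model grid evaluated in validation: every single-feature model,
#: the four high performers combined, the two most meaningful, and all ten.
STANDARD_SUBSETS: dict[str, list[str]] = {
    **{name: [name] for name in FEATURE_NAMES},
    "A1+B2+C3+D1": ["A1", "B2", "C3", "D1"],
    "C3+A1": ["C3", "A1"],
    "ALL": list(FEATURE_NAMES),
}


def model_grid(
    table: pd.DataFrame,
    subsets: dict[str, list[str]] | None = None,
) -> list[tuple[str, EvaluationReport]]:
    """LOUO-evaluate each subset; returns (name, report) ranked by accuracy."""
    subsets = STANDARD_SUBSETS if subsets is None else subsets
    results = [
        (name, leave_one_user_out(table, features))
        for name, features in subsets.items()
    ]
    return sorted(results, key=lambda item: -item[1].mean_accuracy)
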