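"""Random-forest training, scoring and persistence.

The classifier sits behind a small seam: any object exposing
``fit(X, y)`` and ``score_samples`` semantics compatible with
:class:`TrainedModel` can replace the forest in the evaluation drivers
(see :func:`sixma.evaluate.kfold_cv` and friends).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

MODEL_FORMAT_VERSION = "sixma-model-1"

PathLike = Union[str, Path]


class ModelIOError(ValueError):
    """Raised when a model file cannot be loaded."""


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters; defaults follow the published setup
    (100 trees grown from seed 1, other growth controls at library
    defaults).

    ``vote="prob"`` scores a sample as the mean leaf class-probability
    across trees; ``vote="hard"`` as the fraction of trees whose
    majority leaf votes positive.
    """

    n_trees: int = 100
    seed: int = 1
    max_features: Union[str, int, float, None] = "sqrt"
    min_leaf: int = 1
    vote: str = "prob"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.vote not in ("prob", "hard"):
            raise ValueError(f"vote must be 'prob' or 'hard', got {self.vote!r}")


class ScoringClassifier(Protocol):
    """The seam the evaluation drivers rely on."""

    feature_names: tuple[str, ...]

    def scores(self, X) -> np.ndarray: ...


def _as_matrix(X, feature_names: Optional[Sequence[str]] = None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        cols = tuple(str(c) for c in X.columns)
        if feature_names is not None and cols != tuple(feature_names):
            missing = sorted(set(feature_names) - set(cols))
            extra = sorted(set(cols) - set(feature_names))
            raise ValueError(
                f"feature columns do not match the model: missing={missing}, extra={extra}"
                if missing or extra
                else "feature columns are in the wrong order"
            )
        return X.to_numpy(dtype=float), cols
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D feature matrix, got shape {arr.shape}")
    if feature_names is not None:
        if arr.shape[1] != len(feature_names):
            raise ValueError(
                f"expected {len(feature_names)} feature columns, got {arr.shape[1]}"
            )
        return arr, tuple(feature_names)
    return arr, tuple(f"f{i}" for i in range(arr.shape[1]))


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to reuse it safely."""

    config: RFConfig
    feature_names: tuple[str, ...]
    estimator: RandomForestClassifier
    metadata: dict = field(default_factory=dict)

    def scores(self, X) -> np.ndarray:
        return predict_scores(self, X)


def train(X, y, config: RFConfig = RFConfig(), metadata: Optional[dict] = None) -> TrainedModel:
    """Fit a forest of ``config.n_trees`` trees; deterministic per seed.

    ``X`` may be a DataFrame (column names are recorded and later
    enforced) or an array.  Both classes must be present and ``X`` must
    be finite.
    """
    mat, names = _as_matrix(X)
    yv = np.asarray(y).astype(int).ravel()
    if mat.shape[0] != len(yv):
        raise ValueError(f"X has {mat.shape[0]} rows but y has {len(yv)} entries")
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not np.isfinite(mat).all():
        raise ValueError("X contains NaN or infinite values")
    classes = np.unique(yv)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"y must contain both classes {{0, 1}}, got {classes.tolist()}")
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        random_state=config.seed,
        max_features=config.max_features,
        min_samples_leaf=config.min_leaf,
    )
    est.fit(mat, yv)
    meta = {
        "n_pos": int((yv == 1).sum()),
        "n_neg": int((yv == 0).sum()),
        **(metadata or {}),
    }
    return TrainedModel(config=config, feature_names=names, estimator=est, metadata=meta)


def predict_scores(model: TrainedModel, X) -> np.ndarray:
    """Per-row positive-class score in [0, 1].

    Mean tree probability by default, or hard-vote fraction when the
    model was configured with ``vote="hard"``.
    """
    mat, _ = _as_matrix(X, model.feature_names)
    if model.config.vote == "hard":
        votes = np.stack([tree.predict(mat) for tree in model.estimator.estimators_])
        return votes.mean(axis=0)
    pos_col = int(np.flatnonzero(model.estimator.classes_ == 1)[0])
    return model.estimator.predict_proba(mat)[:, pos_col]


def predict_labels(model: TrainedModel, X, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff score >= threshold; threshold must be in (0, 1)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return (predict_scores(model, X) >= threshold).astype(int)


def save_model(model: TrainedModel, path: PathLike) -> None:
    """Persist the model to a versioned container file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": model.config,
        "feature_names": model.feature_names,
        "estimator": model.estimator,
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path: PathLike) -> TrainedModel:
    """Load a model saved by :func:`save_model`; validates the container."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt / truncated file
        raise ModelIOError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelIOError(f"{path} is not a sixma model container")
    version = payload["format_version"]
    if version != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"{path}: unsupported model format {version!r} (expected {MODEL_FORMAT_VERSION!r})"
        )
    return TrainedModel(
        config=payload["config"],
        feature_names=tuple(payload["feature_names"]),
        estimator=payload["estimator"],
        metadata=dict(payload["metadata"]),
    )
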