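"""Confusion metrics, ROC/AUC and the evaluation protocols.

Metric definitions follow the four-quantity confusion parameterisation:
``n_pos``/``n_neg`` are the true class sizes, ``fn`` the positives
predicted negative, ``fp`` the negatives predicted positive, and

    Sn  = 1 - fn / n_pos
    Sp  = 1 - fp / n_neg
    Acc = 1 - (fn + fp) / (n_pos + n_neg)

MCC is the standard Matthews coefficient in [-1, 1]; a confusion table
with a zero marginal gets MCC = 0 with a warning.  All cross-validation
drivers pool the held-out scores across folds and compute ONE ROC/AUC
and one confusion table from them, so each protocol yields a single
report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from sixma.encoders import DEFAULT_K_VALUES, encode_matrix
from sixma.model import RFConfig, TrainedModel, predict_scores, train
from sixma.seqio import SampleWindow

JACKKNIFE_CAP = 2000

TrainerFn = Callable[[np.ndarray, np.ndarray], object]


@dataclass(frozen=True)
class ConfusionCounts:
    """The four confusion quantities: class sizes and cross errors."""

    n_pos: int
    n_neg: int
    fn: int  # true positives predicted negative
    fp: int  # true negatives predicted positive

    def __post_init__(self) -> None:
        if not 0 <= self.fn <= self.n_pos:
            raise ValueError(f"fn must be in [0, n_pos]: fn={self.fn}, n_pos={self.n_pos}")
        if not 0 <= self.fp <= self.n_neg:
            raise ValueError(f"fp must be in [0, n_neg]: fp={self.fp}, n_neg={self.n_neg}")

    @property
    def tp(self) -> int:
        return self.n_pos - self.fn

    @property
    def tn(self) -> int:
        return self.n_neg - self.fp


@dataclass
class MetricsReport:
    """Sn/Sp/Acc/MCC plus (optionally) the ROC points and their AUC."""

    sn: float
    sp: float
    acc: float
    mcc: float
    counts: ConfusionCounts
    auc: Optional[float] = None
    roc: Optional[np.ndarray] = None  # (n, 2) array of (FPR, TPR)
    protocol: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serialisable view of the report."""
        out = {
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
            "counts": {
                "n_pos": self.counts.n_pos,
                "n_neg": self.counts.n_neg,
                "fn": self.counts.fn,
                "fp": self.counts.fp,
            },
            "auc": self.auc,
            "protocol": self.protocol,
        }
        if self.roc is not None:
            out["roc"] = [[float(a), float(b)] for a, b in self.roc]
        return out


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count the four confusion quantities from two binary vectors."""
    yt = np.asarray(y_true).astype(int).ravel()
    yp = np.asarray(y_pred).astype(int).ravel()
    if len(yt) != len(yp):
        raise ValueError(f"length mismatch: {len(yt)} true vs {len(yp)} predicted")
    for name, v in (("y_true", yt), ("y_pred", yp)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary over {{0, 1}}")
    return ConfusionCounts(
        n_pos=int((yt == 1).sum()),
        n_neg=int((yt == 0).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
    )


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Standard Matthews coefficient; 0 (with a warning) on a zero marginal."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("confusion table has a zero marginal; reporting MCC = 0")
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_ratio_form(c: ConfusionCounts) -> float:
    """MCC written in error-rate form over the class sizes.

    Algebraically identical to :func:`mcc_from_counts` whenever both are
    defined:

        (1 - fn/n_pos - fp/n_neg)
        / sqrt((1 + (fp - fn)/n_pos) * (1 + (fn - fp)/n_neg))
    """
    if c.n_pos == 0 or c.n_neg == 0:
        raise ValueError("ratio form requires both classes non-empty")
    num = 1.0 - (c.fn / c.n_pos + c.fp / c.n_neg)
    den = (1.0 + (c.fp - c.fn) / c.n_pos) * (1.0 + (c.fn - c.fp) / c.n_neg)
    if den == 0:
        warnings.warn("degenerate confusion table in ratio-form MCC; reporting 0")
        return 0.0
    return num / math.sqrt(den)


def metrics(
    c: ConfusionCounts,
    auc: Optional[float] = None,
    roc: Optional[np.ndarray] = None,
    protocol: Optional[dict] = None,
    strict: bool = True,
) -> MetricsReport:
    """Build a report from confusion counts.

    With ``strict=True`` (default) an empty class raises; with
    ``strict=False`` the undefined rate is reported as NaN instead
    (used by the independent-test path on degenerate inputs).
    """
    if strict and (c.n_pos == 0 or c.n_neg == 0):
        raise ValueError(
            f"both classes must be non-empty: n_pos={c.n_pos}, n_neg={c.n_neg}"
        )
    sn = 1.0 - c.fn / c.n_pos if c.n_pos else float("nan")
    sp = 1.0 - c.fp / c.n_neg if c.n_neg else float("nan")
    total = c.n_pos + c.n_neg
    acc = 1.0 - (c.fn + c.fp) / total if total else float("nan")
    return MetricsReport(
        sn=sn,
        sp=sp,
        acc=acc,
        mcc=mcc_from_counts(c),
        counts=c,
        auc=auc,
        roc=roc,
        protocol=dict(protocol or {}),
    )


def roc_curve(y_true, scores) -> np.ndarray:
    """ROC points from a descending threshold sweep over unique scores.

    Returns an (n, 2) array of (FPR, TPR) starting at (0, 0) and ending
    at (1, 1); tied scores collapse to a single point, so FPR and TPR
    are non-decreasing.  Requires both classes present.
    """
    yt = np.asarray(y_true).astype(int).ravel()
    sc = np.asarray(scores, dtype=float).ravel()
    if len(yt) != len(sc):
        raise ValueError(f"length mismatch: {len(yt)} labels vs {len(sc)} scores")
    n_pos = int((yt == 1).sum())
    n_neg = int((yt == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-sc, kind="stable")
    sc_sorted = sc[order]
    yt_sorted = yt[order]
    tp_cum = np.cumsum(yt_sorted == 1)
    fp_cum = np.cumsum(yt_sorted == 0)
    # keep only the last index of each tied-score run
    last_of_run = np.r_[np.diff(sc_sorted) != 0, True]
    tpr = tp_cum[last_of_run] / n_pos
    fpr = fp_cum[last_of_run] / n_neg
    points = np.column_stack(
        (np.concatenate(([0.0], fpr, [1.0])), np.concatenate(([0.0], tpr, [1.0])))
    )
    return points


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under an ROC point list.

    Equals the Mann-Whitney statistic P(score_pos > score_neg) +
    0.5 * P(tie) computed on the same data.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError(f"need an (n >= 2, 2) ROC point array, got shape {pts.shape}")
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """Convenience: ROC points and their trapezoidal AUC."""
    pts = roc_curve(y_true, scores)
    return pts, auc(pts)


# ---------------------------------------------------------------------------
# protocol drivers


def _default_trainer(config: RFConfig) -> TrainerFn:
    return lambda X, y: train(X, y, config=config)


def _encode(windows: Sequence[SampleWindow], schemes, k_values):
    if isinstance(schemes, str):
        schemes = [s for s in schemes.replace("+", ",").split(",") if s]
    df = encode_matrix(windows, schemes, k_values=k_values, with_labels=True)
    y = df.pop("label").to_numpy(dtype=int)
    return df, y


def _score_with(clf, X) -> np.ndarray:
    if isinstance(clf, TrainedModel):
        return predict_scores(clf, X)
    return np.asarray(clf.scores(X), dtype=float)


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified partition into k folds; class ratio per fold
    preserved within one sample."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than k={k} folds"
            )
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(len(idx)) % k
    return [np.flatnonzero(fold_of == f) for f in range(k)]


def kfold_cv(
    windows: Sequence[SampleWindow],
    schemes: Union[str, Sequence[str]] = "mnbe",
    config: RFConfig = RFConfig(),
    k: int = 5,
    seed: int = 1,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    threshold: float = 0.5,
    trainer: Optional[TrainerFn] = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation with pooled out-of-fold scoring.

    Each fold is scored by a model trained on the remaining folds; the
    held-out scores are pooled into one ROC/AUC and one confusion table
    (hard calls at ``threshold``).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    X, y = _encode(windows, schemes, k_values)
    if k == len(y):
        # leave-one-out: singleton folds, definitionally unstratifiable
        folds = [np.array([i]) for i in range(len(y))]
    else:
        folds = _stratified_folds(y, k, seed)
    fit = trainer or _default_trainer(config)
    oof = np.full(len(y), np.nan)
    for fold_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[fold_idx] = False
        clf = fit(X.iloc[mask], y[mask])
        oof[fold_idx] = _score_with(clf, X.iloc[fold_idx])
    assert not np.isnan(oof).any(), "every sample must be scored exactly once"
    pts, area = roc_auc(y, oof)
    c = confusion(y, (oof >= threshold).astype(int))
    return metrics(
        c,
        auc=area,
        roc=pts,
        protocol={
            "name": "kfold_cv",
            "k": k,
            "seed": seed,
            "schemes": schemes if isinstance(schemes, str) else list(schemes),
            "n_trees": config.n_trees,
            "rf_seed": config.seed,
            "threshold": threshold,
        },
    )


def _stratified_split(y: np.ndarray, train_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_train = int(round(train_fraction * len(idx)))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def ratio_split_eval(
    windows: Sequence[SampleWindow],
    schemes: Union[str, Sequence[str]] = "mnbe",
    config: RFConfig = RFConfig(),
    train_fraction: float = 0.5,
    seed: int = 1,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    threshold: float = 0.5,
    trainer: Optional[TrainerFn] = None,
) -> tuple[MetricsReport, MetricsReport]:
    """Stratified train/test split; returns (testing, training) reports.

    The testing report scores the held-out part with a model fitted on
    the training part.  The training report is an internal fivefold CV
    on the training part alone (plain resubstitution would be trivially
    perfect for a forest and carry no information).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    X, y = _encode(windows, schemes, k_values)
    tr, te = _stratified_split(y, train_fraction, seed)
    for part, name in ((tr, "training"), (te, "testing")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"degenerate split: {name} part lacks a class")
    fit = trainer or _default_trainer(config)
    clf = fit(X.iloc[tr], y[tr])
    test_scores = _score_with(clf, X.iloc[te])
    pts, area = roc_auc(y[te], test_scores)
    meta = {
        "name": "ratio_split",
        "train_fraction": train_fraction,
        "seed": seed,
        "schemes": schemes if isinstance(schemes, str) else list(schemes),
        "n_trees": config.n_trees,
        "rf_seed": config.seed,
        "threshold": threshold,
    }
    testing = metrics(
        confusion(y[te], (test_scores >= threshold).astype(int)),
        auc=area,
        roc=pts,
        protocol={**meta, "part": "testing"},
    )
    training = kfold_cv(
        [windows[i] for i in tr],
        schemes=schemes,
        config=config,
        k=5,
        seed=seed,
        k_values=k_values,
        threshold=threshold,
        trainer=trainer,
    )
    training.protocol = {**meta, "part": "training", "inner_k": 5}
    return testing, training


def jackknife_cv(
    windows: Sequence[SampleWindow],
    schemes: Union[str, Sequence[str]] = "mnbe",
    config: RFConfig = RFConfig(),
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    threshold: float = 0.5,
    cap: int = JACKKNIFE_CAP,
    force: bool = False,
    trainer: Optional[TrainerFn] = None,
) -> MetricsReport:
    """Leave-one-out cross-validation (n fits, pooled predictions).

    Refuses to run above ``cap`` samples unless ``force=True`` — use
    :func:`kfold_cv` at scale.
    """
    X, y = _encode(windows, schemes, k_values)
    n = len(y)
    if n > cap and not force:
        raise ValueError(
            f"jackknife on {n} samples exceeds the cap of {cap}; "
            "use kfold_cv or pass force=True"
        )
    fit = trainer or _default_trainer(config)
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = fit(X.iloc[mask], y[mask])
        scores[i] = _score_with(clf, X.iloc[[i]])[0]
        mask[i] = True
    pts, area = roc_auc(y, scores)
    c = confusion(y, (scores >= threshold).astype(int))
    return metrics(
        c,
        auc=area,
        roc=pts,
        protocol={
            "name": "jackknife",
            "n": n,
            "schemes": schemes if isinstance(schemes, str) else list(schemes),
            "n_trees": config.n_trees,
            "rf_seed": config.seed,
            "threshold": threshold,
        },
    )


def independent_eval(
    model: TrainedModel,
    windows: Sequence[SampleWindow],
    schemes: Union[str, Sequence[str], None] = None,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    threshold: float = 0.5,
) -> MetricsReport:
    """Score an independent labelled set with a fitted model; no refit.

    The caller asserts disjointness from the training data.  A
    single-class test set still yields the point metrics (with the
    undefined rate as NaN) but no ROC/AUC.
    """
    if schemes is None:
        schemes = model.metadata.get("schemes", "mnbe")
    X, y = _encode(windows, schemes, k_values)
    scores = predict_scores(model, X)
    c = confusion(y, (scores >= threshold).astype(int))
    pts: Optional[np.ndarray] = None
    area: Optional[float] = None
    if c.n_pos > 0 and c.n_neg > 0:
        pts, area = roc_auc(y, scores)
    return metrics(
        c,
        auc=area,
        roc=pts,
        protocol={
            "name": "independent",
            "n": len(y),
            "schemes": schemes if isinstance(schemes, str) else list(schemes),
            "threshold": threshold,
        },
        strict=False,
    )
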