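"""Residue classifiers and cross-validated binary evaluation.

The predictor is an extreme-gradient-boosting (XGBoost) classifier trained
on the balanced residue table; support-vector-machine (RBF) and single
classification-tree (CART) baselines share the same interface.  Evaluation
reports accuracy, sensitivity, specificity, precision, the Matthews
correlation coefficient and ROC AUC, under jackknife (leave-one-out),
k-fold cross-validation, or independent-set testing.

Metric definitions (on the confusion counts):

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SEN = TP / (TP + FN)
    SPE = TN / (TN + FP)
    PRE = TP / (TP + FP)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A zero denominator yields NaN with a warning, never a silent 0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier


@dataclass
class ModelConfig:
    """Learner choice plus hyperparameter overrides and the training seed.

    Defaults: gradient boosting with 500 trees, depth 6, learning rate 0.1;
    SVM with an RBF kernel, C = 1, gamma = 'scale'; CART with Gini impurity
    and unlimited depth.
    """

    algorithm: str = "xgboost"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("xgboost", "svm", "cart"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Classification metrics with the counts they were computed from."""

    acc: float
    sen: float
    spe: float
    pre: float
    mcc: float
    auc: float | None
    counts: ConfusionCounts
    protocol: str

    def summary(self) -> str:
        fmt = lambda v: "   nan" if v is None or math.isnan(v) else f"{v:.4f}"
        lines = [
            f"protocol: {self.protocol}",
            f"counts:   TP={self.counts.tp} TN={self.counts.tn} "
            f"FP={self.counts.fp} FN={self.counts.fn}",
            f"ACC={fmt(self.acc)}  SEN={fmt(self.sen)}  SPE={fmt(self.spe)}  "
            f"PRE={fmt(self.pre)}  MCC={fmt(self.mcc)}  "
            f"AUC={'  n/a' if self.auc is None else fmt(self.auc)}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "ACC": self.acc, "SEN": self.sen, "SPE": self.spe,
            "PRE": self.pre, "MCC": self.mcc, "AUC": self.auc,
            "counts": {"TP": self.counts.tp, "TN": self.counts.tn,
                       "FP": self.counts.fp, "FN": self.counts.fn},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class TrainedModel:
    """A fitted learner plus the feature schema it was trained on."""

    def __init__(self, estimator, feature_columns: list[str], cfg: ModelConfig):
        self.estimator = estimator
        self.feature_columns = list(feature_columns)
        self.cfg = cfg

    def scores(self, rows: pd.DataFrame) -> np.ndarray:
        """Per-row positive-class score in [0, 1] after schema realignment."""
        missing = [c for c in self.feature_columns if c not in rows.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        x = rows[self.feature_columns].to_numpy(dtype=float)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(x)[:, 1]
        # margin classifiers: logistic map keeps the 0.5 threshold at margin 0
        z = est.decision_function(x)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(scores, hard labels); ties at 0.5 classify positive."""
        s = self.scores(rows)
        return s, (s >= 0.5).astype(int)


def _make_estimator(cfg: ModelConfig):
    hp = dict(cfg.hyperparameters)
    if cfg.algorithm == "xgboost":
        params = dict(n_estimators=500, max_depth=6, learning_rate=0.1,
                      tree_method="hist", n_jobs=1, random_state=cfg.seed,
                      eval_metric="logloss")
        params.update(hp)
        return XGBClassifier(**params)
    if cfg.algorithm == "svm":
        params = dict(kernel="rbf", C=1.0, gamma="scale", random_state=cfg.seed)
        params.update(hp)
        return SVC(**params)
    params = dict(criterion="gini", random_state=cfg.seed)
    params.update(hp)
    return DecisionTreeClassifier(**params)


def feature_matrix(t: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Split a feature table into (feature frame, labels, feature column names)."""
    meta = {"structure_id", "chain", "resnum", "icode", "resname", "label"}
    cols = [c for c in t.columns if c not in meta]
    return t[cols], t["label"].to_numpy(dtype=int), cols


def train(t: pd.DataFrame, cfg: ModelConfig | None = None) -> TrainedModel:
    """Fit a classifier on a labelled feature table.

    Deterministic for a fixed seed with single-threaded training; raises
    on an empty or single-class table.
    """
    cfg = cfg or ModelConfig()
    if t.empty:
        raise ValueError("cannot train on an empty table")
    x, y, cols = feature_matrix(t)
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    est = _make_estimator(cfg)
    est.fit(x.to_numpy(dtype=float), y)
    return TrainedModel(est, cols, cfg)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def metrics(
    c: ConfusionCounts,
    scores: np.ndarray | None = None,
    y_true: Sequence[int] | None = None,
    protocol: str = "custom",
    spe_fn_variant: bool = False,
) -> EvalReport:
    """Evaluation metrics from confusion counts (and scores, for AUC).

    ``spe_fn_variant=True`` computes specificity as TN/(TN+FN) instead
    of the standard TN/(TN+FP).  AUC is the trapezoidal area under the ROC
    curve of ``scores`` against ``y_true``; it is omitted (None), never
    fabricated, when scores are not supplied.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    acc = _ratio(tp + tn, c.total, "ACC")
    sen = _ratio(tp, tp + fn, "SEN")
    spe = (_ratio(tn, tn + fn, "SPE") if spe_fn_variant
           else _ratio(tn, tn + fp, "SPE"))
    pre = _ratio(tp, tp + fp, "PRE")
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "MCC")
    auc = None
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true required alongside scores for AUC")
        y = np.asarray(y_true, dtype=int)
        if len(np.unique(y)) < 2:
            warnings.warn("AUC undefined with a single class; reporting NaN")
            auc = float("nan")
        else:
            auc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    return EvalReport(acc, sen, spe, pre, mcc, auc, c, protocol)


def _check_both_classes(y: np.ndarray, idx: np.ndarray) -> bool:
    return len(np.unique(y[idx])) == 2


def cross_validate(
    t: pd.DataFrame,
    cfg: ModelConfig | None = None,
    protocol: str = "kfold",
    k: int = 10,
    seed: int = 0,
    spe_fn_variant: bool = False,
) -> EvalReport:
    """Cross-validated evaluation with metrics pooled over out-of-fold rows.

    ``protocol='jackknife'`` is leave-one-row-out; ``'kfold'`` uses
    class-stratified folds with deterministic seeded assignment (k = n
    degenerates to leave-one-out and therefore reproduces the jackknife
    for a deterministic learner).  If a training fold loses a class the
    folds are re-drawn once with a shifted seed, then an error is raised.
    """
    cfg = cfg or ModelConfig()
    n = len(t)
    x, y, cols = feature_matrix(t)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present")

    if protocol == "jackknife" or (protocol == "kfold" and k == n):
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
        label = "jackknife" if protocol == "jackknife" else f"kfold(k={k})"
    elif protocol == "kfold":
        if not 2 <= k <= n:
            raise ValueError(f"k must be in [2, {n}], got {k}")
        for attempt_seed in (seed, seed + 1):
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=attempt_seed)
            folds = list(skf.split(np.zeros(n), y))
            if all(_check_both_classes(y, tr) for tr, _ in folds):
                break
        else:
            raise ValueError("a training fold is missing a class even after re-draw")
        label = f"kfold(k={k})"
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    pooled_scores = np.full(n, np.nan)
    for tr, te in folds:
        if not _check_both_classes(y, tr):
            raise ValueError("a jackknife training fold is missing a class")
        model = train(t.iloc[tr], cfg)
        pooled_scores[te] = model.scores(t.iloc[te])
    assert not np.isnan(pooled_scores).any(), "a row was never held out"
    y_pred = (pooled_scores >= 0.5).astype(int)
    return metrics(confusion(y, y_pred), pooled_scores, y, label,
                   spe_fn_variant)


def evaluate_independent(
    model: TrainedModel,
    test: pd.DataFrame,
    spe_fn_variant: bool = False,
) -> EvalReport:
    """Evaluate a trained model on an untouched, naturally imbalanced test
    table (no refitting, no resampling)."""
    if test.empty:
        raise ValueError("independent test set is empty")
    y = test["label"].to_numpy(dtype=int)
    scores, y_pred = model.predict(test)
    return metrics(confusion(y, y_pred), scores, y, "independent",
                   spe_fn_variant)
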