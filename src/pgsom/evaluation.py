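"""Metrics, cross-validation and hyperparameter-grid machinery.

Evaluation follows the standard protocol for unsupervised activity
classifiers: the confusion matrix of true versus predicted class feeds
accuracy (trace over total), Cohen's kappa (observed agreement corrected
for the agreement expected from the marginals), macro-averaged recall and
macro F-measure (classes absent from the truth are excluded from macro
averages).  Cross-validation is seeded stratified k-fold; each fold trains
an unsupervised map on the fold-train portion, calibrates it with a fixed
seeded labeled subset, and scores the held-out fold.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import core
from .calibration import calibrate, predict
from .core import TrainConfig, train


@dataclass
class EvalReport:
    """Scalar summary of one evaluation."""

    accuracy: float
    kappa: float
    macro_recall: float
    macro_f1: float
    per_class_recall: Dict[int, float]
    neuron_count: int = 0
    inference_ms: float = 0.0     # informational; hardware-dependent


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     labels: Optional[Sequence[int]] = None
                     ) -> Tuple[np.ndarray, List[int]]:
    """K x K count matrix, rows = true class, cols = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if labels is None:
        labels = sorted(set(np.unique(y_true)) | set(np.unique(y_pred)))
    labels = [int(l) for l in labels]
    index = {l: i for i, l in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[int(t)], index[int(p)]] += 1
    return cm, labels


def metrics(cm: np.ndarray, labels: Optional[Sequence[int]] = None) -> EvalReport:
    """Accuracy, Cohen's kappa, macro recall and macro F1 from a count matrix.

    Kappa = (p_o - p_e) / (1 - p_e) with p_e from the row/column marginals;
    degenerate p_e = 1 yields kappa 1 for perfect agreement, else 0.
    Per-class F1 is 0 when precision + recall is 0.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if cm.size == 0 or total <= 0:
        raise ValueError("confusion matrix is empty")
    k = cm.shape[0]
    if labels is None:
        labels = list(range(1, k + 1))
    p_o = np.trace(cm) / total
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    p_e = float(np.dot(row, col)) / total ** 2
    if p_e >= 1.0:
        kappa = 1.0 if p_o >= 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)

    recalls, f1s, per_class = [], [], {}
    for i in range(k):
        if row[i] == 0:
            continue                      # class absent from the truth
        rec = cm[i, i] / row[i]
        prec = cm[i, i] / col[i] if col[i] > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        recalls.append(rec)
        f1s.append(f1)
        per_class[int(labels[i])] = float(rec)
    return EvalReport(
        accuracy=float(p_o),
        kappa=float(kappa),
        macro_recall=float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
        per_class_recall=per_class,
    )


def evaluate_model(state: core.NetworkState, label_map, X: np.ndarray,
                   y: np.ndarray) -> Tuple[EvalReport, np.ndarray, List[int]]:
    """Score a calibrated map on labeled data; returns (report, cm, labels)."""
    t0 = time.perf_counter()
    y_pred = predict(state, label_map, X)
    elapsed = time.perf_counter() - t0
    cm, labels = confusion_matrix(y, y_pred)
    rep = metrics(cm, labels)
    rep.neuron_count = len(state)
    rep.inference_ms = 1000.0 * elapsed / max(1, len(y))
    return rep, cm, labels


def train_validation_split(n: int, ratio: float = 0.9) -> Tuple[int, int]:
    """Sizes of a train/validation split at the given ratio (floor on train)."""
    n_train = int(n * ratio)
    return n_train, n - n_train


def stratified_folds(y: np.ndarray, k: int,
                     rng: np.random.Generator) -> List[np.ndarray]:
    """Seeded stratified partition into k folds (sizes differ by <= 1).

    Within each class the shuffled members are dealt round-robin to folds,
    starting from a rotating offset so fold sizes stay balanced overall.
    """
    y = np.asarray(y)
    n = len(y)
    if k < 2 or k > n:
        raise ValueError(f"k must lie in [2, {n}]")
    fold_of = np.empty(n, dtype=np.int64)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            fold_of[i] = (offset + j) % k
        offset = (offset + len(idx)) % k
    return [np.flatnonzero(fold_of == f) for f in range(k)]


def run_fold(X: np.ndarray, y: np.ndarray, train_idx: np.ndarray,
             test_idx: np.ndarray, config: TrainConfig) -> EvalReport:
    """Train on the fold-train portion, calibrate, score the held-out fold."""
    state = train(X[train_idx], config)
    rng = np.random.default_rng(config.seed + 1)
    n_cal = min(config.calib_size, len(train_idx))
    cal = rng.choice(len(train_idx), size=n_cal, replace=False)
    lm = calibrate(state, X[train_idx][cal], y[train_idx][cal])
    missing = set(np.unique(y[test_idx])) - set(np.unique(y[train_idx][cal]))
    if missing:
        warnings.warn(f"classes {sorted(missing)} absent from calibration; "
                      "metrics computed on present classes", RuntimeWarning)
    rep, _, _ = evaluate_model(state, lm, X[test_idx], y[test_idx])
    return rep


def holdout_run(X: np.ndarray, y: np.ndarray, config: TrainConfig,
                holdout: float = 0.1) -> Tuple[EvalReport, core.NetworkState]:
    """Train/calibrate on the leading (1 - holdout) fraction, score the rest.

    The split is positional (generators already shuffle rows); the
    calibration subset is a fixed seeded draw from the training portion.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_train, _ = train_validation_split(len(X), 1.0 - holdout)
    state = train(X[:n_train], config)
    rng = np.random.default_rng(config.seed + 1)
    n_cal = min(config.calib_size, n_train)
    cal = rng.choice(n_train, size=n_cal, replace=False)
    lm = calibrate(state, X[cal], y[cal])
    rep, _, _ = evaluate_model(state, lm, X[n_train:], y[n_train:])
    return rep, state


def cross_validate(X: np.ndarray, y: np.ndarray, config: TrainConfig,
                   k: int = 10) -> Dict[str, object]:
    """Seeded stratified k-fold cross-validation.

    Returns per-fold reports plus mean/std of accuracy, kappa, macro F1
    and neuron count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(config.seed)
    folds = stratified_folds(y, k, rng)
    reports: List[EvalReport] = []
    for f, test_idx in enumerate(folds):
        train_idx = np.concatenate([folds[g] for g in range(k) if g != f])
        reports.append(run_fold(X, y, train_idx, test_idx, config))
    summary = {}
    for name in ("accuracy", "kappa", "macro_f1", "neuron_count"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        summary[f"{name}_mean"] = float(vals.mean())
        summary[f"{name}_std"] = float(vals.std())
    return {"folds": reports, **summary}


def grid_search(X: np.ndarray, y: np.ndarray, sf_list: Sequence[float],
                rf_list: Sequence[float], config: TrainConfig,
                k: int = 10) -> pd.DataFrame:
    """Cross-validate every (SF, RF) cell with shared seeds.

    Returns a table with one row per cell: sf, rf, mean accuracy, accuracy
    std, mean neuron count.
    """
    if not sf_list or not rf_list:
        raise ValueError("sf_list and rf_list must be non-empty")
    rows = []
    for sf in sf_list:
        for rf in rf_list:
            cfg = TrainConfig(**{**config.__dict__, "sf": sf, "rf": rf,
                                 "m": None})
            res = cross_validate(X, y, cfg, k=k)
            rows.append({"sf": sf, "rf": rf,
                         "accuracy_mean": res["accuracy_mean"],
                         "accuracy_std": res["accuracy_std"],
                         "neuron_count_mean": res["neuron_count_mean"]})
    return pd.DataFrame(rows)


def percent_reduction(baseline: float, reduced: float) -> float:
    """Percent reduction of ``reduced`` relative to ``baseline``, 1 decimal.

    E.g. a map shrinking from 1254 to 856.1 neurons is a 31.7% reduction.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (1.0 - reduced / baseline), 1)
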