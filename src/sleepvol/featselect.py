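"""Discriminative feature selection between sleep-stage pairs.

Ranks wavelet-derived window features by mutual information with stage
labels, random-forest impurity importance, and absolute linear-SVM weights,
and runs recursive feature elimination (RFE) with cross-validation to emit
one binary row of the selection matrix ``B`` per unordered stage pair
(``B[pair, f] = 1`` iff feature ``f`` is kept for that pair).  The selected
indicators of a stage's pairs are the importance weights ``b_i`` used by
the wavelet features.

Standardization: features are z-scored before SVM fitting (zero-variance
columns get weight 0); trees see raw values.  All stochastic selectors are
reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .wavelets import _quantile_bin

__all__ = [
    "FeatureMatrix",
    "SelectionMatrixB",
    "mutual_information",
    "rf_importance",
    "svm_weight_ranking",
    "rfe_select",
    "build_selection_matrix",
    "build_selection_heatmap",
    "weights_for_stage",
]

log = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Windows x features matrix with per-window stage labels."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.y) != len(self.X):
            raise ValueError("label count != row count")
        if not np.all(np.isfinite(self.X.to_numpy(dtype=float))):
            raise ValueError("feature matrix contains non-finite entries")


@dataclass
class SelectionMatrixB:
    """Binary selection matrix: stage pairs x features."""

    table: pd.DataFrame  # index: "Si|Sj" pair labels, columns: features
    n_keep: int

    def __post_init__(self) -> None:
        vals = self.table.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("selection matrix must be strictly binary")
        if not np.all(vals.sum(axis=1) == self.n_keep):
            raise ValueError(
                f"every row must select exactly n_keep={self.n_keep} features")


def mutual_information(feature, labels, bins: int = 10) -> float:
    """Plug-in mutual information (nats) between a binned feature and labels.

    The feature is quantile-binned (default 10 bins), so the estimate is
    invariant to strictly monotone feature transformations.  A single label
    class carries no information and returns 0 (logged).
    """
    x = np.asarray(feature, dtype=float).ravel()
    y = np.asarray(labels)
    if len(x) != len(y):
        raise ValueError("feature and labels differ in length")
    classes, yi = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        log.debug("mutual_information: single label class, MI = 0")
        return 0.0
    xi, n_bins = _quantile_bin(x, bins)
    joint = np.zeros((n_bins, len(classes)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz]
                                           / (px @ py)[nz])))


def _validate_xy(X, y, min_per_class: int = 10):
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if Xa.ndim != 2 or len(Xa) != len(y):
        raise ValueError("X must be 2-d with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two label classes")
    if counts.min() < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} rows per class, got {counts.min()}")
    return Xa, y


def rf_importance(X, y, n_estimators: int = 200, seed: int = 0) -> np.ndarray:
    """Mean impurity-decrease importance per feature over the forest.

    Importances are non-negative and normalized to sum to 1.
    """
    Xa, y = _validate_xy(X, y)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(Xa, y)
    imp = rf.feature_importances_
    total = imp.sum()
    return imp / total if total > 0 else imp


def _standardize(Xa: np.ndarray) -> np.ndarray:
    mu = Xa.mean(axis=0)
    sd = Xa.std(axis=0)
    out = np.zeros_like(Xa)
    nz = sd > 0
    out[:, nz] = (Xa[:, nz] - mu[nz]) / sd[nz]
    return out  # zero-variance columns stay 0 -> SVM weight 0


def _svm_weights(Xa: np.ndarray, y, C: float) -> np.ndarray:
    clf = SVC(kernel="linear", C=C)
    clf.fit(_standardize(Xa), y)
    return np.abs(np.asarray(clf.coef_).ravel())


def svm_weight_ranking(X, y, C: float = 1.0) -> np.ndarray:
    """Feature indices ranked by descending absolute linear-SVM weight.

    Ties are broken by ascending column index (stable sort).  Labels must
    be binary (one stage pair).
    """
    Xa, y = _validate_xy(X, y, min_per_class=2)
    if len(np.unique(y)) != 2:
        raise ValueError("svm_weight_ranking expects exactly two classes")
    w = _svm_weights(Xa, y, C)
    return np.argsort(-w, kind="stable")


def rfe_select(X, y, n_keep: int, cv_folds: int = 5, C: float = 1.0,
               seed: int = 0) -> tuple[np.ndarray, list]:
    """Recursive feature elimination with a linear SVM.

    Repeatedly drops the lowest-|w| feature and refits until ``n_keep``
    features remain.  Returns the binary selection row and the
    cross-validated accuracy trace ``[(n_features, accuracy), ...]``
    recorded at each elimination step.
    """
    Xa, y = _validate_xy(X, y, min_per_class=2)
    n_features = Xa.shape[1]
    if n_keep > n_features:
        raise ValueError(
            f"n_keep={n_keep} exceeds feature count {n_features}")
    active = list(range(n_features))
    trace: list[tuple[int, float]] = []
    cv = StratifiedKFold(n_splits=min(cv_folds,
                                      int(np.bincount(
                                          pd.factorize(y)[0]).min())),
                         shuffle=True, random_state=seed)
    while True:
        scores = cross_val_score(SVC(kernel="linear", C=C),
                                 _standardize(Xa[:, active]), y, cv=cv)
        trace.append((len(active), float(scores.mean())))
        if len(active) <= n_keep:
            break
        w = _svm_weights(Xa[:, active], y, C)
        # drop the lowest-weight feature; ties resolved to the lowest index
        drop = int(np.argmin(w))
        del active[drop]
    row = np.zeros(n_features, dtype=int)
    row[active] = 1
    return row, trace


def build_selection_matrix(fm: FeatureMatrix, n_keep: int = 20,
                           cv_folds: int = 5, C: float = 1.0, seed: int = 0,
                           mode: str = "pairs") -> SelectionMatrixB:
    """RFE-selected binary matrix B over stage pairs (or one-vs-rest).

    ``mode="pairs"`` (default) emits one row per unordered stage pair;
    ``mode="one-vs-rest"`` one row per stage.
    """
    y = np.asarray(fm.y)
    stages = sorted(set(y))
    Xa = fm.X.to_numpy(dtype=float)
    rows, labels = [], []
    if mode == "pairs":
        tasks = [(f"{a}|{b}", np.isin(y, (a, b))) for a, b in
                 combinations(stages, 2)]
    elif mode == "one-vs-rest":
        tasks = [(str(s), np.ones(len(y), dtype=bool)) for s in stages]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for label, sel in tasks:
        ysub = y[sel] if mode == "pairs" else (y == label)
        row, _ = rfe_select(Xa[sel], ysub, n_keep, cv_folds, C, seed)
        rows.append(row)
        labels.append(label)
    table = pd.DataFrame(rows, index=labels, columns=list(fm.X.columns))
    table.index.name = "stage_pair"
    return SelectionMatrixB(table=table, n_keep=n_keep)


def weights_for_stage(B: SelectionMatrixB, stage: str) -> np.ndarray:
    """Binary b_i weights for a stage: union over pairs involving it."""
    mask = [stage in idx.split("|") for idx in B.table.index]
    if not any(mask):
        raise KeyError(f"stage {stage!r} appears in no selection row")
    return (B.table.loc[mask].to_numpy().max(axis=0)).astype(float)


def build_selection_heatmap(B: SelectionMatrixB, path=None) -> pd.DataFrame:
    """Row/column-labeled matrix export for heatmap visualization."""
    df = B.table.copy()
    df.index.name = "stage_pair"
    if path is not None:
        df.to_csv(path)
    return df
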