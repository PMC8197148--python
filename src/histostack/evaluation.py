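"""Classification metrics, the 5x2cv paired t-test, learning curves and QC.

The 5x2cv paired t-test (Dietterich, 1998) compares two classifiers with
five replications of stratified two-fold cross-validation.  With
``d_i^(j)`` the accuracy difference on fold ``j`` of replication ``i``,
``d_bar_i`` the replication mean and ``s_i^2 = (d_i^(1) - d_bar_i)^2 +
(d_i^(2) - d_bar_i)^2`` the replication variance, the statistic

    t = d_1^(1) / sqrt(sum_i s_i^2 / 5)

follows a Student t distribution with 5 degrees of freedom under the null
hypothesis of equal accuracy.  Both classifiers are refit from scratch in
every fold so the comparison covers the whole training procedure, not one
fitted model.

The misclassification report links errors to the blank-space QC statistic:
patches dominated by near-white/near-black pixels carry little texture and
dominate the error set in real slide data.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .fusion import FeatureTable
from .patch_io import Manifest, blankspace_fraction, read_patch
from .stacking import derive_seed

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Confusion counts and the four headline metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float

    def to_text(self) -> str:
        return (
            f"confusion: TP={self.tp} FP={self.fp} FN={self.fn} TN={self.tn}\n"
            f"accuracy={self.accuracy:.6f} precision={self.precision:.6f} "
            f"recall={self.recall:.6f} f1={self.f1:.6f}\n"
        )


def confusion_and_metrics(y_true: Sequence[int], y_pred: Sequence[int]) -> EvalReport:
    """Binary confusion counts plus accuracy / precision / recall / F1.

    Conventions: precision = 1 when no positives are predicted (zero false
    positives, logged); F1 = 0 when precision + recall = 0.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    accuracy = (tp + tn) / y_true.size
    if tp + fp == 0:
        log.info("no positive predictions: precision = 1.0 by convention")
        precision = 1.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(tp, fp, fn, tn, accuracy, precision, recall, f1)


@dataclass
class TTest52Result:
    t: float
    df: int
    p_two_sided: float
    per_replication: np.ndarray  # 5 x 2 accuracy differences


def t_from_differences(d: np.ndarray) -> TTest52Result:
    """The 5x2cv statistic from a 5 x 2 grid of fold accuracy differences."""
    d = np.asarray(d, dtype=np.float64)
    if d.shape != (5, 2):
        raise ValueError(f"need a 5 x 2 difference grid, got {d.shape}")
    d_bar = d.mean(axis=1)
    s2 = ((d[:, 0] - d_bar) ** 2) + ((d[:, 1] - d_bar) ** 2)
    denom = np.sqrt(s2.sum() / 5.0)
    if np.all(d == 0):
        return TTest52Result(0.0, 5, 1.0, d)
    if denom == 0:
        t = np.inf if d[0, 0] > 0 else -np.inf
    else:
        t = d[0, 0] / denom
    p = float(2.0 * stats.t.sf(abs(t), df=5))
    return TTest52Result(float(t), 5, p, d)


def _fresh(clf):
    """A fresh unfitted copy: clone estimators, call factories."""
    if isinstance(clf, BaseEstimator):
        return clone(clf)
    if callable(clf):
        return clf()
    return copy.deepcopy(clf)


def ttest_5x2(clf_a, clf_b, table: FeatureTable, seed: int) -> TTest52Result:
    """Dietterich's 5x2cv paired t-test on a labelled feature table.

    ``clf_a`` / ``clf_b`` are estimators (cloned per fold) or zero-argument
    factories returning fresh estimators.
    """
    X, y = table.X, table.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) < 10:
        raise ValueError("need at least 10 rows for 5x2cv")
    d = np.zeros((5, 2))
    for i in range(5):
        cv = StratifiedKFold(n_splits=2, shuffle=True, random_state=derive_seed(seed, i))
        try:
            for j, (idx_fit, idx_eval) in enumerate(cv.split(X, y)):
                accs = []
                for clf in (clf_a, clf_b):
                    est = _fresh(clf)
                    est.fit(X[idx_fit], y[idx_fit])
                    accs.append(float(np.mean(est.predict(X[idx_eval]) == y[idx_eval])))
                d[i, j] = accs[0] - accs[1]
        except ValueError as exc:
            raise ValueError(f"degenerate folds in replication {i}: {exc}") from exc
    return t_from_differences(d)


def learning_curve(
    table: FeatureTable,
    fractions: Sequence[float],
    fixed_test: FeatureTable,
    seed: int,
    clf=None,
) -> list[tuple[int, float]]:
    """Test accuracy versus training-pool fraction, with an unaltered test set.

    Each fraction draws a stratified subsample of the training pool, refits
    the full pipeline from scratch and scores the fixed test partition.
    """
    from .stacking import StackedClassifier

    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if set(table.source_ids) & set(fixed_test.source_ids):
        raise ValueError("test partition overlaps the training pool")
    X, y = table.X, table.y
    Xt, yt = fixed_test.X, fixed_test.y
    clf = clf if clf is not None else StackedClassifier(seed=derive_seed(seed, 7))
    points: list[tuple[int, float]] = []
    for k, frac in enumerate(fractions):
        if frac == 1.0:
            idx = np.arange(len(y))
        else:
            splitter = StratifiedShuffleSplit(
                n_splits=1, train_size=frac, random_state=derive_seed(seed, 100 + k)
            )
            try:
                idx, _ = next(splitter.split(X, y))
            except ValueError:
                log.warning("fraction %.3f yields < 2 samples per class; skipped", frac)
                continue
        counts = np.bincount(y[idx])
        if counts.min() < 2:
            log.warning("fraction %.3f yields < 2 samples per class; skipped", frac)
            continue
        est = _fresh(clf)
        est.fit(X[idx], y[idx])
        acc = float(np.mean(est.predict(Xt) == yt))
        points.append((len(idx), acc))
    return points


def misclassification_report(
    test_manifest: Manifest,
    y_true: Sequence[int],
    y_pred: Sequence[int],
    white_thr: int = 240,
    black_thr: int = 15,
) -> pd.DataFrame:
    """Misclassified patches with their blank-space fraction.

    Returns one row per error with columns ``source_id, true, pred, section,
    blankspace_fraction``; false positives first, each section sorted by
    blank-space fraction descending.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if not (len(test_manifest) == len(y_true) == len(y_pred)):
        raise ValueError("manifest, y_true and y_pred must be aligned")
    rows = []
    for (path, _, source_id), t, p in zip(test_manifest.records, y_true, y_pred):
        if t == p:
            continue
        frac = blankspace_fraction(read_patch(path), white_thr, black_thr)
        rows.append(
            {
                "source_id": source_id,
                "true": int(t),
                "pred": int(p),
                "section": "FP" if p == 1 else "FN",
                "blankspace_fraction": frac,
            }
        )
    df = pd.DataFrame(rows, columns=["source_id", "true", "pred", "section", "blankspace_fraction"])
    if len(df):
        df = df.sort_values(
            ["section", "blankspace_fraction"], ascending=[True, False]
        ).reset_index(drop=True)
    return df
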