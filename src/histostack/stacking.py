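"""Two-fold stacking with Pearson-correlation pruning of the meta-features.

The ensemble works in two stages.  Stage 1 splits the training partition into
two stratified halves, fits each base learner on the first half and scores
the second half (and the test partition); the per-learner positive-class
scores become the *meta-features*.  Because base learners trained on the same
data tend to agree, the meta-feature columns are then pruned: columns are
greedily eliminated while any pair correlates above a threshold ``tau``
(|Pearson r| > tau), always dropping the column most correlated on average
with the others (ties broken toward the lower validation accuracy, then the
higher column index).  Stage 2 fits a meta-classifier on the surviving
columns only.

The six-learner roster is XGB (XGBoost), AB (AdaBoost), GB (gradient-boosted
trees), RF (random forest), ET (extra trees) and MLP (a multilayer perceptron
with hidden layers 100-50-20-10, z-scored inputs fit on its own training
fold).  Any roster learner can also serve as the meta-classifier; the
boosted-tree learner GB is the default meta.  All randomness derives from one
master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .fusion import FeatureTable

log = logging.getLogger(__name__)

ROSTER_NAMES = ("XGB", "AB", "GB", "RF", "ET", "MLP")
MLP_HIDDEN_LAYERS = (100, 50, 20, 10)


def derive_seed(master: int, *keys: int) -> int:
    """Stable child seed < 2^31 from a master seed and integer keys."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(keys))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class BaseLearnerSpec:
    """Name + hyperparameters + seed of one roster member."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ROSTER_NAMES:
            raise ValueError(f"unknown learner {self.name!r}; roster names are {ROSTER_NAMES}")


def build_learner(spec: BaseLearnerSpec):
    """Instantiate the scikit-learn / XGBoost estimator behind a spec."""
    params = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.name == "XGB":
        return XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss", **params
        )
    if spec.name == "AB":
        return AdaBoostClassifier(random_state=seed, **params)
    if spec.name == "GB":
        return HistGradientBoostingClassifier(random_state=seed, **params)
    if spec.name == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if spec.name == "ET":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if spec.name == "MLP":
        params.setdefault("hidden_layer_sizes", MLP_HIDDEN_LAYERS)
        params.setdefault("max_iter", 300)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("mlp", MLPClassifier(random_state=seed, **params)),
            ]
        )
    raise ValueError(spec.name)


def default_roster(seed: int, names: Sequence[str] = ROSTER_NAMES) -> list[BaseLearnerSpec]:
    """One spec per name, each with its own seed derived from the master seed."""
    return [BaseLearnerSpec(name, seed=derive_seed(seed, idx)) for idx, name in enumerate(names)]


def _positive_scores(est, X: np.ndarray) -> np.ndarray:
    proba = est.predict_proba(X)
    classes = list(est.classes_) if hasattr(est, "classes_") else [0, 1]
    return proba[:, classes.index(1)]


@dataclass
class MetaFeatureTable:
    """Per-sample stage-1 scores, one column per base learner."""

    df: pd.DataFrame  # columns = learner names, values in [0, 1]
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        vals = self.df.to_numpy(dtype=np.float64)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("meta-feature scores must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.df):
                raise ValueError("labels misaligned with rows")

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def column_accuracies(self) -> np.ndarray:
        """Accuracy of thresholding each column at 0.5 against the labels."""
        if self.labels is None:
            raise ValueError("no labels attached")
        X = self.df.to_numpy(dtype=np.float64)
        return np.array([np.mean((X[:, j] >= 0.5) == self.labels) for j in range(X.shape[1])])


@dataclass
class CorrelationMatrix:
    R: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=np.float64)
        if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] != len(self.column_names):
            raise ValueError("correlation matrix shape mismatch")
        self.R = R


def pearson_matrix(meta: MetaFeatureTable) -> CorrelationMatrix:
    """Pairwise Pearson r of the meta-feature columns (constant column -> r = 0)."""
    X = meta.df.to_numpy(dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for a correlation")
    k = X.shape[1]
    centered = X - X.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    constant = norms == 0
    if constant.any():
        log.warning("constant meta-feature column(s) %s: correlation set to 0",
                    [meta.columns[j] for j in np.flatnonzero(constant)])
    safe = np.where(constant, 1.0, norms)
    R = (centered / safe).T @ (centered / safe)
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    return CorrelationMatrix(R, meta.columns)


def select_complementary(
    R: CorrelationMatrix, tau: float, col_accuracies: Sequence[float]
) -> list[int]:
    """Greedy redundancy elimination on |r| > tau; returns surviving column indices.

    While any remaining off-diagonal |r| exceeds ``tau``, drop the column with
    the largest mean |r| to the other survivors; ties go to the lower
    validation accuracy, then to the higher index.  Never empties the set.
    """
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    absR = np.abs(R.R)
    acc = np.asarray(col_accuracies, dtype=np.float64)
    if len(acc) != absR.shape[0]:
        raise ValueError("col_accuracies misaligned with R")
    alive = list(range(absR.shape[0]))
    while len(alive) > 1:
        sub = absR[np.ix_(alive, alive)]
        off = sub - np.eye(len(alive))
        if not (off > tau).any():
            break
        mean_r = (sub.sum(axis=1) - 1.0) / (len(alive) - 1)
        # drop: max mean |r|, then min accuracy, then max original index
        order = sorted(
            range(len(alive)),
            key=lambda j: (-mean_r[j], acc[alive[j]], -alive[j]),
        )
        alive.remove(alive[order[0]])
    return alive


@dataclass
class StackedModel:
    """Fitted stage-1 roster + kept meta-columns + fitted meta-classifier."""

    roster: list[BaseLearnerSpec]
    learners: list
    kept_indices: list[int]
    meta_spec: BaseLearnerSpec
    meta_learner: object
    tau: float
    hard_labels: bool = False

    @property
    def kept_names(self) -> list[str]:
        return [self.roster[j].name for j in self.kept_indices]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "roster": [{"name": s.name, "hyperparameters": s.hyperparameters, "seed": s.seed}
                       for s in self.roster],
            "meta_spec": {"name": self.meta_spec.name,
                          "hyperparameters": self.meta_spec.hyperparameters,
                          "seed": self.meta_spec.seed},
            "kept_indices": self.kept_indices,
            "tau": self.tau,
            "hard_labels": self.hard_labels,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2) + "\n")
        for spec, est in zip(self.roster, self.learners):
            joblib.dump(est, directory / f"base_{spec.name}.joblib")
        joblib.dump(self.meta_learner, directory / "meta.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "StackedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        roster = [BaseLearnerSpec(**s) for s in meta["roster"]]
        learners = [joblib.load(directory / f"base_{s.name}.joblib") for s in roster]
        return cls(
            roster=roster,
            learners=learners,
            kept_indices=list(meta["kept_indices"]),
            meta_spec=BaseLearnerSpec(**meta["meta_spec"]),
            meta_learner=joblib.load(directory / "meta.joblib"),
            tau=meta["tau"],
            hard_labels=meta["hard_labels"],
        )


def stratified_split(
    table: FeatureTable, test_fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Deterministic stratified train/test split of a labelled table."""
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    y = table.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for a stratified split")
    idx_train, idx_test = train_test_split(
        np.arange(len(table)), test_size=test_fraction, stratify=y, random_state=seed
    )
    df = table.df
    return (
        FeatureTable(df.iloc[np.sort(idx_train)].reset_index(drop=True)),
        FeatureTable(df.iloc[np.sort(idx_test)].reset_index(drop=True)),
    )


def _fit_stage1(
    X: np.ndarray, y: np.ndarray, roster: Sequence[BaseLearnerSpec], seed: int
) -> tuple[list, np.ndarray, np.ndarray]:
    """Split (X, y) into stratified halves, fit the roster on the first half.

    Returns (fitted learners, X of the held-out half, y of the held-out half).
    """
    idx_fit, idx_val = train_test_split(
        np.arange(len(y)), test_size=0.5, stratify=y, random_state=derive_seed(seed, 101)
    )
    fitted = []
    for spec in roster:
        est = build_learner(spec)
        try:
            est.fit(X[idx_fit], y[idx_fit])
        except Exception as exc:
            raise RuntimeError(f"base learner {spec.name} failed to fit: {exc}") from exc
        fitted.append(est)
    return fitted, X[idx_val], y[idx_val]


def _stage1_scores(
    fitted: Sequence, names: Sequence[str], X: np.ndarray, hard_labels: bool
) -> pd.DataFrame:
    cols = {}
    for name, est in zip(names, fitted):
        s = _positive_scores(est, X)
        cols[name] = (s >= 0.5).astype(np.float64) if hard_labels else s
    return pd.DataFrame(cols)


def stage1_stack(
    train: FeatureTable,
    test: FeatureTable,
    roster: Sequence[BaseLearnerSpec],
    seed: int,
    hard_labels: bool = False,
) -> tuple[MetaFeatureTable, MetaFeatureTable]:
    """Two-fold stage 1: fit on half the training data, score the other half and the test set."""
    if not roster:
        raise ValueError("roster must be non-empty")
    names = [s.name for s in roster]
    fitted, X_val, y_val = _fit_stage1(train.X, train.y, roster, seed)
    meta_train = MetaFeatureTable(_stage1_scores(fitted, names, X_val, hard_labels), labels=y_val)
    test_labels = test.y if test.df["label"].notna().all() else None
    meta_test = MetaFeatureTable(
        _stage1_scores(fitted, names, test.X, hard_labels), labels=test_labels
    )
    return meta_train, meta_test


def fit_meta(
    meta_train: MetaFeatureTable,
    kept_indices: Sequence[int],
    meta_spec: BaseLearnerSpec,
    roster: Optional[Sequence[BaseLearnerSpec]] = None,
    learners: Optional[Sequence] = None,
    tau: float = 0.95,
    hard_labels: bool = False,
) -> StackedModel:
    """Fit the stage-2 classifier on the kept meta-feature columns only."""
    kept = list(kept_indices)
    if not kept or any(j < 0 or j >= len(meta_train.columns) for j in kept):
        raise ValueError(f"invalid kept_indices {kept}")
    est = build_learner(meta_spec)
    X = meta_train.df.to_numpy(dtype=np.float64)[:, kept]
    est.fit(X, meta_train.labels)
    roster = list(roster) if roster is not None else [
        BaseLearnerSpec(n) for n in meta_train.columns
    ]
    return StackedModel(
        roster=roster,
        learners=list(learners) if learners is not None else [],
        kept_indices=kept,
        meta_spec=meta_spec,
        meta_learner=est,
        tau=tau,
        hard_labels=hard_labels,
    )


def predict(model: StackedModel, meta_test: MetaFeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Meta-classifier scores and 0.5-thresholded labels on a meta-feature table."""
    missing = [model.roster[j].name for j in model.kept_indices
               if model.roster[j].name not in meta_test.columns]
    if missing:
        raise ValueError(f"meta table lacks kept columns {missing}")
    X = meta_test.df[[model.roster[j].name for j in model.kept_indices]].to_numpy(np.float64)
    scores = _positive_scores(model.meta_learner, X)
    return (scores >= 0.5).astype(np.int64), scores


class StackedClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn-style facade over the full stack-prune-refit procedure.

    ``fit`` performs the internal two-fold stage 1, correlation pruning at
    ``tau`` and the stage-2 fit; ``predict`` recomputes base-learner scores on
    new data and feeds the kept columns to the meta-classifier.
    """

    def __init__(
        self,
        roster_names: Sequence[str] = ROSTER_NAMES,
        meta: str = "GB",
        tau: float = 0.95,
        seed: int = 0,
        hard_labels: bool = False,
    ) -> None:
        self.roster_names = tuple(roster_names)
        self.meta = meta
        self.tau = tau
        self.seed = seed
        self.hard_labels = hard_labels

    def fit(self, X, y) -> "StackedClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        roster = default_roster(self.seed, self.roster_names)
        fitted, X_val, y_val = _fit_stage1(X, y, roster, self.seed)
        meta_train = MetaFeatureTable(
            _stage1_scores(fitted, self.roster_names, X_val, self.hard_labels), labels=y_val
        )
        R = pearson_matrix(meta_train)
        kept = select_complementary(R, self.tau, meta_train.column_accuracies())
        meta_spec = BaseLearnerSpec(
            self.meta, seed=derive_seed(self.seed, 999)
        )
        self.model_ = fit_meta(
            meta_train, kept, meta_spec, roster=roster, learners=fitted,
            tau=self.tau, hard_labels=self.hard_labels,
        )
        self.correlation_ = R
        self.classes_ = np.array([0, 1])
        return self

    def _meta_table(self, X) -> MetaFeatureTable:
        X = np.asarray(X, dtype=np.float64)
        return MetaFeatureTable(
            _stage1_scores(self.model_.learners, self.roster_names, X, self.hard_labels)
        )

    def predict_proba(self, X) -> np.ndarray:
        _, scores = predict(self.model_, self._meta_table(X))
        return np.column_stack([1.0 - scores, scores])

    def predict(self, X) -> np.ndarray:
        labels, _ = predict(self.model_, self._meta_table(X))
        return labels
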