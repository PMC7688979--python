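"""Multi-centrality prediction of top spreaders with a polynomial-kernel SVM.

Nodes become records of centrality features with a binary label (1 iff the
node is in the true top-f by influence).  A second-degree polynomial SVM
with C tuned over [1, 100] by stratified 5-fold cross-validation is trained
on a random half of the nodes and scored on the rest by F1 and by the
precision function p(f); the whole procedure is repeated over random splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .centrality import CENTRALITY_NAMES
from .ranking import precision_function, quota

__all__ = [
    "NodeDataset",
    "ClassifierConfig",
    "ClassifyEval",
    "build_dataset",
    "train_classifier",
    "evaluate_classifier",
    "repeated_holdout_eval",
]

DEFAULT_C_GRID = (1.0, 3.0, 10.0, 30.0, 100.0)


@dataclass(frozen=True)
class NodeDataset:
    """Per-node feature matrix and binary top-spreader labels."""

    nodes: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self):
        if self.X.shape != (len(self.nodes), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")

    def subset(self, idx: np.ndarray) -> "NodeDataset":
        return NodeDataset(
            tuple(self.nodes[i] for i in idx),
            self.X[idx],
            self.y[idx],
            self.feature_names,
        )

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class ClassifierConfig:
    kernel_degree: int = 2
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    cv_folds: int = 5
    tol: float = 5e-4
    train_fraction: float = 0.5
    repeats: int = 100
    standardize: bool = True

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if any(not 1 <= c <= 100 for c in self.C_grid):
            raise ValueError("C grid must lie within [1, 100]")


@dataclass(frozen=True)
class ClassifyEval:
    f: float
    feature_names: tuple[str, ...]
    f1_scores: tuple[float, ...]
    p_scores: tuple[float, ...]

    @property
    def f1_mean(self) -> float:
        return float(np.mean(self.f1_scores))

    @property
    def p_mean(self) -> float:
        return float(np.mean(self.p_scores))


def build_dataset(
    table: pd.DataFrame,
    influence: Mapping[str, float] | pd.Series,
    f: float,
    features: Sequence[str] | None = None,
) -> NodeDataset:
    """Assemble features and top-f labels from a centrality table and an
    influence map.  Label ties at the top-f boundary break by node label.
    ``features`` defaults to every column of ``table``."""
    if features is None:
        features = list(table.columns)
    unknown = [c for c in features if c not in table.columns]
    if unknown:
        raise KeyError(f"unknown features: {unknown}")
    if isinstance(influence, pd.Series):
        influence = influence.to_dict()
    nodes = tuple(sorted(table.index.astype(str)))
    missing = [u for u in nodes if u not in influence]
    if missing:
        raise KeyError(f"influence missing for nodes: {missing[:5]}")
    k = quota(f, len(nodes))
    top = set(sorted(nodes, key=lambda u: (-influence[u], u))[:k])
    X = table.loc[list(nodes), list(features)].to_numpy(dtype=float)
    y = np.asarray([1 if u in top else 0 for u in nodes], dtype=np.int64)
    return NodeDataset(nodes, X, y, tuple(features))


class SingleClassError(ValueError):
    """Training data contains a single class; use a larger f or split."""


def _make_pipeline(cfg: ClassifierConfig, C: float) -> Pipeline:
    steps = []
    if cfg.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "svm",
            SVC(
                kernel="poly",
                degree=cfg.kernel_degree,
                coef0=1.0,  # inhomogeneous polynomial: include lower-order terms
                C=C,
                tol=cfg.tol,
                class_weight=None,
                cache_size=200,
            ),
        )
    )
    return Pipeline(steps)


def train_classifier(
    train: NodeDataset, cfg: ClassifierConfig, rng: np.random.Generator
) -> Pipeline:
    """Fit the SVM with C chosen from ``cfg.C_grid`` by stratified k-fold CV
    maximizing F1, then refit on the full training split.

    Falls back to the smallest C without CV when the minority class is too
    small to stratify into at least 2 folds.  The chosen C is recorded on the
    returned pipeline as ``chosen_C``.
    """
    classes, counts = np.unique(train.y, return_counts=True)
    if len(classes) < 2:
        raise SingleClassError(
            "training split has a single class; increase f or the training fraction"
        )
    folds = min(cfg.cv_folds, int(counts.min()))
    if folds >= 2 and len(cfg.C_grid) > 1:
        cv_seed = int(rng.integers(0, 2**31 - 1))
        best_C, best_score = None, -1.0
        for C in cfg.C_grid:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv_seed)
            scores = []
            for tr_idx, va_idx in skf.split(train.X, train.y):
                model = _make_pipeline(cfg, C)
                model.fit(train.X[tr_idx], train.y[tr_idx])
                pred = model.predict(train.X[va_idx])
                scores.append(f1_score(train.y[va_idx], pred, zero_division=0))
            score = float(np.mean(scores))
            if score > best_score:
                best_C, best_score = C, score
        chosen_C = best_C
    else:
        chosen_C = min(cfg.C_grid)
    model = _make_pipeline(cfg, chosen_C)
    model.fit(train.X, train.y)
    model.chosen_C = chosen_C
    return model


def evaluate_classifier(
    model: Pipeline, test: NodeDataset, influence: Mapping[str, float]
) -> tuple[float, float]:
    """Score predictions on a test split: (F1, precision function p).

    p compares the mean influence of predicted positives against the test
    split's true positives and is capped at 1.  An empty prediction scores
    (0, 0) by convention.
    """
    if test.n == 0:
        raise ValueError("test split is empty")
    pred = model.predict(test.X)
    pred_set = {u for u, yh in zip(test.nodes, pred) if yh == 1}
    true_set = {u for u, yt in zip(test.nodes, test.y) if yt == 1}
    if not pred_set:
        return 0.0, 0.0
    if not true_set:
        raise ValueError("test split has no true positives")
    tp = len(pred_set & true_set)
    recall = tp / len(true_set)
    precision = tp / len(pred_set)
    f1 = 0.0 if tp == 0 else 2 / (1 / recall + 1 / precision)
    p = precision_function(true_set, pred_set, influence)
    return f1, p


def repeated_holdout_eval(
    table: pd.DataFrame,
    influence: Mapping[str, float] | pd.Series,
    f: float,
    cfg: ClassifierConfig,
    rng: np.random.Generator,
    features: Sequence[str] | None = None,
) -> ClassifyEval:
    """Repeat {random train/test split, train, evaluate} ``cfg.repeats``
    times.  Splits with a single-class training half or a positive-free test
    half are redrawn (up to 10 times each)."""
    if cfg.repeats < 1:
        raise ValueError("repeats must be >= 1")
    data = build_dataset(table, influence, f, features)
    if isinstance(influence, pd.Series):
        influence = influence.to_dict()
    n_train = max(1, int(round(cfg.train_fraction * data.n)))
    f1s, ps = [], []
    for _ in range(cfg.repeats):
        for attempt in range(10):
            perm = rng.permutation(data.n)
            train = data.subset(perm[:n_train])
            test = data.subset(perm[n_train:])
            if len(np.unique(train.y)) == 2 and test.y.sum() > 0:
                break
        else:
            raise SingleClassError(
                "could not draw a usable train/test split in 10 attempts; "
                "increase f or the network size"
            )
        model = train_classifier(train, cfg, rng)
        f1, p = evaluate_classifier(model, test, influence)
        f1s.append(f1)
        ps.append(p)
    return ClassifyEval(
        f=f,
        feature_names=data.feature_names,
        f1_scores=tuple(f1s),
        p_scores=tuple(ps),
    )
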