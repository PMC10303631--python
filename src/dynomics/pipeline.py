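"""Nested stratified cross-validation for radiomic classification.

Outer folds estimate performance; inner folds select the gradient-boosted
tree hyperparameters (maximum tree depth, minimum child weight, per-tree
column subsample ratio) by mean inner-fold AUC.  Within every training set
the features are standardized and reduced by PCA truncated at the smallest
number of components whose cumulative explained variance reaches the
threshold (default 90%); test rows are always transformed with statistics
and loadings derived from the training rows only.  Metrics are computed on
the pooled out-of-fold predicted probabilities.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .temporal import DesignMatrix

__all__ = [
    "CvConfig", "Standardizer", "PcaModel", "FoldModel", "PerformanceReport",
    "standardize_fit_apply", "pca_reduce", "inner_search", "nested_cv",
    "compute_metrics", "roc_auc",
]

DEFAULT_GRID: dict[str, tuple] = {
    "max_tree_depth": (2, 3, 4, 6),
    "min_child_weight": (1, 3, 5),
    "column_subsample_ratio": (0.5, 0.75, 1.0),
}

_VAR_TOL = 1e-12


@dataclass
class CvConfig:
    outer_folds: int = 5
    inner_folds: int = 5
    seed: int = 0
    variance_threshold: float = 0.90
    grid: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_GRID))
    grouping: str = "none"  # "none" | "by_subject"
    n_estimators: int = 100
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0.0 < self.variance_threshold <= 1.0):
            raise ValueError("variance_threshold must be in (0, 1]")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be nonempty")
        if self.grouping not in ("none", "by_subject"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class Standardizer:
    mean: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray  # boolean flags of constant train columns

    def transform(self, x: np.ndarray) -> np.ndarray:
        out = (x - self.mean) / self.scale
        out[:, self.zero_variance] = 0.0
        return out


def standardize_fit_apply(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, Standardizer]:
    """Column-wise z-scoring fit on the training rows.

    Zero-variance training columns (e.g. shape features in MAD mode) map to
    exactly 0 in both sets and are flagged on the returned standardizer.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("train matrix needs >= 2 rows")
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    zero = std < _VAR_TOL
    scale = np.where(zero, 1.0, std)
    st = Standardizer(mean, scale, zero)
    return st.transform(train), (None if test is None else st.transform(test)), st


@dataclass
class PcaModel:
    loadings: np.ndarray          # (k, n_features) eigenvector rows
    eigenvalues: np.ndarray       # full spectrum
    explained_variance_ratio: np.ndarray  # full spectrum
    n_components: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) @ self.loadings.T

    center: np.ndarray = field(default_factory=lambda: np.zeros(1))


def pca_reduce(
    train: np.ndarray, test: np.ndarray | None, variance_threshold: float = 0.90
) -> tuple[np.ndarray, np.ndarray | None, PcaModel]:
    """PCA on standardized training rows, truncated at the smallest k whose
    cumulative explained variance ratio reaches the threshold."""
    train = np.asarray(train, dtype=float)
    if not np.any(np.abs(train) > 0):
        raise ValueError("degenerate all-zero matrix")
    full = PCA(n_components=None, svd_solver="full")
    full.fit(train)
    ratio = full.explained_variance_ratio_
    cum = np.cumsum(ratio)
    k = int(np.searchsorted(cum, variance_threshold - _VAR_TOL) + 1)
    k = min(k, len(ratio))
    model = PcaModel(
        loadings=full.components_[:k],
        eigenvalues=full.explained_variance_,
        explained_variance_ratio=ratio,
        n_components=k,
        center=full.mean_,
    )
    return model.transform(train), (
        None if test is None else model.transform(test)
    ), model


def _xgb_classifier(params: dict[str, Any], config: CvConfig, seed: int):
    return xgb.XGBClassifier(
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        max_depth=int(params["max_tree_depth"]),
        min_child_weight=params["min_child_weight"],
        colsample_bytree=params["column_subsample_ratio"],
        objective="binary:logistic",
        eval_metric="logloss",
        # exact splits fall mid-gap between consecutive training values,
        # which matters for the small-n matrices this pipeline sees
        tree_method="exact",
        n_jobs=1,
        random_state=seed % (2**31 - 1),
    )


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank statistic with tie correction."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _grid_points(grid: dict[str, tuple]) -> list[dict[str, Any]]:
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def _fit_transform_pipeline(x_tr, x_te, threshold):
    z_tr, z_te, st = standardize_fit_apply(x_tr, x_te)
    s_tr, s_te, pca = pca_reduce(z_tr, z_te, threshold)
    return s_tr, s_te, st, pca


def inner_search(
    x: np.ndarray, y: np.ndarray, config: CvConfig, seed: int
) -> tuple[dict[str, Any], float]:
    """Grid search scored by mean inner-fold AUC; ties break to the first
    point in grid order, so the selection is deterministic."""
    counts = np.bincount(y)
    if len(counts) < 2 or counts.min() == 0:
        raise ValueError("both classes required for the inner search")
    n_splits = min(config.inner_folds, int(counts.min()))
    if n_splits < 2:
        raise ValueError("a class is too small to stratify the inner folds")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=seed % (2**31 - 1))
    splits = list(skf.split(x, y))
    best: tuple[dict[str, Any], float] | None = None
    for params in _grid_points(config.grid):
        aucs = []
        for tr, te in splits:
            s_tr, s_te, _, _ = _fit_transform_pipeline(
                x[tr], x[te], config.variance_threshold)
            clf = _xgb_classifier(params, config, seed)
            clf.fit(s_tr, y[tr])
            aucs.append(roc_auc(y[te], clf.predict_proba(s_te)[:, 1]))
        score = float(np.nanmean(aucs))
        if best is None or score > best[1]:
            best = (params, score)
    return best


@dataclass
class FoldModel:
    fold: int
    standardizer: Standardizer
    pca: PcaModel
    classifier: Any
    best_params: dict[str, Any]
    inner_auc: float
    train_index: np.ndarray
    test_index: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.standardizer.transform(
            np.asarray(x, dtype=float)))


@dataclass
class PerformanceReport:
    auc: float
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    classes: tuple[str, str]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    sample_ids: list[str]
    per_fold: list[dict[str, Any]]

    def to_dict(self) -> dict[str, Any]:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "classes": list(self.classes),
            "per_fold": self.per_fold,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2),
                              encoding="utf-8")

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "label": [self.classes[i] for i in self.pooled_labels],
            "score": self.pooled_scores,
        })


def compute_metrics(
    labels: np.ndarray,
    scores: np.ndarray,
    classes: tuple[str, str],
    threshold: float = 0.5,
    sample_ids: list[str] | None = None,
    per_fold: list[dict[str, Any]] | None = None,
) -> PerformanceReport:
    """AUC (rank statistic), accuracy at the 0.5 threshold, and per-class
    precision/recall with each class in turn taken as positive."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    acc = float((pred == labels).mean())
    precision, recall = {}, {}
    for cls_idx, cls_name in enumerate(classes):
        tp = int(((pred == cls_idx) & (labels == cls_idx)).sum())
        fp = int(((pred == cls_idx) & (labels != cls_idx)).sum())
        fn = int(((pred != cls_idx) & (labels == cls_idx)).sum())
        precision[cls_name] = tp / (tp + fp) if tp + fp else 0.0
        recall[cls_name] = tp / (tp + fn) if tp + fn else 0.0
    return PerformanceReport(
        auc=roc_auc(labels, scores),
        accuracy=acc,
        precision=precision,
        recall=recall,
        classes=classes,
        pooled_scores=scores,
        pooled_labels=labels,
        sample_ids=sample_ids or [str(i) for i in range(len(labels))],
        per_fold=per_fold or [],
    )


def nested_cv(
    design: DesignMatrix,
    config: CvConfig | None = None,
    groups: np.ndarray | None = None,
) -> tuple[PerformanceReport, list[FoldModel]]:
    """Run the full nested cross-validation on a design matrix.

    ``groups`` (or ``config.grouping="by_subject"`` with sample ids of the
    form ``<subject>/<voi>``) keeps all rows of a subject in the same outer
    fold, preventing leakage in the tumor-vs-reference task.
    """
    config = config or CvConfig()
    x = design.X.to_numpy(dtype=float)
    classes = tuple(sorted(design.labels.unique()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y = (design.labels.to_numpy() == classes[1]).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.outer_folds:
        raise ValueError(
            f"class too small to stratify: {counts.min()} < {config.outer_folds}")

    if groups is None and config.grouping == "by_subject":
        groups = np.array([str(i).split("/")[0] for i in design.X.index])

    rs = config.seed % (2**31 - 1)
    if groups is not None:
        outer = StratifiedGroupKFold(n_splits=config.outer_folds, shuffle=True,
                                     random_state=rs)
        splits = list(outer.split(x, y, groups))
    else:
        outer = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                                random_state=rs)
        splits = list(outer.split(x, y))

    n = len(y)
    pooled = np.full(n, np.nan)
    fold_models: list[FoldModel] = []
    per_fold = []
    for f, (tr, te) in enumerate(splits):
        fold_seed = rs + 1000 * (f + 1)
        params, inner_auc = inner_search(x[tr], y[tr], config, fold_seed)
        z_tr, z_te, st = standardize_fit_apply(x[tr], x[te])
        s_tr, s_te, pca = pca_reduce(z_tr, z_te, config.variance_threshold)
        clf = _xgb_classifier(params, config, fold_seed)
        clf.fit(s_tr, y[tr])
        scores = clf.predict_proba(s_te)[:, 1]
        pooled[te] = scores
        fold_models.append(FoldModel(f, st, pca, clf, params, inner_auc,
                                     tr, te))
        per_fold.append({
            "fold": f,
            "n_components": pca.n_components,
            "cumulative_evr": float(
                pca.explained_variance_ratio[:pca.n_components].sum()),
            "best_params": params,
            "inner_auc": inner_auc,
            "auc": roc_auc(y[te], scores),
            "accuracy": float(((scores >= 0.5).astype(int) == y[te]).mean()),
        })
    if np.isnan(pooled).any():
        raise RuntimeError("outer folds did not cover every sample")
    report = compute_metrics(y, pooled, classes,
                             sample_ids=[str(i) for i in design.X.index],
                             per_fold=per_fold)
    return report, fold_models
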