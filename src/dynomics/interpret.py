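"""Shapley-value attribution of principal components and the mapping of the
top component back to its highest-loading original features.

Per-component Shapley values are exact tree-path (TreeSHAP) contributions,
computed by the boosted-tree library on each outer-fold model over that
fold's held-out rows, then aggregated as the mean absolute value per
component across samples and folds.  For the loading table a single
whole-dataset standardize+PCA is computed (interpretation only — never used
for performance estimates), with the sign convention that each component's
largest-|loading| entry is positive so reruns are comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .pipeline import FoldModel, pca_reduce, standardize_fit_apply
from .temporal import DesignMatrix

__all__ = [
    "AttributionReport", "shapley_attribution", "top_loadings",
    "shap_values_for_fold", "whole_dataset_pca", "fix_loading_signs",
]


def shap_values_for_fold(model: FoldModel, x_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-component Shapley values (and margin predictions) of one
    fitted fold model on raw-feature rows.

    Returns ``(contribs, margins)`` where ``contribs`` has one column per
    principal component plus a final bias column, and rows sum to the margin
    (log-odds) prediction — the additivity property of Shapley values.
    """
    scores = model.transform(x_raw)
    booster = model.classifier.get_booster()
    dm = xgb.DMatrix(scores)
    contribs = booster.predict(dm, pred_contribs=True)
    margins = booster.predict(dm, output_margin=True)
    if contribs.shape[1] != scores.shape[1] + 1:
        raise ValueError("component/contribution dimension mismatch")
    return contribs, margins


def fix_loading_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| entry is positive."""
    out = loadings.copy()
    for r in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[r])))
        if out[r, j] < 0:
            out[r] = -out[r]
    return out


def whole_dataset_pca(design: DesignMatrix, variance_threshold: float = 0.90):
    """Standardize + PCA on the full design matrix (loading table only)."""
    z, _, _ = standardize_fit_apply(design.X.to_numpy(dtype=float))
    _, _, pca = pca_reduce(z, None, variance_threshold)
    pca.loadings = fix_loading_signs(pca.loadings)
    return pca


@dataclass
class AttributionReport:
    """Mean |Shapley| per principal component, the descending component
    ranking, and the top component's highest-loading original features."""

    mean_abs_shap: list[float]
    ranking: list[int]               # component indices, descending importance
    top_component: int
    top_features: list[tuple[str, float]]  # (feature name, signed loading)
    top_component_evr: float

    def to_dict(self) -> dict:
        return {
            "mean_abs_shap": self.mean_abs_shap,
            "ranking": [f"PC{c + 1}" for c in self.ranking],
            "top_component": f"PC{self.top_component + 1}",
            "top_component_explained_variance": self.top_component_evr,
            "top_features": [
                {"feature": n, "loading": v} for n, v in self.top_features
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2),
                              encoding="utf-8")

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.top_features, columns=["feature", "loading"])


def shapley_attribution(
    fold_models: list[FoldModel],
    design: DesignMatrix,
    top_k: int = 5,
    variance_threshold: float = 0.90,
) -> AttributionReport:
    """Aggregate exact TreeSHAP attributions of all outer-fold models on
    their own held-out rows, rank components by mean |Shapley| value, and map
    the top component to its ``top_k`` highest-loading original features via
    a whole-dataset PCA."""
    if not fold_models:
        raise ValueError("no fold models")
    x = design.X.to_numpy(dtype=float)
    max_k = max(m.pca.n_components for m in fold_models)
    sums = np.zeros(max_k)
    counts = np.zeros(max_k)
    for m in fold_models:
        contribs, _ = shap_values_for_fold(m, x[m.test_index])
        k = m.pca.n_components
        sums[:k] += np.abs(contribs[:, :k]).sum(axis=0)
        counts[:k] += contribs.shape[0]
    mean_abs = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    ranking = list(np.argsort(-mean_abs, kind="stable"))
    top = int(ranking[0])

    pca = whole_dataset_pca(design, variance_threshold)
    comp = min(top, pca.n_components - 1)  # whole-data PCA may retain fewer
    features = top_loadings(pca.loadings, comp, top_k,
                            feature_names=list(design.X.columns))
    return AttributionReport(
        mean_abs_shap=[float(v) for v in mean_abs],
        ranking=[int(c) for c in ranking],
        top_component=top,
        top_features=features,
        top_component_evr=float(pca.explained_variance_ratio[comp])
        if comp < len(pca.explained_variance_ratio) else 0.0,
    )


def top_loadings(
    loadings: np.ndarray,
    component: int,
    k: int = 5,
    feature_names: list[str] | None = None,
) -> list[tuple[str, float]]:
    """The ``k`` original features with the largest |loading| on a component,
    sorted descending, with signed loading values."""
    if not (0 <= component < loadings.shape[0]):
        raise ValueError(f"component {component} out of range")
    row = loadings[component]
    if k > row.size:
        raise ValueError(f"k={k} exceeds feature count {row.size}")
    names = feature_names or [f"f{j}" for j in range(row.size)]
    order = np.argsort(-np.abs(row), kind="stable")[:k]
    return [(names[j], float(row[j])) for j in order]


def save_importance_plot(report: AttributionReport, path: str | Path) -> None:
    """Bar plot of mean |Shapley| per component (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = report.mean_abs_shap
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar([f"PC{i + 1}" for i in range(len(vals))], vals)
    ax.set_ylabel("mean |SHAP value|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
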