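"""Shapley attribution and PCA loading interpretation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from dynomics.interpret import (
    fix_loading_signs,
    shap_values_for_fold,
    shapley_attribution,
    top_loadings,
    whole_dataset_pca,
)
from dynomics.pipeline import CvConfig, FoldModel, PcaModel, Standardizer, nested_cv
from dynomics.temporal import DesignMatrix


# ---------------------------------------------------------------- oracle

def _tree_tables(booster):
    df = booster.trees_to_dataframe()
    return [g.set_index("ID") for _, g in df.groupby("Tree")]


def _expected_value(tree, node_id, x, subset):
    """Cover-weighted conditional expectation of one tree given that only
    the features in ``subset`` are known (tree-path-dependent semantics)."""
    row = tree.loc[node_id]
    if row["Feature"] == "Leaf":
        return row["Gain"]  # leaf value is stored in the Gain column
    feat = int(row["Feature"].lstrip("f"))
    if feat in subset:
        branch = row["Yes"] if x[feat] < row["Split"] else row["No"]
        return _expected_value(tree, branch, x, subset)
    cy = tree.loc[row["Yes"], "Cover"]
    cn = tree.loc[row["No"], "Cover"]
    vy = _expected_value(tree, row["Yes"], x, subset)
    vn = _expected_value(tree, row["No"], x, subset)
    return (cy * vy + cn * vn) / (cy + cn)


def shapley_oracle(booster, x, n_features):
    """Exact Shapley values by enumerating all 2^n feature subsets."""
    trees = _tree_tables(booster)

    def v(subset):
        return sum(_expected_value(t, t.index[0], x, subset) for t in trees)

    phi = np.zeros(n_features)
    feats = list(range(n_features))
    for i in feats:
        rest = [f for f in feats if f != i]
        for r in range(len(rest) + 1):
            for s in itertools.combinations(rest, r):
                w = (math.factorial(len(s))
                     * math.factorial(n_features - len(s) - 1)
                     / math.factorial(n_features))
                phi[i] += w * (v(set(s) | {i}) - v(set(s)))
    return phi, v(set())


def _fit_booster(x, y, n_estimators=8, max_depth=2, seed=0):
    clf = xgb.XGBClassifier(n_estimators=n_estimators, max_depth=max_depth,
                            learning_rate=0.3, objective="binary:logistic",
                            tree_method="exact", base_score=0.5,
                            n_jobs=1, random_state=seed)
    clf.fit(x, y)
    return clf


def _identity_fold(clf, k, test_index):
    """FoldModel whose transform is the identity on k columns."""
    st = Standardizer(np.zeros(k), np.ones(k), np.zeros(k, bool))
    pca = PcaModel(np.eye(k), np.ones(k), np.full(k, 1.0 / k), k,
                   center=np.zeros(k))
    return FoldModel(0, st, pca, clf, {}, 1.0, np.array([]), test_index)


class TestTreeShapley:
    def test_matches_subset_enumeration_oracle(self, rng):
        x = rng.normal(size=(60, 3))
        y = ((x[:, 0] + 0.5 * x[:, 1] > 0)).astype(int)
        clf = _fit_booster(x, y)
        fold = _identity_fold(clf, 3, np.arange(5))
        contribs, margins = shap_values_for_fold(fold, x[:5])
        for i in range(5):
            phi, base = shapley_oracle(clf.get_booster(), x[i], 3)
            np.testing.assert_allclose(contribs[i, :3], phi, atol=1e-4)
            assert contribs[i, 3] == pytest.approx(base, abs=1e-4)
            assert margins[i] == pytest.approx(phi.sum() + base, abs=1e-4)

    def test_single_stump_two_leaf_closed_form(self, rng):
        # one depth-1 tree on one feature: phi = leaf(x) - cover-weighted
        # mean leaf, and the bias is that mean
        x = rng.normal(size=(40, 1))
        y = (x[:, 0] > 0).astype(int)
        clf = _fit_booster(x, y, n_estimators=1, max_depth=1)
        tree = _tree_tables(clf.get_booster())[0]
        leaves = tree[tree["Feature"] == "Leaf"]
        mean_leaf = float((leaves["Gain"] * leaves["Cover"]).sum()
                          / leaves["Cover"].sum())
        fold = _identity_fold(clf, 1, np.arange(len(x)))
        contribs, _ = shap_values_for_fold(fold, x)
        split = float(tree.iloc[0]["Split"])
        leaf_lo = float(tree.loc[tree.iloc[0]["Yes"], "Gain"])
        leaf_hi = float(tree.loc[tree.iloc[0]["No"], "Gain"])
        for xi, c in zip(x[:, 0], contribs):
            leaf = leaf_lo if xi < split else leaf_hi
            assert c[0] == pytest.approx(leaf - mean_leaf, abs=1e-5)
            assert c[1] == pytest.approx(mean_leaf, abs=1e-5)

    def test_unused_features_get_zero_attribution(self, rng):
        x = rng.normal(size=(80, 4))
        y = (x[:, 0] > 0).astype(int)  # only feature 0 is informative
        clf = _fit_booster(x, y, n_estimators=5, max_depth=1)
        used = {f for d in clf.get_booster().get_dump() for f in ("f1", "f2", "f3")
                if f in d}
        assert not used  # stumps split feature 0 only
        fold = _identity_fold(clf, 4, np.arange(10))
        contribs, _ = shap_values_for_fold(fold, x[:10])
        np.testing.assert_allclose(contribs[:, 1:4], 0.0, atol=1e-12)

    def test_additivity_on_random_model(self, rng):
        x = rng.normal(size=(50, 6))
        y = rng.integers(0, 2, size=50)
        clf = _fit_booster(x, y, n_estimators=20, max_depth=3)
        fold = _identity_fold(clf, 6, np.arange(50))
        contribs, margins = shap_values_for_fold(fold, x)
        np.testing.assert_allclose(contribs.sum(axis=1), margins, atol=1e-4)


class TestTopLoadings:
    def test_sorted_by_absolute_value_with_signs(self):
        loadings = np.array([[0.9, -0.5, 0.1]])
        out = top_loadings(loadings, 0, k=2, feature_names=["a", "b", "c"])
        assert out == [("a", pytest.approx(0.9)), ("b", pytest.approx(-0.5))]

    def test_identity_matrix(self):
        out = top_loadings(np.eye(4), 2, k=1)
        assert out[0][0] == "f2"

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            top_loadings(np.eye(3), 0, k=4)
        with pytest.raises(ValueError):
            top_loadings(np.eye(3), 5, k=1)

    def test_sign_convention_largest_entry_positive(self):
        l = np.array([[-0.8, 0.3], [0.2, 0.6]])
        fixed = fix_loading_signs(l)
        np.testing.assert_allclose(fixed[0], [0.8, -0.3])
        np.testing.assert_allclose(fixed[1], [0.2, 0.6])

    def test_rank_one_factor_model_recovers_generator(self, rng):
        gen = np.array([0.1, 0.9, 0.3, 0.05, 0.2])
        x = rng.normal(size=(100, 1)) @ gen[None, :]
        x += rng.normal(scale=0.01, size=x.shape)
        X = pd.DataFrame(x, columns=[f"v{j}" for j in range(5)],
                         index=[f"s{i}" for i in range(100)])
        d = DesignMatrix(X, pd.Series(["a"] * 50 + ["b"] * 50, index=X.index),
                         "static")
        pca = whole_dataset_pca(d)
        out = top_loadings(pca.loadings, 0, k=1,
                           feature_names=list(X.columns))
        assert out[0][0] == "v1"
        assert out[0][1] > 0


class TestAttributionReport:
    def test_end_to_end_ranking_and_top_features(self, rng):
        n, m = 60, 10
        y = np.arange(n) % 2
        x = rng.normal(scale=0.05, size=(n, m)) + y[:, None]
        X = pd.DataFrame(x, index=[f"s{i:03d}/l" for i in range(n)],
                         columns=[f"feat{j}" for j in range(m)])
        d = DesignMatrix(X, pd.Series(np.where(y, "b", "a"), index=X.index),
                         "static")
        cfg = CvConfig(seed=2, grid={"max_tree_depth": (2,),
                                     "min_child_weight": (1,),
                                     "column_subsample_ratio": (1.0,)})
        report, models = nested_cv(d, cfg)
        att = shapley_attribution(models, d, top_k=5)
        assert att.ranking[0] == att.top_component
        assert len(att.top_features) == 5
        ranked = [att.mean_abs_shap[c] for c in att.ranking]
        assert ranked == sorted(ranked, reverse=True)
        # the class axis is PC1, so it must dominate the attribution
        assert att.top_component == 0
        d2 = att.to_dict()
        assert d2["top_component"] == "PC1"
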