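"""Gray-level dependence matrix (GLDM) features.

The dependence of a voxel is the number of its in-mask 26-neighbours whose
gray level differs from the center level by at most alpha (default 0).
P(g, d) counts voxels of level g with dependence d; feature formulas weight
by the dependence *size* j = d + 1 (the center voxel counts itself), so an
isolated voxel occupies the j = 1 column and all features stay finite.
"""

from __future__ import annotations

import numpy as np

from ._directions import ALL_NEIGHBOR_OFFSETS, shifted_views
from .discretize import QuantizedVoi

GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def gldm_matrix(qvoi: QuantizedVoi, alpha: float = 0.0) -> np.ndarray:
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    lv, mask = qvoi.levels, qvoi.mask
    dep = np.zeros(lv.shape, dtype=np.int64)
    for d in ALL_NEIGHBOR_OFFSETS:
        if any(abs(k) >= s for k, s in zip(d, lv.shape)):
            continue
        ca, cb = shifted_views(lv, d)
        ma, mb = shifted_views(mask, d)
        dca, _ = shifted_views(dep, d)
        hit = ma & mb & (np.abs(ca - cb) <= alpha)
        dca += hit
    g = lv[mask] - 1
    dvals = dep[mask]
    p = np.zeros((qvoi.ng, int(dvals.max()) + 1))
    np.add.at(p, (g, dvals), 1.0)
    return p


def _features(pmat: np.ndarray) -> dict[str, float]:
    ng, nd = pmat.shape
    nz_count = pmat.sum()
    p = pmat / nz_count
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nd + 1, dtype=float)  # dependence size = count + 1
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_g = float((pg * i).sum())
    mu_d = float((pd * j).sum())
    nz = p > 0
    ii, jj = np.meshgrid(i, j, indexing="ij")
    return {
        "SmallDependenceEmphasis": float((pd / j**2).sum()),
        "LargeDependenceEmphasis": float((pd * j**2).sum()),
        "GrayLevelNonUniformity": float((pmat.sum(axis=1) ** 2).sum() / nz_count),
        "DependenceNonUniformity": float((pmat.sum(axis=0) ** 2).sum() / nz_count),
        "DependenceNonUniformityNormalized": float((pd**2).sum()),
        "GrayLevelVariance": float((pg * (i - mu_g) ** 2).sum()),
        "DependenceVariance": float((pd * (j - mu_d) ** 2).sum()),
        "DependenceEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelEmphasis": float((pg / i**2).sum()),
        "HighGrayLevelEmphasis": float((pg * i**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (ii**2 * jj**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * ii**2 / jj**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * jj**2 / ii**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * ii**2 * jj**2).sum()),
    }


def gldm_features(qvoi: QuantizedVoi, alpha: float = 0.0) -> dict[str, float]:
    return _features(gldm_matrix(qvoi, alpha))
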