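"""Gray-level run-length matrix (GLRLM) features.

A run is a maximal set of consecutive in-mask voxels with identical gray
level along one of the 13 unique 3D directions.  One matrix P(g, r) is built
per direction; the 16 features are evaluated per direction and averaged.
Out-of-mask voxels break runs.
"""

from __future__ import annotations

import numpy as np

from ._directions import UNIQUE_DIRECTIONS
from .discretize import QuantizedVoi

GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def _runs_along(coords: np.ndarray, levels: np.ndarray,
                d: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Gray level and length of every run along direction d.

    Voxels on the same line share the invariant u = k*coord - t*d where
    t = coord . d and k = d . d; sorting by (u, t) makes runs contiguous.
    """
    dvec = np.array(d)
    k = int(dvec @ dvec)
    t = coords @ dvec
    u = k * coords - np.outer(t, dvec)
    # lexicographic sort by line id then position
    order = np.lexsort((t, u[:, 2], u[:, 1], u[:, 0]))
    t_s = t[order]
    u_s = u[order]
    lv_s = levels[order]
    new_run = np.ones(len(t_s), dtype=bool)
    if len(t_s) > 1:
        same_line = np.all(u_s[1:] == u_s[:-1], axis=1)
        contiguous = (t_s[1:] - t_s[:-1]) == k
        same_level = lv_s[1:] == lv_s[:-1]
        new_run[1:] = ~(same_line & contiguous & same_level)
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, len(t_s)))
    return lv_s[starts], lengths


def glrlm_matrices(qvoi: QuantizedVoi) -> list[np.ndarray]:
    coords = np.argwhere(qvoi.mask)
    levels = qvoi.levels[qvoi.mask]
    ng = qvoi.ng
    mats = []
    for d in UNIQUE_DIRECTIONS:
        g, r = _runs_along(coords, levels, d)
        nr_max = int(r.max())
        p = np.zeros((ng, nr_max))
        np.add.at(p, (g - 1, r - 1), 1.0)
        mats.append(p)
    return mats


def _features_one(pmat: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, nr_len = pmat.shape
    nr = pmat.sum()
    p = pmat / nr
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nr_len + 1, dtype=float)
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    mu_g = float((pg * i).sum())
    mu_r = float((pr * j).sum())
    nz = p > 0
    ii, jj = np.meshgrid(i, j, indexing="ij")
    return {
        "ShortRunEmphasis": float((pr / j**2).sum()),
        "LongRunEmphasis": float((pr * j**2).sum()),
        "GrayLevelNonUniformity": float((pmat.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "RunLengthNonUniformity": float((pmat.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pr**2).sum()),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((pg * (i - mu_g) ** 2).sum()),
        "RunVariance": float((pr * (j - mu_r) ** 2).sum()),
        "RunEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelRunEmphasis": float((pg / i**2).sum()),
        "HighGrayLevelRunEmphasis": float((pg * i**2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((p / (ii**2 * jj**2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((p * ii**2 / jj**2).sum()),
        "LongRunLowGrayLevelEmphasis": float((p * jj**2 / ii**2).sum()),
        "LongRunHighGrayLevelEmphasis": float((p * ii**2 * jj**2).sum()),
    }


def glrlm_features(qvoi: QuantizedVoi) -> dict[str, float]:
    n = qvoi.n_voxels
    per_dir = [_features_one(p, n) for p in glrlm_matrices(qvoi)]
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_FEATURES
    }
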