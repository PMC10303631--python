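"""Gray-level co-occurrence matrix (GLCM) features.

Co-occurrence is counted between in-mask voxel pairs at the given Chebyshev
distance along each of the 13 unique 3D directions; each directional matrix
is symmetrized and normalized, the 24 features are evaluated per direction
and averaged over directions.  Directions with no valid voxel pair are
skipped; if no direction has a pair (single-voxel VOI) the degenerate
single-level matrix P = [[1]] is used, which yields the documented
conventions (Contrast 0, JointEnergy 1, Correlation 1, ...).

Logs are base 2 with 0*log(0) = 0.
"""

from __future__ import annotations

import numpy as np

from ._directions import UNIQUE_DIRECTIONS, shifted_views
from .discretize import QuantizedVoi

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "MCC", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)

_EPS = 1e-30


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_matrices(qvoi: QuantizedVoi, distance: int = 1) -> list[np.ndarray]:
    """Symmetric, normalized co-occurrence matrices, one per direction with
    at least one in-mask pair."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    ng = qvoi.ng
    lv, mask = qvoi.levels, qvoi.mask
    mats = []
    for d in UNIQUE_DIRECTIONS:
        dd = tuple(distance * k for k in d)
        if any(abs(k) >= s for k, s in zip(dd, lv.shape)):
            continue
        ca, cb = shifted_views(lv, dd)
        ma, mb = shifted_views(mask, dd)
        valid = ma & mb
        a = ca[valid] - 1
        b = cb[valid] - 1
        if a.size == 0:
            continue
        p = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
        p = p + p.T
        mats.append(p / p.sum())
    if not mats:
        mats = [np.ones((1, 1))]
    return mats


def _features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((px * i).sum())
    uy = float((py * i).sum())
    sigx2 = float((px * (i - ux) ** 2).sum())
    sigy2 = float((py * (i - uy) ** 2).sum())

    # diagonal (|i-j|) and cross-diagonal (i+j) distributions
    k_diff = np.arange(ng, dtype=float)                      # 0 .. Ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)            # 2 .. 2Ng
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, p)

    diff_avg = float((p_diff * k_diff).sum())
    hxy = float(-_xlog2(p).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxpy = np.outer(px, py)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(np.maximum(pxpy[nz], _EPS))).sum())
    hxy2 = float(-_xlog2(pxpy).sum())

    div = max(hx, hy)
    imc1 = (hxy - hxy1) / div if div > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sigx2 > 1e-20 and sigy2 > 1e-20:
        corr = float(((p * ii * jj).sum() - ux * uy) / np.sqrt(sigx2 * sigy2))
    else:
        corr = 1.0

    # MCC: second-largest eigenvalue of Q over the observed gray levels
    obs = px > 0
    if obs.sum() >= 2:
        psub = p[np.ix_(obs, obs)]
        pxs = px[obs]
        pys = py[obs]
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
        q = (psub / pxs[:, None]) @ (psub / pys[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, min(1.0, eig[-2]))))
    else:
        mcc = 1.0

    offdiag = np.abs(ii - jj) > 0
    inv_var = float((p[offdiag] / (ii - jj)[offdiag] ** 2).sum())

    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "JointAverage": ux,
        "ClusterProminence": float((p * (ii + jj - ux - uy) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - ux - uy) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - ux - uy) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-_xlog2(p_diff).sum()),
        "DifferenceVariance": float((p_diff * (k_diff - diff_avg) ** 2).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "MCC": mcc,
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((p_sum * k_sum).sum()),
        "SumEntropy": float(-_xlog2(p_sum).sum()),
        "SumSquares": float((p * (ii - ux) ** 2).sum()),
    }


def glcm_features(qvoi: QuantizedVoi, distance: int = 1) -> dict[str, float]:
    per_dir = [_features_one(p) for p in glcm_matrices(qvoi, distance)]
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_FEATURES
    }
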