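"""Gray-level size-zone matrix (GLSZM) features.

A zone is a 26-connected component of in-mask voxels sharing one gray level;
P(g, s) counts zones of level g and size s.  A single merged matrix is used
(the zone concept has no direction).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import QuantizedVoi

GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(qvoi: QuantizedVoi) -> np.ndarray:
    ng = qvoi.ng
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, ng + 1):
        binary = qvoi.levels == g
        if not binary.any():
            continue
        labels, n_zones = ndimage.label(binary, structure=_STRUCT26)
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            zones.append((g, int(s)))
            max_size = max(max_size, int(s))
    p = np.zeros((ng, max_size))
    for g, s in zones:
        p[g - 1, s - 1] += 1.0
    return p


def _features(pmat: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, smax = pmat.shape
    nz_count = pmat.sum()
    p = pmat / nz_count
    i = np.arange(1, ng + 1, dtype=float)
    s = np.arange(1, smax + 1, dtype=float)
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((pg * i).sum())
    mu_s = float((ps * s).sum())
    nz = p > 0
    ii, ss = np.meshgrid(i, s, indexing="ij")
    return {
        "SmallAreaEmphasis": float((ps / s**2).sum()),
        "LargeAreaEmphasis": float((ps * s**2).sum()),
        "GrayLevelNonUniformity": float((pmat.sum(axis=1) ** 2).sum() / nz_count),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "SizeZoneNonUniformity": float((pmat.sum(axis=0) ** 2).sum() / nz_count),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum()),
        "ZonePercentage": float(nz_count / n_voxels),
        "GrayLevelVariance": float((pg * (i - mu_g) ** 2).sum()),
        "ZoneVariance": float((ps * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "LowGrayLevelZoneEmphasis": float((pg / i**2).sum()),
        "HighGrayLevelZoneEmphasis": float((pg * i**2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((p / (ii**2 * ss**2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((p * ii**2 / ss**2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((p * ss**2 / ii**2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((p * ii**2 * ss**2).sum()),
    }


def glszm_features(qvoi: QuantizedVoi) -> dict[str, float]:
    return _features(glszm_matrix(qvoi), qvoi.n_voxels)
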