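"""Neighbouring gray-tone difference matrix (NGTDM) features.

For every in-mask voxel with at least one in-mask 26-neighbour, the absolute
difference between its gray level and the mean level of those neighbours is
accumulated per level: s_i = sum |i - A_i|.  Features follow the standard
definitions with the degenerate conventions: Contrast = 0 when only one
level is present; Busyness and Strength = 0 when their denominators vanish;
Coarseness capped at 1e6 for fully homogeneous regions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import QuantizedVoi

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_KERNEL26 = np.ones((3, 3, 3))
_KERNEL26[1, 1, 1] = 0.0

COARSENESS_CAP = 1e6


def ngtdm_table(qvoi: QuantizedVoi) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level voxel counts n_i and difference sums s_i, plus the number of
    voxels that entered the tally (those with >= 1 in-mask neighbour)."""
    mask = qvoi.mask
    lv = qvoi.levels.astype(float)
    nb_sum = ndimage.convolve(lv * mask, _KERNEL26, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mask.astype(float), _KERNEL26, mode="constant",
                              cval=0.0)
    valid = mask & (nb_cnt > 0.5)
    levels = qvoi.levels[valid]
    diffs = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
    n_i = np.bincount(levels, minlength=qvoi.ng + 1)[1:].astype(float)
    s_i = np.zeros(qvoi.ng)
    np.add.at(s_i, levels - 1, diffs)
    return n_i, s_i, int(valid.sum())


def ngtdm_features(qvoi: QuantizedVoi) -> dict[str, float]:
    n_i, s_i, nvp = ngtdm_table(qvoi)
    ng = qvoi.ng
    i = np.arange(1, ng + 1, dtype=float)
    if nvp == 0:
        # single isolated voxel: no neighbourhood at all
        return {"Coarseness": COARSENESS_CAP, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())

    denom_coarse = float((p_i * s_i).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 1e-30 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        di_, dj_ = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float(
            (pi_ * pj_ * (di_ - dj_) ** 2).sum() / (ngp * (ngp - 1))
            * s_i.sum() / nvp
        )
        busy_den = float(np.abs(np.subtract.outer(
            (i * p_i)[present], (i * p_i)[present])).sum())
        busyness = denom_coarse / busy_den if busy_den > 1e-30 else 0.0
        si_, sj_ = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = float(
            (np.abs(di_ - dj_) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum()
            / nvp
        )
        s_sum = float(s_i.sum())
        strength = (
            float(((pi_ + pj_) * (di_ - dj_) ** 2).sum()) / s_sum
            if s_sum > 1e-30 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity,
            "Strength": strength}
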