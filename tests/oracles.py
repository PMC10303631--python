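"""Independent brute-force oracles for the texture feature families.

Everything here is written as plain per-voxel enumeration (explicit Python
loops, flood fills, neighbour walks) so it shares no code path with the
vectorized engine it checks.  Only usable at toy sizes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3)
           if d != (0, 0, 0) and d > (0, 0, 0)]
OFFS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _inb(idx, shape):
    return all(0 <= i < s for i, s in zip(idx, shape))


def _log2(x):
    return math.log2(x)


# ---------------------------------------------------------------- GLCM

def glcm_matrix_oracle(levels, mask, ng, d, distance=1):
    p = np.zeros((ng, ng))
    dd = tuple(distance * k for k in d)
    for idx in np.argwhere(mask):
        for sign in (1, -1):
            nb = tuple(idx + sign * np.array(dd))
            if _inb(nb, mask.shape) and mask[nb]:
                p[levels[tuple(idx)] - 1, levels[nb] - 1] += 1
    s = p.sum()
    return p / s if s else None


def glcm_features_oracle(levels, mask, ng, distance=1):
    mats = [glcm_matrix_oracle(levels, mask, ng, d, distance) for d in DIRS_13]
    mats = [m for m in mats if m is not None]
    if not mats:
        mats = [np.ones((1, 1))]
    per = [_glcm_one(m, m.shape[0]) for m in mats]
    return {k: float(np.mean([f[k] for f in per])) for k in per[0]}


def _glcm_one(p, ng):
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    ux = sum((i + 1) * px[i] for i in range(ng))
    uy = sum((j + 1) * py[j] for j in range(ng))
    sx2 = sum(px[i] * (i + 1 - ux) ** 2 for i in range(ng))
    sy2 = sum(py[j] * (j + 1 - uy) ** 2 for j in range(ng))
    pdiff = [0.0] * ng
    psum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            pdiff[abs(i - j)] += p[i][j]
            psum[i + j] += p[i][j]
    da = sum(k * pdiff[k] for k in range(ng))
    hxy = -sum(p[i][j] * _log2(p[i][j]) for i in range(ng) for j in range(ng)
               if p[i][j] > 0)
    hx = -sum(v * _log2(v) for v in px if v > 0)
    hy = -sum(v * _log2(v) for v in py if v > 0)
    hxy1 = -sum(p[i][j] * _log2(px[i] * py[j]) for i in range(ng)
                for j in range(ng) if p[i][j] > 0)
    hxy2 = -sum(px[i] * py[j] * _log2(px[i] * py[j]) for i in range(ng)
                for j in range(ng) if px[i] * py[j] > 0)
    div = max(hx, hy)
    autoc = sum(p[i][j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng))
    corr = ((autoc - ux * uy) / math.sqrt(sx2 * sy2)
            if sx2 > 1e-20 and sy2 > 1e-20 else 1.0)
    obs = [i for i in range(ng) if px[i] > 0]
    if len(obs) >= 2:
        q = np.zeros((len(obs), len(obs)))
        for a, i in enumerate(obs):
            for b, j in enumerate(obs):
                q[a, b] = sum(p[i][k] * p[j][k] / (px[i] * py[k])
                              for k in range(ng) if py[k] > 0)
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, min(1.0, eig[-2])))
    else:
        mcc = 1.0
    return {
        "Autocorrelation": autoc,
        "JointAverage": ux,
        "ClusterProminence": sum(p[i][j] * (i + j + 2 - ux - uy) ** 4
                                 for i in range(ng) for j in range(ng)),
        "ClusterShade": sum(p[i][j] * (i + j + 2 - ux - uy) ** 3
                            for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum(p[i][j] * (i + j + 2 - ux - uy) ** 2
                               for i in range(ng) for j in range(ng)),
        "Contrast": sum(p[i][j] * (i - j) ** 2 for i in range(ng)
                        for j in range(ng)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * _log2(v) for v in pdiff if v > 0),
        "DifferenceVariance": sum(pdiff[k] * (k - da) ** 2 for k in range(ng)),
        "JointEnergy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / div if div > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "Idm": sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng)
                   for j in range(ng)),
        "MCC": mcc,
        "Idmn": sum(p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng)
                    for j in range(ng)),
        "Id": sum(p[i][j] / (1 + abs(i - j)) for i in range(ng)
                  for j in range(ng)),
        "Idn": sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng)
                   for j in range(ng)),
        "InverseVariance": sum(p[i][j] / (i - j) ** 2 for i in range(ng)
                               for j in range(ng) if i != j),
        "MaximumProbability": max(p[i][j] for i in range(ng) for j in range(ng)),
        "SumAverage": sum(psum[k] * (k + 2) for k in range(2 * ng - 1)),
        "SumEntropy": -sum(v * _log2(v) for v in psum if v > 0),
        "SumSquares": sum(p[i][j] * (i + 1 - ux) ** 2 for i in range(ng)
                          for j in range(ng)),
    }


# ---------------------------------------------------------------- GLRLM

def glrlm_runs_oracle(levels, mask, d):
    """All (gray level, run length) runs along direction d, by walking."""
    runs = []
    shape = mask.shape
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        prev = tuple(np.array(idx) - np.array(d))
        # run start: predecessor out of bounds, out of mask, or other level
        if (_inb(prev, shape) and mask[prev]
                and levels[prev] == levels[idx]):
            continue
        length = 1
        cur = idx
        while True:
            nxt = tuple(np.array(cur) + np.array(d))
            if (_inb(nxt, shape) and mask[nxt]
                    and levels[nxt] == levels[idx]):
                length += 1
                cur = nxt
            else:
                break
        runs.append((levels[idx], length))
    return runs


def glrlm_features_oracle(levels, mask, ng):
    n_vox = int(mask.sum())
    per = []
    for d in DIRS_13:
        runs = glrlm_runs_oracle(levels, mask, d)
        rmax = max(r for _, r in runs)
        mat = np.zeros((ng, rmax))
        for g, r in runs:
            mat[g - 1, r - 1] += 1
        per.append(_run_zone_features(mat, n_vox, prefix="run"))
    return {k: float(np.mean([f[k] for f in per])) for k in per[0]}


def _run_zone_features(mat, n_vox, prefix):
    """Shared run/zone-style matrix features, computed by plain loops."""
    ng, smax = mat.shape
    total = mat.sum()
    p = mat / total
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = sum((i + 1) * pg[i] for i in range(ng))
    mu_s = sum((j + 1) * ps[j] for j in range(smax))
    feats = {
        "SmallEmphasis": sum(ps[j] / (j + 1) ** 2 for j in range(smax)),
        "LargeEmphasis": sum(ps[j] * (j + 1) ** 2 for j in range(smax)),
        "GrayLevelNonUniformity": sum(mat[i].sum() ** 2 for i in range(ng)) / total,
        "GrayLevelNonUniformityNormalized": sum(pg[i] ** 2 for i in range(ng)),
        "SizeNonUniformity": sum(mat[:, j].sum() ** 2 for j in range(smax)) / total,
        "SizeNonUniformityNormalized": sum(ps[j] ** 2 for j in range(smax)),
        "Percentage": total / n_vox,
        "GrayLevelVariance": sum(pg[i] * (i + 1 - mu_g) ** 2 for i in range(ng)),
        "SizeVariance": sum(ps[j] * (j + 1 - mu_s) ** 2 for j in range(smax)),
        "Entropy": -sum(p[i, j] * _log2(p[i, j]) for i in range(ng)
                        for j in range(smax) if p[i, j] > 0),
        "LowGrayLevelEmphasis": sum(pg[i] / (i + 1) ** 2 for i in range(ng)),
        "HighGrayLevelEmphasis": sum(pg[i] * (i + 1) ** 2 for i in range(ng)),
        "SmallLowGrayLevelEmphasis": sum(
            p[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
            for i in range(ng) for j in range(smax)),
        "SmallHighGrayLevelEmphasis": sum(
            p[i, j] * (i + 1) ** 2 / (j + 1) ** 2
            for i in range(ng) for j in range(smax)),
        "LargeLowGrayLevelEmphasis": sum(
            p[i, j] * (j + 1) ** 2 / (i + 1) ** 2
            for i in range(ng) for j in range(smax)),
        "LargeHighGrayLevelEmphasis": sum(
            p[i, j] * (i + 1) ** 2 * (j + 1) ** 2
            for i in range(ng) for j in range(smax)),
    }
    return feats


GLRLM_NAME_MAP = {
    "ShortRunEmphasis": "SmallEmphasis",
    "LongRunEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity": "SizeNonUniformity",
    "RunLengthNonUniformityNormalized": "SizeNonUniformityNormalized",
    "RunPercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "RunVariance": "SizeVariance",
    "RunEntropy": "Entropy",
    "LowGrayLevelRunEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelRunEmphasis": "HighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}

GLSZM_NAME_MAP = {
    "SmallAreaEmphasis": "SmallEmphasis",
    "LargeAreaEmphasis": "LargeEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity": "SizeNonUniformity",
    "SizeZoneNonUniformityNormalized": "SizeNonUniformityNormalized",
    "ZonePercentage": "Percentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "ZoneVariance": "SizeVariance",
    "ZoneEntropy": "Entropy",
    "LowGrayLevelZoneEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelZoneEmphasis": "HighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis": "SmallLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis": "SmallHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis": "LargeLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis": "LargeHighGrayLevelEmphasis",
}


# ---------------------------------------------------------------- GLSZM

def glszm_zones_oracle(levels, mask):
    """(level, size) of every 26-connected same-level zone, by flood fill."""
    visited = np.zeros(mask.shape, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        g = levels[start]
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in OFFS_26:
                nb = tuple(np.array(cur) + np.array(d))
                if (_inb(nb, mask.shape) and mask[nb] and not visited[nb]
                        and levels[nb] == g):
                    visited[nb] = True
                    stack.append(nb)
        zones.append((g, size))
    return zones


def glszm_features_oracle(levels, mask, ng):
    zones = glszm_zones_oracle(levels, mask)
    smax = max(s for _, s in zones)
    mat = np.zeros((ng, smax))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return _run_zone_features(mat, int(mask.sum()), prefix="zone")


# ---------------------------------------------------------------- NGTDM

def ngtdm_features_oracle(levels, mask, ng):
    n_i = [0.0] * ng
    s_i = [0.0] * ng
    nvp = 0
    for idx in map(tuple, np.argwhere(mask)):
        nbs = []
        for d in OFFS_26:
            nb = tuple(np.array(idx) + np.array(d))
            if _inb(nb, mask.shape) and mask[nb]:
                nbs.append(levels[nb])
        if not nbs:
            continue
        nvp += 1
        g = levels[idx]
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - sum(nbs) / len(nbs))
    if nvp == 0:
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p_i = [n / nvp for n in n_i]
    present = [i for i in range(ng) if p_i[i] > 0]
    ngp = len(present)
    denom = sum(p_i[i] * s_i[i] for i in range(ng))
    coarse = min(1.0 / denom if denom > 1e-30 else 1e6, 1e6)
    if ngp > 1:
        contrast = (sum(p_i[i] * p_i[j] * (i - j) ** 2
                        for i in present for j in present)
                    / (ngp * (ngp - 1)) * sum(s_i) / nvp)
        busy_den = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
                       for i in present for j in present)
        busy = denom / busy_den if busy_den > 1e-30 else 0.0
        complexity = sum(abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                         / (p_i[i] + p_i[j])
                         for i in present for j in present) / nvp
        ssum = sum(s_i)
        strength = (sum((p_i[i] + p_i[j]) * (i - j) ** 2
                        for i in present for j in present) / ssum
                    if ssum > 1e-30 else 0.0)
    else:
        contrast = busy = complexity = strength = 0.0
    return {"Coarseness": coarse, "Contrast": contrast, "Busyness": busy,
            "Complexity": complexity, "Strength": strength}


# ---------------------------------------------------------------- GLDM

def gldm_features_oracle(levels, mask, ng, alpha=0.0):
    deps = []
    for idx in map(tuple, np.argwhere(mask)):
        d_count = 0
        for d in OFFS_26:
            nb = tuple(np.array(idx) + np.array(d))
            if (_inb(nb, mask.shape) and mask[nb]
                    and abs(levels[nb] - levels[idx]) <= alpha):
                d_count += 1
        deps.append((levels[idx], d_count))
    dmax = max(d for _, d in deps)
    mat = np.zeros((ng, dmax + 1))
    for g, d in deps:
        mat[g - 1, d] += 1
    feats = _run_zone_features(mat, int(mask.sum()), prefix="dep")
    return {
        "SmallDependenceEmphasis": feats["SmallEmphasis"],
        "LargeDependenceEmphasis": feats["LargeEmphasis"],
        "GrayLevelNonUniformity": feats["GrayLevelNonUniformity"],
        "DependenceNonUniformity": feats["SizeNonUniformity"],
        "DependenceNonUniformityNormalized": feats["SizeNonUniformityNormalized"],
        "GrayLevelVariance": feats["GrayLevelVariance"],
        "DependenceVariance": feats["SizeVariance"],
        "DependenceEntropy": feats["Entropy"],
        "LowGrayLevelEmphasis": feats["LowGrayLevelEmphasis"],
        "HighGrayLevelEmphasis": feats["HighGrayLevelEmphasis"],
        "SmallDependenceLowGrayLevelEmphasis": feats["SmallLowGrayLevelEmphasis"],
        "SmallDependenceHighGrayLevelEmphasis": feats["SmallHighGrayLevelEmphasis"],
        "LargeDependenceLowGrayLevelEmphasis": feats["LargeLowGrayLevelEmphasis"],
        "LargeDependenceHighGrayLevelEmphasis": feats["LargeHighGrayLevelEmphasis"],
    }


# ---------------------------------------------------------------- first order

def first_order_oracle(values, levels, ng, voxel_volume):
    """18 first-order statistics by direct computation on a value list."""
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n

    def pct(q):
        # linear interpolation between order statistics
        h = (n - 1) * q / 100.0
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    p10, p25, p50, p75, p90 = (pct(q) for q in (10, 25, 50, 75, 90))
    counts = [0] * ng
    for g in levels:
        counts[g - 1] += 1
    probs = [c / n for c in counts if c > 0]
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    energy = sum(v * v for v in x)
    if var > 1e-30:
        skew = (sum((v - mean) ** 3 for v in x) / n) / var**1.5
        kurt = (sum((v - mean) ** 4 for v in x) / n) / var**2
    else:
        skew = kurt = 0.0
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": -sum(p * _log2(p) for p in probs),
        "Minimum": x[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": (
            sum(abs(v - rmean) for v in robust) / len(robust) if robust else 0.0),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": sum(p * p for p in probs),
    }
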