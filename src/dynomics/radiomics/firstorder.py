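"""First-order (intensity histogram) features.

All statistics are computed on the raw in-mask intensities except Entropy and
Uniformity, which operate on the discretized gray-level histogram (base-2
log, with the 0*log(0) = 0 convention).  Percentiles use linear interpolation
between order statistics.  Skewness and Kurtosis of a zero-variance region
are defined as 0; Kurtosis is the raw (non-excess) fourth standardized
moment, so a Gaussian region scores ~3.
"""

from __future__ import annotations

import numpy as np

from .discretize import QuantizedVoi

FIRSTORDER_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(data: np.ndarray, mask: np.ndarray, qvoi: QuantizedVoi,
                         voxel_volume_mm3: float) -> dict[str, float]:
    x = np.asarray(data, dtype=float)[np.asarray(mask, dtype=bool)]
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # histogram statistics on discretized levels
    counts = np.bincount(qvoi.masked_levels, minlength=qvoi.ng + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 1e-30:
        z = x - mean
        skew = float((z**3).mean() / var**1.5)
        kurt = float((z**4).mean() / var**2)
    else:
        skew = 0.0
        kurt = 0.0

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
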