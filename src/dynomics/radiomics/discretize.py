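"""Gray-level discretization of a VOI prior to texture-matrix computation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiscretizationScheme:
    """How in-mask intensities are binned into integer gray levels 1..Ng.

    ``fixed_bin_count`` rescales the in-mask range onto ``n_bins`` levels
    (robust to frame-to-frame SUV range changes, the package default);
    ``fixed_bin_width`` uses absolute-intensity bins of width ``bin_width``.
    """

    mode: str = "fixed_bin_count"
    n_bins: int = 32
    bin_width: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_bin_count" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.mode == "fixed_bin_width" and self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass
class QuantizedVoi:
    """Integer gray levels over a VOI.

    ``levels`` holds 1..Ng inside the mask and 0 outside; arrays may be the
    full grid or a cropped bounding box — all texture code is crop-agnostic.
    """

    levels: np.ndarray
    ng: int
    mask: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(data: np.ndarray, mask: np.ndarray,
               scheme: DiscretizationScheme | None = None,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> QuantizedVoi:
    """Quantize in-mask intensities to integer levels.

    fixed_bin_count: level = 1 + floor(Ng*(x-min)/(max-min)), clipped to Ng;
    a constant region maps to a single level (Ng = 1).
    fixed_bin_width: level = floor(x/w) - floor(min/w) + 1.
    """
    scheme = scheme or DiscretizationScheme()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(data, dtype=float)[mask]
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite in-mask intensities")
    levels = np.zeros(mask.shape, dtype=np.int64)
    mn, mx = float(x.min()), float(x.max())
    if scheme.mode == "fixed_bin_count":
        if mx == mn:
            lv = np.ones_like(x, dtype=np.int64)
            ng = 1
        else:
            ng = scheme.n_bins
            lv = 1 + np.floor(ng * (x - mn) / (mx - mn)).astype(np.int64)
            np.clip(lv, 1, ng, out=lv)
    else:
        w = scheme.bin_width
        lv = (np.floor(x / w) - np.floor(mn / w)).astype(np.int64) + 1
        ng = int(lv.max())
    levels[mask] = lv
    return QuantizedVoi(levels, ng, mask, tuple(spacing))


def crop_to_bbox(arrays: list[np.ndarray], mask: np.ndarray) -> list[np.ndarray]:
    """Crop arrays (and the mask, passed last by the caller) to the mask's
    bounding box — texture matrices only see in-mask voxels, so this is a
    pure speed optimization."""
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return [a[sl] for a in arrays]
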