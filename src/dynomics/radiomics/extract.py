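"""Full 107-feature extraction from one 3D volume + VOI mask.

The canonical roster is 18 first-order + 14 shape(3D) + 24 GLCM + 16 GLRLM
+ 16 GLSZM + 5 NGTDM + 14 GLDM = 107 features, named ``family/Feature``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..types import Volume3D, VoiMask
from .discretize import DiscretizationScheme, crop_to_bbox, discretize
from .firstorder import FIRSTORDER_FEATURES, first_order_features
from .gldm import GLDM_FEATURES, gldm_features
from .glcm import GLCM_FEATURES, glcm_features
from .glrlm import GLRLM_FEATURES, glrlm_features
from .glszm import GLSZM_FEATURES, glszm_features
from .ngtdm import NGTDM_FEATURES, ngtdm_features
from .shape import SHAPE_FEATURES, shape3d_features

FAMILIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("firstorder", FIRSTORDER_FEATURES),
    ("shape", SHAPE_FEATURES),
    ("glcm", GLCM_FEATURES),
    ("glrlm", GLRLM_FEATURES),
    ("glszm", GLSZM_FEATURES),
    ("ngtdm", NGTDM_FEATURES),
    ("gldm", GLDM_FEATURES),
)

#: canonical ordered names of all 107 features
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{fam}/{name}" for fam, names in FAMILIES for name in names
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 107

#: names of features that depend only on the mask, not the intensities
SHAPE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"shape/{name}" for name in SHAPE_FEATURES
)


@dataclass(frozen=True)
class ExtractionSettings:
    """Texture-family knobs: GLCM pair distance (voxels) and GLDM dependence
    tolerance alpha (gray levels)."""

    glcm_distance: int = 1
    gldm_alpha: float = 0.0


def extract_all(
    volume: Volume3D | np.ndarray,
    mask: VoiMask | np.ndarray,
    scheme: DiscretizationScheme | None = None,
    settings: ExtractionSettings | None = None,
    spacing: tuple[float, float, float] | None = None,
    _shape_values: dict[str, float] | None = None,
) -> pd.Series:
    """All 107 features of one VOI on one 3D image, in canonical order.

    ``_shape_values`` lets callers that extract many frames over a fixed mask
    reuse the (intensity-independent) shape block.
    """
    if isinstance(volume, Volume3D):
        data = volume.data
        spacing = volume.spacing
    else:
        data = np.asarray(volume, dtype=float)
        if spacing is None:
            spacing = (1.0, 1.0, 1.0)
    mdata = mask.data if isinstance(mask, VoiMask) else np.asarray(mask, dtype=bool)
    if mdata.shape != data.shape:
        raise ValueError("volume and mask grids differ")
    scheme = scheme or DiscretizationScheme()
    settings = settings or ExtractionSettings()

    cdata, cmask = crop_to_bbox([data, mdata], mdata)
    qvoi = discretize(cdata, cmask, scheme, spacing)
    voxvol = float(np.prod(spacing))

    values: dict[str, float] = {}
    blocks = {
        "firstorder": lambda: first_order_features(cdata, cmask, qvoi, voxvol),
        "shape": lambda: (_shape_values if _shape_values is not None
                          else shape3d_features(mdata, spacing)),
        "glcm": lambda: glcm_features(qvoi, settings.glcm_distance),
        "glrlm": lambda: glrlm_features(qvoi),
        "glszm": lambda: glszm_features(qvoi),
        "ngtdm": lambda: ngtdm_features(qvoi),
        "gldm": lambda: gldm_features(qvoi, settings.gldm_alpha),
    }
    for fam, names in FAMILIES:
        try:
            block = blocks[fam]()
        except Exception as exc:  # add family context, re-raise
            raise RuntimeError(f"feature family {fam!r} failed: {exc}") from exc
        for name in names:
            values[f"{fam}/{name}"] = float(block[name])

    vec = pd.Series(values, index=list(FEATURE_NAMES), dtype=float)
    if not np.all(np.isfinite(vec.to_numpy())):
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise RuntimeError(f"non-finite features: {bad}")
    return vec


def write_feature_csv(vectors: dict[str, pd.Series], path) -> None:
    """Rows = samples, columns = canonical feature names."""
    df = pd.DataFrame({k: v for k, v in vectors.items()}).T
    df = df[list(FEATURE_NAMES)]
    df.index.name = "sample_id"
    df.to_csv(path)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"feature CSV missing {len(missing)} canonical columns")
    return df[list(FEATURE_NAMES)]
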