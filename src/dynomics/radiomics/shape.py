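"""3D shape features of a binary VOI.

Mesh-based quantities (volume, surface area, sphericity, diameters) come
from a marching-cubes iso-surface at 0.5 on the zero-padded binary mask;
axis lengths come from the eigen-decomposition of the covariance of the
physical coordinates of in-mask voxel centers (length = 4*sqrt(eigenvalue)).

Masks too small to mesh (a single voxel) fall back to voxel-based
approximations and emit a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

SHAPE_FEATURES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance, via the convex hull when it helps."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 64:
        try:
            pts = points[ConvexHull(points, qhull_options="QJ").vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(pts).max())


def _axis_lengths(coords_mm: np.ndarray) -> np.ndarray:
    """Eigenvalues (desc) of the coordinate covariance (sample covariance)."""
    cov = np.cov(coords_mm.T)
    eig = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
    return np.clip(eig, 0.0, None)


def shape3d_features(mask: np.ndarray,
                     spacing: tuple[float, float, float]) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing)
    n = int(mask.sum())
    voxel_volume = float(np.prod(spacing))
    coords_mm = np.argwhere(mask) * np.array(spacing)

    if n < 2:
        warnings.warn("mask too small to mesh; using voxel-based shape "
                      "approximations", stacklevel=2)
        a, b, c = spacing
        eig = np.sort(np.array(spacing) ** 2 / 12.0)[::-1]
        diam3d = float(np.linalg.norm(spacing))
        feats = {
            "MeshVolume": voxel_volume,
            "VoxelVolume": voxel_volume,
            "SurfaceArea": 2.0 * (a * b + b * c + a * c),
            "Maximum3DDiameter": diam3d,
            "Maximum2DDiameterSlice": float(np.hypot(a, b)),
            "Maximum2DDiameterColumn": float(np.hypot(b, c)),
            "Maximum2DDiameterRow": float(np.hypot(a, c)),
        }
    else:
        padded = np.pad(mask, 1).astype(float)
        verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
        area = float(mesh_surface_area(verts, faces))
        tri = verts[faces]
        mesh_volume = float(
            np.abs(np.einsum("ij,ij->i", tri[:, 0],
                             np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0
        )
        feats = {
            "MeshVolume": mesh_volume,
            "VoxelVolume": n * voxel_volume,
            "SurfaceArea": area,
            "Maximum3DDiameter": _max_pairwise(verts),
            "Maximum2DDiameterSlice": _max_pairwise(verts[:, [0, 1]]),
            "Maximum2DDiameterColumn": _max_pairwise(verts[:, [1, 2]]),
            "Maximum2DDiameterRow": _max_pairwise(verts[:, [0, 2]]),
        }
        eig = _axis_lengths(coords_mm)

    v, a = feats["MeshVolume"], feats["SurfaceArea"]
    feats["SurfaceVolumeRatio"] = a / v
    feats["Sphericity"] = float((36.0 * np.pi * v**2) ** (1.0 / 3.0) / a)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    feats["MajorAxisLength"] = major
    feats["MinorAxisLength"] = minor
    feats["LeastAxisLength"] = least
    feats["Elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    feats["Flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    return {k: float(feats[k]) for k in SHAPE_FEATURES}
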