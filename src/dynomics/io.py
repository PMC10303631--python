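"""Reading/writing volumes and masks, SUV normalization, static image,
mirrored reference mask.

NIfTI-1 is the on-disk format for 3D/4D images and masks (nibabel); frame
schedules and subject tables are CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import DynamicSeries, FrameSchedule, Volume3D, VoiMask

__all__ = [
    "load_dynamic_series",
    "save_dynamic_series",
    "load_mask",
    "save_mask",
    "suv_normalize",
    "make_static_image",
    "mirror_reference_mask",
    "left_right_axis",
    "load_subject_table",
]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    z = img.header.get_zooms()[:3]
    return tuple(float(v) for v in z)


def load_dynamic_series(
    volume_path: str | Path, schedule_path: str | Path, units: str = "concentration"
) -> DynamicSeries:
    """Load a 4D NIfTI volume plus its frame-schedule CSV.

    Fails (rather than truncating) when the number of frames in the volume
    does not equal the number of schedule rows.
    """
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{volume_path}: expected a 4D NIfTI, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{volume_path}: non-finite voxel values")
    schedule = FrameSchedule.from_csv(schedule_path)
    # DynamicSeries.__post_init__ enforces the frame-count match
    return DynamicSeries(data, schedule, _spacing_from(img), units=units)


def save_dynamic_series(series: DynamicSeries, volume_path: str | Path,
                        schedule_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.spacing))
    img.header.set_zooms(series.spacing + (1.0,))
    nib.save(img, str(volume_path))
    if schedule_path is not None:
        series.schedule.to_csv(schedule_path)


def load_mask(path: str | Path) -> VoiMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return VoiMask(data > 0.5, _spacing_from(img))


def save_mask(mask: VoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing))
    nib.save(img, str(path))


def suv_normalize(series: DynamicSeries, dose_MBq: float, weight_kg: float) -> DynamicSeries:
    """Convert activity concentration to standardized uptake values.

    SUV_bw = C[kBq/mL] * weight[g] / dose[kBq], assuming tissue density of
    1 g/mL, i.e. numerically C * weight_kg / dose_MBq.  Decay correction is
    assumed to have been applied at reconstruction; no decay term is added.
    """
    if series.units == "SUV":
        raise ValueError("series is already SUV-normalized")
    if dose_MBq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    factor = weight_kg / dose_MBq  # == (weight_kg*1000 g) / (dose_MBq*1000 kBq)
    return DynamicSeries(series.data * factor, series.schedule, series.spacing,
                         units="SUV", origin=series.origin)


def make_static_image(series: DynamicSeries, k: int = 5) -> Volume3D:
    """Static image: voxelwise mean of the last ``k`` timeframes (default 5)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > series.n_frames:
        raise ValueError(f"k={k} exceeds frame count {series.n_frames}")
    return Volume3D(series.data[..., -k:].mean(axis=3), series.spacing, series.origin)


def left_right_axis(affine: np.ndarray) -> int:
    """Array axis closest to the patient left-right (world x) direction."""
    return int(np.argmax(np.abs(affine[0, :3])))


def mirror_reference_mask(
    lesion: VoiMask,
    offset_vox: tuple[int, int, int] = (0, 0, 0),
    axis: int = 0,
) -> VoiMask:
    """Reflect a lesion mask across the grid midplane of ``axis`` (default the
    first spatial axis, i.e. left-right for RAS-aligned grids), then translate
    by an integer voxel offset.

    The reflection maps index i -> W-1-i; foreground cardinality is preserved.
    Raises if the translated mask would leave the grid (reporting how many
    voxels would be clipped) rather than silently shrinking the VOI.
    """
    flipped = np.flip(lesion.data, axis=axis)
    offset = tuple(int(o) for o in offset_vox)
    if any(offset):
        idx = np.argwhere(flipped)
        idx = idx + np.array(offset)
        inside = np.all((idx >= 0) & (idx < np.array(flipped.shape)), axis=1)
        n_clip = int((~inside).sum())
        if n_clip:
            raise ValueError(
                f"mirrored mask leaves the grid after offset {offset}: "
                f"{n_clip} voxel(s) clipped"
            )
        out = np.zeros_like(flipped)
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        flipped = out
    return VoiMask(flipped, lesion.spacing)


def load_subject_table(path: str | Path) -> pd.DataFrame:
    """Subject table CSV: subject_id, series_path, lesion_path,
    reference_path, dose_MBq, weight_kg, label."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "series_path", "lesion_path", "reference_path",
                "dose_MBq", "weight_kg", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
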