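"""Core containers for dynamic PET data.

A dynamic PET study is a time-ordered stack of 3D activity volumes acquired
on a fixed grid, together with the frame schedule (start and duration of each
timeframe, in seconds).  Volumes carry voxel spacing in millimetres; masks are
binary volumes of interest (VOIs) on the same grid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

#: frame blocks (count, duration_s) of the dynamic breast FLT protocol:
#: 16x5, 7x10, 5x30, 5x60, 5x180, 6x300 s -> 44 frames, 3220 s.
FLT_BREAST_SCHEDULE_BLOCKS: tuple[tuple[int, float], ...] = (
    (16, 5.0), (7, 10.0), (5, 30.0), (5, 60.0), (5, 180.0), (6, 300.0),
)


@dataclass(frozen=True)
class FrameSchedule:
    """Timing of the frames of a dynamic acquisition.

    Frames are ``(start_s, duration_s)`` pairs, sorted by start, strictly
    positive durations, non-overlapping.
    """

    starts_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        durs = np.asarray(self.durations_s, dtype=float)
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "durations_s", durs)
        if starts.ndim != 1 or starts.shape != durs.shape or starts.size < 1:
            raise ValueError("schedule needs >= 1 (start, duration) pair")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        ends = starts + durs
        if np.any(ends[:-1] > starts[1:] + 1e-9):
            raise ValueError("frames overlap")

    def __len__(self) -> int:
        return int(self.starts_s.size)

    @property
    def midpoints_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2.0

    @classmethod
    def from_blocks(cls, blocks: Sequence[tuple[int, float]]) -> "FrameSchedule":
        """Build a contiguous schedule from (n_frames, duration_s) blocks."""
        durs = np.concatenate([np.full(n, d, dtype=float) for n, d in blocks])
        starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    @classmethod
    def flt_breast_default(cls) -> "FrameSchedule":
        return cls.from_blocks(FLT_BREAST_SCHEDULE_BLOCKS)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrameSchedule":
        """Read a ``start_s,duration_s`` CSV (UTF-8, comma separated)."""
        starts, durs = [], []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"start_s", "duration_s"} <= set(
                reader.fieldnames
            ):
                raise ValueError(f"{path}: expected header start_s,duration_s")
            for row in reader:
                starts.append(float(row["start_s"]))
                durs.append(float(row["duration_s"]))
        return cls(np.array(starts), np.array(durs))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["start_s", "duration_s"])
            for s, d in zip(self.starts_s, self.durations_s):
                writer.writerow([f"{s:g}", f"{d:g}"])


@dataclass
class Volume3D:
    """A single 3D scalar volume (activity in kBq/mL, or unitless SUV)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Volume3D data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D contains non-finite voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DynamicSeries:
    """A 4D dynamic series: (x, y, z, t) activity + schedule + spacing.

    ``units`` is either ``"concentration"`` (kBq/mL) or ``"SUV"``.
    """

    data: np.ndarray
    schedule: FrameSchedule
    spacing: tuple[float, float, float]
    units: str = "concentration"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DynamicSeries data must be 4D (x, y, z, t)")
        if self.data.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame-count mismatch: volume has {self.data.shape[3]} frames, "
                f"schedule has {len(self.schedule)} rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DynamicSeries contains non-finite voxels")
        if self.units not in ("concentration", "SUV"):
            raise ValueError(f"unknown units {self.units!r}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[3])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    def frame(self, f: int) -> Volume3D:
        return Volume3D(self.data[..., f], self.spacing, self.origin)

    def frames(self) -> Iterator[Volume3D]:
        for f in range(self.n_frames):
            yield self.frame(f)


@dataclass
class VoiMask:
    """Binary volume of interest on the image grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("VoiMask data must be 3D")
        if not self.data.any():
            raise ValueError("VoiMask has no foreground voxels")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class SubjectRecord:
    """One subject: dynamic series, lesion/reference VOIs and metadata."""

    subject_id: str
    series: DynamicSeries
    lesion: VoiMask
    reference: VoiMask
    dose_MBq: float
    weight_kg: float
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.dose_MBq <= 0:
            raise ValueError("dose must be positive")
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        for voi in (self.lesion, self.reference):
            if voi.data.shape != self.series.grid_shape:
                raise ValueError("VOI grid does not match series grid")
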