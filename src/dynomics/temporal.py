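"""Dynamic radiomics ("dynomics"): per-frame feature extraction over a 4D
series and temporal summarization.

Each timeframe of a dynamic series is treated as an independent 3D image:
the full 107-feature vector is computed per frame (each frame discretized on
its own in-mask range by default), giving a frames x features matrix.  The
temporal profile of every feature is then summarized by its median and its
median absolute deviation (MAD, unscaled — no Gaussian consistency factor),
which become the sample's feature values for classification.  Shape features
depend only on the (fixed) mask, so their temporal MAD is structurally 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .radiomics import DiscretizationScheme, ExtractionSettings, extract_all
from .radiomics.shape import shape3d_features
from .types import DynamicSeries, FrameSchedule, VoiMask

__all__ = [
    "FeatureTimeSeries",
    "SampleFeatures",
    "DesignMatrix",
    "extract_per_frame",
    "temporal_median",
    "temporal_mad",
    "assemble_design_matrix",
    "export_timeseries_tensor",
]

MODES = ("static", "median", "mad", "median+mad", "timeseries")


@dataclass
class FeatureTimeSeries:
    """frames x features matrix for one VOI over a dynamic series."""

    values: pd.DataFrame  # index = frame number, columns = canonical names
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        if len(self.values) != len(self.schedule):
            raise ValueError("row count != frame count")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("non-finite feature values")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "start_s", self.schedule.starts_s)
        out.index.name = "frame"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, schedule: FrameSchedule | None = None
                 ) -> "FeatureTimeSeries":
        df = pd.read_csv(path, index_col="frame")
        starts = df.pop("start_s").to_numpy()
        if schedule is None:
            durs = np.diff(starts)
            durs = np.append(durs, durs[-1] if durs.size else 1.0)
            schedule = FrameSchedule(starts, durs)
        return cls(df, schedule)


def extract_per_frame(
    series: DynamicSeries,
    mask: VoiMask,
    scheme: DiscretizationScheme | None = None,
    settings: ExtractionSettings | None = None,
) -> FeatureTimeSeries:
    """Extract all 107 features from every frame of a dynamic series.

    The mask is fixed over time, so the shape block is computed once and
    reused across frames.
    """
    if mask.data.shape != series.grid_shape:
        raise ValueError("series and mask grids differ")
    shape_vals = shape3d_features(mask.data, series.spacing)
    rows = []
    for f in range(series.n_frames):
        try:
            rows.append(
                extract_all(series.frame(f), mask, scheme, settings,
                            _shape_values=shape_vals)
            )
        except Exception as exc:
            raise RuntimeError(f"frame {f}: {exc}") from exc
    df = pd.DataFrame(rows).reset_index(drop=True)
    return FeatureTimeSeries(df, series.schedule)


def temporal_median(fts: FeatureTimeSeries) -> pd.Series:
    """Per-feature median over frames (even count: mean of middle pair)."""
    return fts.values.median(axis=0)


def temporal_mad(fts: FeatureTimeSeries) -> pd.Series:
    """Per-feature median absolute deviation over frames, unscaled:
    median(|x_f - median(x)|)."""
    med = fts.values.median(axis=0)
    return (fts.values - med).abs().median(axis=0)


@dataclass
class SampleFeatures:
    """Per-sample inputs to design-matrix assembly.

    ``static`` is the feature vector of the static image; ``timeseries`` the
    per-frame matrix.  Either may be omitted if the target mode allows it.
    """

    sample_id: str
    label: str
    static: pd.Series | None = None
    timeseries: FeatureTimeSeries | None = None


@dataclass
class DesignMatrix:
    """samples x features table with labels and a mode tag."""

    X: pd.DataFrame
    labels: pd.Series
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.X) != len(self.labels):
            raise ValueError("row/label count mismatch")
        if self.X.isna().any().any():
            raise ValueError("design matrix has missing values")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path) -> None:
        out = self.X.copy()
        out["label"] = self.labels
        out.index.name = "sample_id"
        out.to_csv(path)
        sidecar = Path(str(path) + ".json")
        sidecar.write_text(json.dumps({"mode": self.mode}), encoding="utf-8")


def _summary_row(sample: SampleFeatures, mode: str) -> pd.Series:
    if mode == "static":
        if sample.static is None:
            raise ValueError(f"{sample.sample_id}: no static features")
        return sample.static
    if sample.timeseries is None:
        raise ValueError(f"{sample.sample_id}: no per-frame features")
    if mode == "median":
        return temporal_median(sample.timeseries)
    if mode == "mad":
        return temporal_mad(sample.timeseries)
    med = temporal_median(sample.timeseries)
    mad = temporal_mad(sample.timeseries)
    med.index = [f"{c}/median" for c in med.index]
    mad.index = [f"{c}/mad" for c in mad.index]
    return pd.concat([med, mad])


def assemble_design_matrix(samples: list[SampleFeatures], mode: str) -> DesignMatrix:
    """Build the n x m (or n x 2m for median+mad) classification matrix."""
    if mode not in ("static", "median", "mad", "median+mad"):
        raise ValueError(f"unsupported design-matrix mode {mode!r}")
    if not samples:
        raise ValueError("no samples")
    rows, ids, labels = [], [], []
    for s in samples:
        if not s.label or s.label == "unlabeled":
            raise ValueError(f"{s.sample_id}: missing label")
        rows.append(_summary_row(s, mode))
        ids.append(s.sample_id)
        labels.append(s.label)
    X = pd.DataFrame(rows, index=ids)
    ref = list(rows[0].index)
    if any(list(r.index) != ref for r in rows[1:]):
        raise ValueError("inconsistent feature names across samples")
    return DesignMatrix(X, pd.Series(labels, index=ids), mode)


def export_timeseries_tensor(samples: list[SampleFeatures]) -> pd.DataFrame:
    """Long-form (n*m) x t table: one row per (sample, feature) with the
    feature's full time course and the sample's label, for external
    time-series models."""
    frames = {s.sample_id: s.timeseries for s in samples}
    if any(f is None for f in frames.values()):
        raise ValueError("all samples need per-frame features")
    t_counts = {f.n_frames for f in frames.values()}
    if len(t_counts) != 1:
        raise ValueError(f"heterogeneous frame counts: {sorted(t_counts)}")
    out_rows = []
    index = []
    labels = []
    for s in samples:
        mat = s.timeseries.values.T  # features x frames
        for feat, row in mat.iterrows():
            index.append((s.sample_id, feat))
            out_rows.append(row.to_numpy())
            labels.append(s.label)
    t = t_counts.pop()
    df = pd.DataFrame(
        out_rows,
        index=pd.MultiIndex.from_tuples(index, names=["sample_id", "feature"]),
        columns=[f"t{k}" for k in range(t)],
    )
    df["label"] = labels
    return df
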