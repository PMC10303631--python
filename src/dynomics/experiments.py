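"""High-level experiment workflows.

Two classification tasks are supported end to end:

* ``tumor-vs-reference`` — every subject contributes two samples (the lesion
  VOI and the mirrored reference VOI), n = 2 x subjects; subject grouping in
  the outer CV keeps both rows of a patient in the same fold.
* ``cr-vs-pr`` — one sample per subject, labelled by response class.

Feature modes: ``static`` (features of the late-frame average image),
``median`` / ``mad`` / ``median+mad`` (temporal summaries of the per-frame
features).
"""

from __future__ import annotations

from typing import Iterable

from .io import make_static_image, suv_normalize
from .radiomics import DiscretizationScheme, ExtractionSettings, extract_all
from .temporal import (
    DesignMatrix,
    SampleFeatures,
    assemble_design_matrix,
    extract_per_frame,
)
from .types import SubjectRecord

__all__ = ["subject_samples", "build_design_matrix", "TASKS"]

TASKS = ("tumor-vs-reference", "cr-vs-pr")


def subject_samples(
    subjects: Iterable[SubjectRecord],
    task: str,
    need_timeseries: bool = True,
    need_static: bool = True,
    scheme: DiscretizationScheme | None = None,
    settings: ExtractionSettings | None = None,
) -> list[SampleFeatures]:
    """Extract per-sample features for a task, streaming over subjects.

    Series in concentration units are SUV-normalized first.  Sample ids are
    ``<subject>/<voi>`` so the pipeline can group rows by subject.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    samples: list[SampleFeatures] = []
    for sub in subjects:
        series = sub.series
        if series.units == "concentration":
            series = suv_normalize(series, sub.dose_MBq, sub.weight_kg)
        static = make_static_image(series) if need_static else None
        if task == "tumor-vs-reference":
            vois = (("lesion", sub.lesion), ("reference", sub.reference))
        else:
            vois = (("lesion", sub.lesion),)
        for voi_name, voi in vois:
            label = voi_name if task == "tumor-vs-reference" else sub.label
            samples.append(SampleFeatures(
                sample_id=f"{sub.subject_id}/{voi_name}",
                label=label,
                static=(extract_all(static, voi, scheme, settings)
                        if need_static else None),
                timeseries=(extract_per_frame(series, voi, scheme, settings)
                            if need_timeseries else None),
            ))
    return samples


def build_design_matrix(samples: list[SampleFeatures], mode: str) -> DesignMatrix:
    return assemble_design_matrix(samples, mode)
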