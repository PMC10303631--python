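"""Seeded 4D PET phantoms for end-to-end testing of the dynomics pipeline.

Each phantom subject is a dynamic breast-FLT-like acquisition: a spherical
lesion with high tracer uptake placed in one breast position, a mirrored
low-uptake reference region in the contralateral position, and a dim tissue
background.  Voxel time-activity curves (TACs) follow a monotone uptake
model K*(1 - exp(-t/tau)) + b*t evaluated at frame midpoints (pharmacokinetic
compartment modelling is deliberately out of scope), modulated by a smooth
multiplicative spatial heterogeneity field, with Gaussian noise whose
standard deviation scales as 1/sqrt(frame duration) to mimic counting
statistics.

Two response classes are generated: a *homogeneous* class (single uptake
time constant across the lesion, the complete-responder analogue) and a
*heterogeneous* class (the lesion is partitioned into subregions with
distinct uptake time constants and uptake onset delays, the
partial-responder analogue).  Subregion time constants are drawn from a
bounded range so all subregions converge to their plateau before the static
(late-frame) window, and every lesion is rescaled so its static mean matches
the homogeneous construction exactly: the class signal is carried by
spatial-temporal heterogeneity, not by static uptake level.

Because per-frame fixed-bin-count discretization is invariant to a uniform
rescaling of the whole VOI, a noiseless homogeneous lesion has *identical*
discretized texture in every frame (temporal MAD of texture ~ noise only),
whereas the heterogeneous lesion's spatial pattern genuinely reorganizes as
subregions switch on and saturate at different times.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import mirror_reference_mask, save_dynamic_series, save_mask
from .types import DynamicSeries, FrameSchedule, SubjectRecord, VoiMask

__all__ = [
    "PhantomConfig", "make_tac", "make_heterogeneity_field",
    "generate_subject", "iter_cohort", "generate_cohort",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate the dynamic breast acquisition: the printed frame
    schedule (16x5, 7x10, 5x30, 5x60, 5x180, 6x300 s), 3.9x3.9x4.2 mm
    voxels, SUV-scale amplitudes, and the 19 partial / 12 complete responder
    class imbalance.  The grid is 64x64x24 for desk-speed; the full
    128x128x35 matrix is available by configuration.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (3.9, 3.9, 4.2)
    schedule: FrameSchedule = field(default_factory=FrameSchedule.flt_breast_default)
    lesion_radius_vox: float = 6.0
    lesion_center: tuple[int, int, int] | None = None  # default: 3/4 along x
    # lesion TAC (SUV-scale): plateau amplitude, uptake time constant, late slope
    lesion_K: float = 6.0
    lesion_tau_s: float = 400.0
    late_slope: float = 1e-4
    # low-uptake tissue background
    background_K: float = 0.5
    background_tau_s: float = 200.0
    # spatial heterogeneity (both classes): smooth multiplicative field
    correlation_length_vox: float = 2.0
    amplitude_cv: float = 0.10
    # heterogeneous class: subregions with distinct uptake kinetics; time
    # constants bounded so every subregion plateaus before the static window
    n_subregions: int = 6
    tau_range_s: tuple[float, float] = (100.0, 900.0)
    onset_delay_max_s: float = 200.0
    # Gaussian noise sd = noise_scale / sqrt(frame duration)
    noise_scale: float = 0.05
    # cohort composition (heterogeneous = partial responders)
    n_heterogeneous: int = 19
    n_homogeneous: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate list-valued fields from YAML/JSON configs
        object.__setattr__(self, "grid_shape", tuple(self.grid_shape))
        object.__setattr__(self, "spacing", tuple(self.spacing))
        object.__setattr__(self, "tau_range_s", tuple(self.tau_range_s))
        if self.lesion_center is not None:
            object.__setattr__(self, "lesion_center", tuple(self.lesion_center))
        if self.lesion_radius_vox <= 0 or self.lesion_K <= 0:
            raise ValueError("lesion radius and amplitude must be positive")
        if self.lesion_tau_s <= 0 or self.background_tau_s <= 0:
            raise ValueError("time constants must be positive")
        if self.amplitude_cv < 0 or self.noise_scale < 0:
            raise ValueError("cv and noise must be >= 0")
        if self.n_subregions < 1:
            raise ValueError("n_subregions must be >= 1")
        if not (0 < self.tau_range_s[0] <= self.tau_range_s[1]):
            raise ValueError("invalid tau range")
        if self.onset_delay_max_s < 0:
            raise ValueError("onset delay must be >= 0")


def make_tac(K: float, tau_s: float, b: float,
             schedule: FrameSchedule) -> np.ndarray:
    """Monotone uptake curve K*(1-exp(-t/tau)) + b*t at frame midpoints."""
    if K < 0 or tau_s <= 0:
        raise ValueError("K must be >= 0 and tau > 0")
    t = schedule.midpoints_s
    return K * (1.0 - np.exp(-t / tau_s)) + b * t


def make_heterogeneity_field(shape: tuple[int, ...], correlation_length: float,
                             cv: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field with mean 1 and coefficient of variation
    ``cv`` (sample-exact), clipped away from zero."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.ones(shape)
    g = ndimage.gaussian_filter(rng.standard_normal(shape), correlation_length)
    g = (g - g.mean()) / g.std()
    return np.clip(1.0 + cv * g, 0.05, None)


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _partition_lesion(mask: np.ndarray, n_subregions: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Assign each lesion voxel to the nearest of n seeded points (a seeded
    Voronoi partition into contiguous subregions)."""
    idx = np.argwhere(mask)
    picks = rng.choice(len(idx), size=min(n_subregions, len(idx)),
                       replace=False)
    centers = idx[picks].astype(float)
    d2 = ((idx[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def generate_subject(config: PhantomConfig, class_label: str,
                     seed: int, subject_id: str | None = None) -> SubjectRecord:
    """One phantom subject of class ``"homogeneous"`` or ``"heterogeneous"``.

    The stored series is in concentration units (kBq/mL) consistent with the
    sampled dose and weight, so SUV normalization reproduces the SUV-scale
    construction.
    """
    if class_label not in ("homogeneous", "heterogeneous"):
        raise ValueError(f"unknown class {class_label!r}")
    rng = np.random.default_rng(seed)
    shape = config.grid_shape
    sched = config.schedule
    t_mid = sched.midpoints_s
    n_frames = len(sched)

    center = config.lesion_center or (3 * shape[0] // 4, shape[1] // 2,
                                      shape[2] // 2)
    lesion = _sphere_mask(shape, center, config.lesion_radius_vox)

    # background tissue everywhere
    bg_tac = make_tac(config.background_K, config.background_tau_s,
                      config.late_slope, sched)
    data = np.empty(shape + (n_frames,), dtype=float)
    data[...] = bg_tac  # broadcast over the trailing time axis

    # lesion voxels: amplitude field x per-voxel uptake curve
    amp_field = make_heterogeneity_field(shape, config.correlation_length_vox,
                                         config.amplitude_cv, rng)
    les_idx = np.argwhere(lesion)
    n_les = len(les_idx)
    amps = config.lesion_K * amp_field[lesion]

    if class_label == "heterogeneous" and config.n_subregions > 1:
        # seeded Voronoi subregions with distinct uptake time constants and
        # onset delays; n_subregions == 1 is the null construction where the
        # two classes coincide
        assign = _partition_lesion(lesion, config.n_subregions, rng)
        taus = rng.uniform(*config.tau_range_s, size=config.n_subregions)[assign]
        delays = rng.uniform(0.0, config.onset_delay_max_s,
                             size=config.n_subregions)[assign]
    else:
        taus = np.full(n_les, config.lesion_tau_s)
        delays = np.zeros(n_les)

    t_eff = np.clip(t_mid[None, :] - delays[:, None], 0.0, None)
    uptake = 1.0 - np.exp(-t_eff / taus[:, None])  # (n_les, t)
    lesion_tacs = amps[:, None] * uptake + config.late_slope * t_mid[None, :]

    # match the lesion's static (last-5-frame) mean to the homogeneous
    # construction with the same amplitude field, so static uptake carries
    # no class signal
    target_static = float(np.mean(
        amps[:, None] * (1.0 - np.exp(-t_mid[None, -5:] / config.lesion_tau_s))
        + config.late_slope * t_mid[None, -5:]))
    actual_static = float(lesion_tacs[:, -5:].mean())
    lesion_tacs *= target_static / actual_static
    data[lesion, :] = lesion_tacs

    # counting-like noise: sd shrinks with frame duration
    if config.noise_scale > 0:
        sd = config.noise_scale / np.sqrt(sched.durations_s)
        data += rng.standard_normal(data.shape) * sd
    np.clip(data, 0.0, None, out=data)

    dose = float(rng.uniform(110.0, 204.0))
    weight = float(np.clip(rng.normal(70.0, 12.0), 45.0, 110.0))
    # SUV-scale construction -> concentration units: C = SUV * dose / weight
    data *= dose / weight

    series = DynamicSeries(data, sched, config.spacing, units="concentration")
    lesion_voi = VoiMask(lesion, config.spacing)
    reference = mirror_reference_mask(lesion_voi, axis=0)
    return SubjectRecord(
        subject_id=subject_id or f"sub-{seed}",
        series=series,
        lesion=lesion_voi,
        reference=reference,
        dose_MBq=dose,
        weight_kg=weight,
        label=class_label,
    )


def iter_cohort(config: PhantomConfig):
    """Yield the cohort's subjects one at a time (memory-friendly: a 4D
    series is tens of MB, so callers extracting features should stream)."""
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_heterogeneous + config.n_homogeneous
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(n_total)]
    labels = (["heterogeneous"] * config.n_heterogeneous
              + ["homogeneous"] * config.n_homogeneous)
    for i, (label, seed) in enumerate(zip(labels, child_seeds)):
        yield generate_subject(config, label, seed, subject_id=f"sub-{i:03d}")


def generate_cohort(config: PhantomConfig,
                    out_dir: str | Path | None = None) -> list[SubjectRecord]:
    """Seeded cohort of homogeneous + heterogeneous subjects (defaults
    mirror the 12 complete / 19 partial responder imbalance).  When
    ``out_dir`` is given, writes per-subject 4D NIfTI volumes, mask NIfTIs,
    the schedule CSV and a subject table CSV."""
    subjects = list(iter_cohort(config))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.schedule.to_csv(out / "schedule.csv")
        rows = []
        for s in subjects:
            vol = out / f"{s.subject_id}_dyn.nii.gz"
            les = out / f"{s.subject_id}_lesion.nii.gz"
            ref = out / f"{s.subject_id}_reference.nii.gz"
            save_dynamic_series(s.series, vol)
            save_mask(s.lesion, les)
            save_mask(s.reference, ref)
            rows.append([s.subject_id, vol.name, les.name, ref.name,
                         f"{s.dose_MBq:.6f}", f"{s.weight_kg:.6f}", s.label])
        with open(out / "subjects.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "series_path", "lesion_path",
                        "reference_path", "dose_MBq", "weight_kg", "label"])
            w.writerows(rows)
    return subjects
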