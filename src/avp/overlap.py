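"""Reconstruct acquired voxels in template space and score placement.

All metrics operate on partial-volume masks rendered on one shared 0.5 mm
template-space grid and on one pixel-intensity threshold t (chosen from the
template voxel's threshold table):

* accuracy          100 * #{(subject + template)/2 > t} / #{template > t}
* between-subject   100 * #{mean(subject masks) > t}   / #{template > t}
* within-subject    100 * #{mean(timepoint masks) > t} / #{denominator > t}

Accuracy and between-subject overlap are computed separately per timepoint.
The within-subject denominator defaults to the template voxel so all three
metrics share one denominator semantics; pass ``denominator="first"`` to
use each subject's first-timepoint voxel instead.

Specs always come from acquisition metadata (DICOM header or sidecar) —
the region spectra were actually collected from — never from the
prescription pipeline's internal matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .geometry import VoxelSpec, angulation_from_rotation
from .image import ImageVolume
from .rasterize import (
    DEFAULT_THRESHOLDS,
    Grid,
    ThresholdTable,
    VoxelMask,
    rasterize_voxel,
    select_threshold,
    threshold_table,
)
from .registration import (
    RegistrationBackend,
    RegistrationConfig,
    register,
    resample_trilinear,
)

__all__ = [
    "AcquiredVoxel",
    "OverlapReport",
    "reconstruct_in_template",
    "accuracy",
    "between_subject_overlap",
    "within_subject_overlap",
    "cv_percent",
    "tissue_fractions",
    "compute_overlap_report",
    "write_overlap_summary",
]


@dataclass
class AcquiredVoxel:
    """The voxel actually acquired for one subject at one timepoint."""

    subject_id: str
    timepoint: str
    spec: VoxelSpec
    subject_image: ImageVolume | None = None
    source: str = "manual"
    provenance: dict[str, Any] = field(default_factory=dict)


def reconstruct_in_template(
    av: AcquiredVoxel,
    template: ImageVolume,
    grid: Grid,
    backend: RegistrationBackend | None = None,
    config: RegistrationConfig | None = None,
) -> VoxelMask:
    """Re-rasterize an acquired voxel in template space.

    Mirrors the prescription procedure in reverse: a rigid 6-dof
    subject-to-template registration supplies the rotation (composed with
    the acquired angulation and decomposed to template-frame angles) and a
    9-dof registration maps the center, calibrating for anatomical size
    differences.  The voxel is rendered with its ORIGINAL dimensions —
    never scaled.
    """
    if av.subject_image is None:
        raise ValueError(
            f"{av.subject_id}/{av.timepoint}: no subject image attached"
        )
    try:
        res6 = register(av.subject_image, template, dof=6, backend=backend,
                        config=config)
        res9 = register(av.subject_image, template, dof=9, backend=backend,
                        init=res6.transform, config=config)
    except Exception as e:
        raise RuntimeError(
            f"registration failed for {av.subject_id}/{av.timepoint}: {e}"
        ) from e
    r_reg = res6.transform.matrix[:3, :3]
    ang = angulation_from_rotation(r_reg @ av.spec.rotation)
    center = res9.transform.apply(np.asarray(av.spec.center))
    spec_t = VoxelSpec(
        study=av.spec.study,
        description=av.spec.description,
        dims=av.spec.dims,
        center=tuple(center),
        angulation=ang,
        orientation=template.orientation,
    )
    return rasterize_voxel(spec_t, grid)


def _superlevel_count(mask: VoxelMask, t: float) -> int:
    return mask.count_above(t)


def _require_same_grid(masks: Iterable[VoxelMask]) -> None:
    grids = {id_grid for m in masks
             for id_grid in [(m.grid.shape, m.grid.spacing, m.grid.origin)]}
    if len(grids) > 1:
        raise ValueError("masks live on different grids")


def accuracy(subject_mask: VoxelMask, template_mask: VoxelMask,
             t: float) -> float:
    """Placement accuracy %: thresholded (subject+template)/2 over template."""
    _require_same_grid([subject_mask, template_mask])
    denom = _superlevel_count(template_mask, t)
    if denom == 0:
        raise ValueError(f"template superlevel set empty at threshold {t}")
    avg = (subject_mask.values + template_mask.values) / 2.0
    return 100.0 * int(np.count_nonzero(avg > t)) / denom


def between_subject_overlap(
    masks: Sequence[VoxelMask], template_mask: VoxelMask, t: float
) -> float:
    """Between-subject overlap %: thresholded mean of all subject masks over
    the template voxel.  With one mask this reduces to that mask's accuracy
    denominator-for-denominator."""
    if len(masks) == 0:
        raise ValueError("need at least one subject mask")
    _require_same_grid([*masks, template_mask])
    denom = _superlevel_count(template_mask, t)
    if denom == 0:
        raise ValueError(f"template superlevel set empty at threshold {t}")
    mean = np.mean([m.values for m in masks], axis=0)
    return 100.0 * int(np.count_nonzero(mean > t)) / denom


def within_subject_overlap(
    masks_by_timepoint: Sequence[VoxelMask],
    denominator_mask: VoxelMask,
    t: float,
) -> float:
    """Within-subject overlap %: thresholded mean across a subject's
    timepoints over the denominator voxel (template by default)."""
    if len(masks_by_timepoint) < 2:
        raise ValueError("within-subject overlap needs >= 2 timepoints")
    _require_same_grid([*masks_by_timepoint, denominator_mask])
    denom = _superlevel_count(denominator_mask, t)
    if denom == 0:
        raise ValueError(f"denominator superlevel set empty at threshold {t}")
    mean = np.mean([m.values for m in masks_by_timepoint], axis=0)
    return 100.0 * int(np.count_nonzero(mean > t)) / denom


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation %: 100 * sample SD (n-1) / mean."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("CV% needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV% undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def tissue_fractions(
    pve: Mapping[str, ImageVolume],
    mask: VoxelMask,
    t: float,
) -> dict[str, float]:
    """GM/WM/CSF percentages of the thresholded voxel region.

    Partial-volume maps are resampled onto the mask grid by trilinear
    interpolation; each tissue's percentage is its summed partial volume
    over the summed partial volume of all three tissues within the region,
    so the three values total 100.
    """
    for key in ("gm", "wm", "csf"):
        if key not in pve:
            raise KeyError(f"pve maps must include {key!r}")
    region = mask.values > t
    if not region.any():
        raise ValueError(f"thresholded mask empty at threshold {t}")
    sums = {}
    for key in ("gm", "wm", "csf"):
        res = resample_trilinear(pve[key], None, mask.grid)
        vals = np.clip(res.data[region], 0.0, None)
        sums[key] = float(vals.sum())
    total = sum(sums.values())
    if total <= 0:
        raise ValueError("tissue maps are zero within the voxel region")
    return {k: 100.0 * v / total for k, v in sums.items()}


@dataclass
class OverlapReport:
    """Everything the overlap pipeline measures, one study at a time."""

    threshold_table: ThresholdTable
    selected_threshold: float
    accuracy_per_subject: dict[str, list[tuple[str, float]]]
    accuracy_mean_sd: dict[str, tuple[float, float]]
    between_subject: dict[str, float]
    within_subject_per_subject: dict[str, float]
    within_subject_mean_cv: tuple[float, float] | None
    tissue: dict[tuple[str, str], dict[str, float]]

    def __post_init__(self) -> None:
        for tp, rows in self.accuracy_per_subject.items():
            for _, pct in rows:
                if pct < 0:
                    raise ValueError("negative overlap percentage")


def compute_overlap_report(
    template: ImageVolume,
    template_spec: VoxelSpec,
    acquisitions: Sequence[AcquiredVoxel],
    pve_by_subject: Mapping[tuple[str, str], Mapping[str, ImageVolume]] | None = None,
    spacing: float = 0.5,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    denominator: str = "template",
    backend: RegistrationBackend | None = None,
    config: RegistrationConfig | None = None,
) -> tuple[OverlapReport, dict[tuple[str, str], VoxelMask]]:
    """Run the full overlap pipeline for one template voxel.

    Reconstructs every acquisition in template space on one shared grid,
    selects the working threshold from the template voxel's threshold
    table, and computes accuracy (per subject, per timepoint),
    between-subject overlap (per timepoint), within-subject overlap (per
    subject across timepoints, group mean and CV%), and tissue fractions
    when partial-volume maps are supplied.
    """
    if denominator not in ("template", "first"):
        raise ValueError("denominator must be 'template' or 'first'")
    dims0 = acquisitions[0].spec.dims if acquisitions else template_spec.dims
    for av in acquisitions:
        if not np.allclose(av.spec.dims, dims0, atol=1e-6):
            warnings.warn(
                f"{av.subject_id}/{av.timepoint}: voxel dims {av.spec.dims} "
                f"differ from the study's {dims0}",
                stacklevel=2,
            )

    # one grid generous enough for template voxel and reconstructions
    margin = 2.0 + 0.5 * float(np.linalg.norm(template_spec.dims))
    grid = Grid.for_spec(template_spec, spacing=spacing, margin=margin)
    template_mask = rasterize_voxel(template_spec, grid)
    table = threshold_table(template_mask, thresholds)
    t = select_threshold(table, rotated=template_spec.is_rotated)

    masks: dict[tuple[str, str], VoxelMask] = {}
    for av in acquisitions:
        masks[(av.subject_id, av.timepoint)] = reconstruct_in_template(
            av, template, grid, backend=backend, config=config
        )

    timepoints = sorted({tp for _, tp in masks})
    acc: dict[str, list[tuple[str, float]]] = {}
    acc_stats: dict[str, tuple[float, float]] = {}
    between: dict[str, float] = {}
    for tp in timepoints:
        rows = [(sid, accuracy(m, template_mask, t))
                for (sid, mtp), m in sorted(masks.items()) if mtp == tp]
        acc[tp] = rows
        vals = [p for _, p in rows]
        acc_stats[tp] = (float(np.mean(vals)),
                         float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        between[tp] = between_subject_overlap(
            [m for (sid, mtp), m in sorted(masks.items()) if mtp == tp],
            template_mask, t,
        )

    subjects = sorted({sid for sid, _ in masks})
    within: dict[str, float] = {}
    for sid in subjects:
        series = [m for (msid, tp), m in sorted(masks.items()) if msid == sid]
        if len(series) < 2:
            continue
        denom_mask = template_mask if denominator == "template" else series[0]
        within[sid] = within_subject_overlap(series, denom_mask, t)
    within_summary = None
    if len(within) >= 2:
        vals = list(within.values())
        within_summary = (float(np.mean(vals)), cv_percent(vals))
    elif len(within) == 1:
        within_summary = (float(next(iter(within.values()))), float("nan"))

    tissue: dict[tuple[str, str], dict[str, float]] = {}
    if pve_by_subject:
        for key, m in masks.items():
            if key in pve_by_subject:
                tissue[key] = tissue_fractions(pve_by_subject[key], m, t)

    report = OverlapReport(
        threshold_table=table,
        selected_threshold=t,
        accuracy_per_subject=acc,
        accuracy_mean_sd=acc_stats,
        between_subject=between,
        within_subject_per_subject=within,
        within_subject_mean_cv=within_summary,
        tissue=tissue,
    )
    return report, masks


def write_overlap_summary(report: OverlapReport, path: str | Path) -> None:
    """Write the tab-separated Overlap_Summary.txt report file."""
    lines: list[str] = []
    tbl = report.threshold_table
    lines.append("# Section 1: threshold table")
    lines.append("# Threshold\tPixelCount\tVolume_mm3\tPercent Total Voxel")
    for th, n, v, p in zip(tbl.thresholds, tbl.pixel_counts, tbl.volumes,
                           tbl.percent_total):
        lines.append(f"{th:.2f}\t{int(n)}\t{v:.3f}\t{p:.2f}")
    lines.append(f"# Selected threshold\t{report.selected_threshold:.2f}")

    lines.append("# Section 2: voxel placement accuracy")
    lines.append("# Subject\tTimepoint\tAccuracy_pct")
    for tp, rows in sorted(report.accuracy_per_subject.items()):
        for sid, pct in rows:
            lines.append(f"{sid}\t{tp}\t{pct:.2f}")
    for tp, (m, sd) in sorted(report.accuracy_mean_sd.items()):
        lines.append(f"# Mean_SD\t{tp}\t{m:.2f}\t{sd:.2f}")

    lines.append("# Section 3: between-subject overlap")
    lines.append("# Timepoint\tOverlap_pct")
    for tp, pct in sorted(report.between_subject.items()):
        lines.append(f"{tp}\t{pct:.2f}")

    lines.append("# Section 4: within-subject overlap")
    lines.append("# Subject\tOverlap_pct")
    for sid, pct in sorted(report.within_subject_per_subject.items()):
        lines.append(f"{sid}\t{pct:.2f}")
    if report.within_subject_mean_cv is not None:
        m, cv = report.within_subject_mean_cv
        lines.append(f"# Mean\t{m:.2f}\tCV_pct\t{cv:.2f}")

    lines.append("# Section 5: tissue fractions")
    lines.append("# Subject\tTimepoint\tGM_pct\tWM_pct\tCSF_pct")
    for (sid, tp), fr in sorted(report.tissue.items()):
        lines.append(f"{sid}\t{tp}\t{fr['gm']:.2f}\t{fr['wm']:.2f}"
                     f"\t{fr['csf']:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")
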