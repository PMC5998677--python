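"""Author template voxels and map them onto subject anatomy.

Creating a template voxel renders the prescription in template space (the
cuboid is rotated about the field-of-view center and then translated to its
final location — equivalently, rotated in place about its own center),
writes an overlay mask for visual appraisal, and records the prescription
in the append-only voxel library.

Prescribing onto a subject mirrors the scanner-side procedure: a rigid
6-dof template-to-subject registration supplies the rotation, which is
composed with the template voxel's own rotation and decomposed back into
console angles; a 9-dof (rotation + scale) registration maps the voxel
center coordinate, calibrating for anatomical size differences while the
voxel dimensions are copied unchanged.  The result is reported both at full
precision and quantized to scanner entry precision (0.1 mm / 0.1 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np

from .geometry import (
    VoxelSpec,
    angulation_from_rotation,
    voxel_corners,
)
from .image import ImageVolume
from .rasterize import Grid, VoxelMask, rasterize_voxel
from .registration import RegistrationBackend, RegistrationConfig, register

__all__ = ["Prescription", "create_template_voxel", "prescribe_voxel",
           "round_spec"]

#: scanner console entry precision: 0.1 mm translation, 0.1 deg rotation
SCANNER_QUANTUM = 0.1


def round_spec(spec: VoxelSpec, quantum: float = SCANNER_QUANTUM) -> VoxelSpec:
    """Quantize center and angles to scanner entry precision."""
    center = tuple(round(c / quantum) * quantum for c in spec.center)
    ang = type(spec.angulation)(
        *(round(a / quantum) * quantum for a in spec.angulation.as_tuple())
    )
    return spec.with_pose(center=center, angulation=ang)


@dataclass
class Prescription:
    """A subject-frame prescription with provenance and a rounded copy."""

    spec: VoxelSpec
    rounded: VoxelSpec
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dc = np.abs(np.asarray(self.rounded.center) - np.asarray(self.spec.center))
        da = np.abs(self.rounded.angulation - self.spec.angulation)
        if dc.max() > SCANNER_QUANTUM / 2 + 1e-9 or da.max() > SCANNER_QUANTUM / 2 + 1e-9:
            raise ValueError("rounded prescription strays beyond the scanner "
                             "entry quantum from the full-precision one")


def _check_fov(spec: VoxelSpec, template: ImageVolume) -> None:
    lo, hi = template.world_bounds()
    for corner in voxel_corners(spec):
        if np.any(corner < lo) or np.any(corner > hi):
            raise ValueError(
                f"voxel corner {np.round(corner, 2).tolist()} falls outside "
                f"the template field of view [{np.round(lo, 1).tolist()}, "
                f"{np.round(hi, 1).tolist()}]"
            )


def create_template_voxel(
    params: VoxelSpec,
    template: ImageVolume,
    library_path: str | Path | None = None,
    template_image_path: str = "",
    overwrite: bool = False,
    spacing: float = 0.5,
    mask_path: str | Path | None = None,
) -> tuple[VoxelMask, tuple[VoxelSpec, str]]:
    """Render a template prescription and record it in the voxel library.

    Returns the partial-volume mask (on a 0.5 mm grid, exportable as an
    overlay for appraisal in any world-aware viewer) and the library record.
    Re-running for the same (study, description) replaces the record only
    with ``overwrite``.
    """
    _check_fov(params, template)
    grid = Grid.for_spec(params, spacing=spacing)
    mask = rasterize_voxel(params, grid)
    record = (params, template_image_path)
    if library_path is not None:
        from . import io as avpio

        avpio.append_voxel_record(library_path, params, template_image_path,
                                  overwrite=overwrite)
    if mask_path is not None:
        from . import io as avpio

        avpio.write_mask(mask, mask_path)
    return mask, record


def prescribe_voxel(
    template: ImageVolume,
    template_spec: VoxelSpec,
    subject: ImageVolume,
    backend: RegistrationBackend | None = None,
    config: RegistrationConfig | None = None,
) -> Prescription:
    """Map a template prescription into subject space.

    Rotation: 6-dof template->subject registration; its rotation composed
    with the template voxel's rotation gives the subject-frame angulation.
    Center: the 9-dof registration (initialized from the rigid result) maps
    the template center coordinate.  Dimensions are preserved exactly.
    """
    res6 = register(template, subject, dof=6, backend=backend, config=config)
    res9 = register(template, subject, dof=9, backend=backend,
                    init=res6.transform, config=config)

    r_reg = res6.transform.matrix[:3, :3]
    # voxel axes rotate with the anatomy: R_subject = R_registration @ R_voxel
    ang = angulation_from_rotation(r_reg @ template_spec.rotation)
    center = res9.transform.apply(np.asarray(template_spec.center))

    spec = VoxelSpec(
        study=template_spec.study,
        description=template_spec.description,
        dims=template_spec.dims,
        center=tuple(center),
        angulation=ang,
        orientation=subject.orientation,
    )
    provenance = {
        "template_spec": template_spec,
        "rigid_matrix": res6.transform.matrix.tolist(),
        "affine9_matrix": res9.transform.matrix.tolist(),
        "rigid_converged": res6.converged,
        "affine9_converged": res9.converged,
        "rigid_similarity": res6.similarity,
        "affine9_similarity": res9.similarity,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return Prescription(spec=spec, rounded=round_spec(spec),
                        provenance=provenance)
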