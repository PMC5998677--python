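"""File formats: NIfTI volumes, acquired-voxel geometry, libraries, transforms.

Acquired-voxel geometry — the cuboid from which spectra were actually
collected — can come from a spectroscopy DICOM header (standard MR
Spectroscopy volume-localization fields: one slab per voxel axis with Slab
Thickness (0018,9104), Slab Orientation (0018,9105) and Mid Slab Position
(0018,9106)) or from a documented plain-JSON sidecar, which is the portable
path and the canonical fixture format:

    {
      "subject_id": "sub-01", "timepoint": "baseline",
      "dims": [15.0, 20.0, 15.0],
      "center": [32.0, 25.0, 22.5],
      "angulation": {"t_s": 7.0, "t_c": 20.0, "rot": 15.0},
      "orientation": "LAS",
      "source": "dicom" | "manual"
    }

Coordinates in both formats are taken in the subject image's world frame;
vendor-private headers (e.g. Siemens CSA) are out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np

from .geometry import (
    Angulation,
    HomogeneousTransform,
    RigidTransform,
    AffineTransform9,
    VoxelSpec,
    angulation_from_rotation,
)
from .image import ImageVolume
from .rasterize import VoxelMask

if TYPE_CHECKING:  # pragma: no cover
    from .overlap import AcquiredVoxel

__all__ = [
    "VoxelGeometryError",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_acquired_voxel",
    "write_sidecar",
    "read_voxel_library",
    "append_voxel_record",
    "find_voxel_record",
    "write_transform",
    "read_transform",
]


class VoxelGeometryError(ValueError):
    """A voxel-geometry file is missing or contradicts required fields."""


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(path: str | Path) -> ImageVolume:
    """Load a 3D NIfTI-1 volume (gzip transparent) as an ImageVolume."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return ImageVolume(np.asarray(data, dtype=float), np.asarray(img.affine))


def write_volume(img: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(img.data.astype(np.float32), img.affine),
             str(path))


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a partial-volume mask as NIfTI-1 on its grid's world geometry."""
    nib.save(
        nib.Nifti1Image(mask.values.astype(np.float32), mask.grid.affine),
        str(path),
    )


# ---------------------------------------------------------------------------
# acquired-voxel geometry (DICOM / JSON sidecar)

_SIDECAR_FIELDS = ("subject_id", "timepoint", "dims", "center", "angulation",
                   "orientation")


def write_sidecar(av: "AcquiredVoxel", path: str | Path) -> None:
    """Write an acquired voxel as the JSON sidecar format."""
    spec = av.spec
    payload = {
        "subject_id": av.subject_id,
        "timepoint": av.timepoint,
        "study": spec.study,
        "description": spec.description,
        "dims": list(spec.dims),
        "center": list(spec.center),
        "angulation": {
            "t_s": spec.angulation.t_s,
            "t_c": spec.angulation.t_c,
            "rot": spec.angulation.rot,
        },
        "orientation": spec.orientation,
        "source": av.source,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _read_sidecar(path: Path) -> "AcquiredVoxel":
    from .overlap import AcquiredVoxel

    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise VoxelGeometryError(f"{path}: not valid JSON ({e})") from e
    missing = [k for k in _SIDECAR_FIELDS if k not in payload]
    if missing:
        raise VoxelGeometryError(f"{path}: sidecar missing fields {missing}")
    ang = payload["angulation"]
    try:
        spec = VoxelSpec(
            study=payload.get("study", ""),
            description=payload.get("description", ""),
            dims=tuple(payload["dims"]),
            center=tuple(payload["center"]),
            angulation=Angulation(ang["t_s"], ang["t_c"], ang["rot"]),
            orientation=payload["orientation"],
        )
    except (KeyError, TypeError, ValueError) as e:
        raise VoxelGeometryError(f"{path}: invalid sidecar geometry ({e})") from e
    return AcquiredVoxel(
        subject_id=str(payload["subject_id"]),
        timepoint=str(payload["timepoint"]),
        spec=spec,
        source=str(payload.get("source", "manual")),
    )


_DICOM_TAGS = {
    "SlabThickness": "(0018,9104)",
    "SlabOrientation": "(0018,9105)",
    "MidSlabPosition": "(0018,9106)",
}


def _read_dicom(path: Path, orientation: str) -> "AcquiredVoxel":
    import pydicom
    from pydicom.errors import InvalidDicomError

    from .overlap import AcquiredVoxel

    try:
        ds = pydicom.dcmread(str(path))
    except (InvalidDicomError, EOFError, OSError) as e:
        raise VoxelGeometryError(f"{path}: unreadable DICOM ({e})") from e

    seq = getattr(ds, "VolumeLocalizationSequence", None)
    if seq is None or len(seq) != 3:
        raise VoxelGeometryError(
            f"{path}: needs a 3-item VolumeLocalizationSequence (0018,9126); "
            f"got {0 if seq is None else len(seq)} items"
        )
    dims, axes, centers = [], [], []
    for i, item in enumerate(seq):
        missing = [t for t in _DICOM_TAGS if not hasattr(item, t)]
        if missing:
            tags = ", ".join(f"{t} {_DICOM_TAGS[t]}" for t in missing)
            raise VoxelGeometryError(
                f"{path}: slab {i} missing required tags: {tags}"
            )
        dims.append(float(item.SlabThickness))
        axes.append(np.asarray([float(v) for v in item.SlabOrientation]))
        centers.append(np.asarray([float(v) for v in item.MidSlabPosition]))
    r = np.stack(axes, axis=1)  # slab normals are the voxel axes (columns)
    if not np.allclose(r.T @ r, np.eye(3), atol=1e-3):
        raise VoxelGeometryError(
            f"{path}: slab orientations are not orthonormal (beyond 1e-3)"
        )
    if np.linalg.det(r) < 0:
        r[:, 2] = -r[:, 2]  # right-handed voxel frame; z slab sign is free
    center = centers[0]
    if not all(np.allclose(c, center, atol=1e-3) for c in centers[1:]):
        raise VoxelGeometryError(
            f"{path}: slab mid positions disagree: {[c.tolist() for c in centers]}"
        )
    # orthonormalize residual numerical error before decomposition
    u, _, vt = np.linalg.svd(r)
    ang = angulation_from_rotation(u @ vt)
    spec = VoxelSpec(
        study=str(getattr(ds, "StudyDescription", "")),
        description=str(getattr(ds, "SeriesDescription", "")),
        dims=tuple(dims),
        center=tuple(center),
        angulation=ang,
        orientation=orientation,
    )
    return AcquiredVoxel(
        subject_id=str(getattr(ds, "PatientID", "")),
        timepoint=str(getattr(ds, "StudyID", "")),
        spec=spec,
        source="dicom",
    )


def read_acquired_voxel(
    path: str | Path,
    subject_id: str | None = None,
    timepoint: str | None = None,
    subject_image: ImageVolume | None = None,
    orientation: str = "LAS",
) -> "AcquiredVoxel":
    """Read acquired-voxel geometry from a DICOM file or JSON sidecar.

    Dispatches on the ``.json`` extension.  Parse failures raise
    :class:`VoxelGeometryError` naming the absent fields; a partially
    populated record is never returned.
    """
    p = Path(path)
    if p.suffix.lower() == ".json":
        av = _read_sidecar(p)
    else:
        av = _read_dicom(p, orientation)
    if subject_id is not None:
        av.subject_id = subject_id
    if timepoint is not None:
        av.timepoint = timepoint
    av.subject_image = subject_image
    av.provenance = {"path": str(p)}
    return av


# ---------------------------------------------------------------------------
# voxel library (voxel_locations.txt)

_LIB_COLUMNS = ("study", "description", "dx", "dy", "dz", "cx", "cy", "cz",
                "t_s", "t_c", "rot", "orientation", "template_image_path")


def _record_to_line(spec: VoxelSpec, template_image_path: str) -> str:
    fields = [
        spec.study, spec.description,
        *(f"{v:g}" for v in spec.dims),
        *(f"{v:g}" for v in spec.center),
        *(f"{v:g}" for v in spec.angulation.as_tuple()),
        spec.orientation, template_image_path,
    ]
    return "\t".join(fields)


def read_voxel_library(path: str | Path) -> list[tuple[VoxelSpec, str]]:
    """Parse voxel_locations.txt into (spec, template_image_path) records.

    Tab-separated; lines starting with '#' are comments.
    """
    out: list[tuple[VoxelSpec, str]] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(_LIB_COLUMNS):
            raise VoxelGeometryError(
                f"{path}:{ln}: expected {len(_LIB_COLUMNS)} tab-separated "
                f"fields, got {len(parts)}"
            )
        spec = VoxelSpec(
            study=parts[0], description=parts[1],
            dims=tuple(float(v) for v in parts[2:5]),
            center=tuple(float(v) for v in parts[5:8]),
            angulation=Angulation(*(float(v) for v in parts[8:11])),
            orientation=parts[11],
        )
        out.append((spec, parts[12]))
    return out


def append_voxel_record(
    path: str | Path,
    spec: VoxelSpec,
    template_image_path: str,
    overwrite: bool = False,
) -> None:
    """Append (or replace, with ``overwrite``) a record in the voxel library.

    The library is keyed by (study, description); re-running a create for
    the same key without ``overwrite`` is an error.
    """
    path = Path(path)
    records: list[tuple[VoxelSpec, str]] = []
    if path.exists():
        records = read_voxel_library(path)
    key = (spec.study, spec.description)
    existing = [i for i, (s, _) in enumerate(records) if
                (s.study, s.description) == key]
    if existing and not overwrite:
        raise ValueError(
            f"library already has a record for study={spec.study!r} "
            f"description={spec.description!r}; pass overwrite to replace it"
        )
    for i in reversed(existing):
        records.pop(i)
    records.append((spec, template_image_path))
    lines = ["# " + "\t".join(_LIB_COLUMNS)]
    lines += [_record_to_line(s, t) for s, t in records]
    path.write_text("\n".join(lines) + "\n")


def find_voxel_record(
    path: str | Path, study: str, description: str
) -> tuple[VoxelSpec, str]:
    for spec, tmpl in read_voxel_library(path):
        if spec.study == study and spec.description == description:
            return spec, tmpl
    raise KeyError(f"no library record for study={study!r} "
                   f"description={description!r} in {path}")


# ---------------------------------------------------------------------------
# transforms


def write_transform(
    t: HomogeneousTransform,
    path: str | Path,
    moving: str = "",
    fixed: str = "",
) -> None:
    """Serialize a world-to-world transform as a row-major 4x4 text matrix."""
    header = f"# world-to-world mm transform; moving={moving} fixed={fixed}\n"
    body = "\n".join(
        " ".join(f"{v:.12g}" for v in row) for row in t.matrix
    )
    Path(path).write_text(header + body + "\n")


def read_transform(path: str | Path) -> HomogeneousTransform:
    """Read a 4x4 text transform, returning the most specific class that fits."""
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(v) for v in line.split()])
    m = np.asarray(rows, float)
    if m.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {m.shape}")
    for cls in (RigidTransform, AffineTransform9):
        try:
            return cls(m)
        except ValueError:
            continue
    return HomogeneousTransform(m)
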