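"""Synthetic head phantoms with known tissue maps and ground-truth motion.

The generator builds a T1-like head: nested ellipsoidal compartments (outer
CSF shell, GM ribbon, WM core) plus asymmetric internal structures
(ventricles, two off-center blobs) that break rotational symmetry so
intensity-based registration is well conditioned.  Partial-volume GM/WM/CSF
maps are constructed from the same analytic geometry, so ground-truth
tissue fractions inside any region are computable to arbitrary precision.
"Subject" scans are the template pulled through a known rigid (6-dof) or
rotation+scale (9-dof) transform with fresh Gaussian noise.

What this emulates: T1 contrast ordering (WM > GM > CSF), smooth intensity
variation (a mild multiplicative bias field), scanner noise, and realistic
head repositioning.  What it does not: cortical folding, skull/scalp
layers, MR physics, or inhomogeneity structure of real coils — phantom
results bound registration behaviour on clean geometry only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    AffineTransform9,
    HomogeneousTransform,
    RigidTransform,
    rotation_from_angulation,
)
from .image import ImageVolume
from .registration import resample_trilinear

__all__ = [
    "PhantomStudy",
    "PROFILES",
    "make_phantom",
    "perturb_subject",
    "make_study",
]

#: (shape, spacing mm) presets; both cover the same 192 mm field of view.
PROFILES = {
    "default": ((128, 128, 128), 1.5),
    "quick": ((96, 96, 96), 2.0),
}

# tissue T1-like mean intensities (arbitrary units, WM > GM > CSF)
_INTENSITY = {"csf": 0.25, "gm": 0.70, "wm": 1.00}
# head ellipsoid semi-axes (mm); sized so Table-1-scale shifts stay in FOV
_HEAD_AXES = np.array([52.0, 62.0, 48.0])
# normalized-radius boundaries of the WM core and GM ribbon
_RHO_WM, _RHO_GM = 0.72, 0.88


@dataclass
class PhantomStudy:
    """A template, its tissue maps, and perturbed subject scans."""

    template: ImageVolume
    pve: dict[str, ImageVolume]
    subjects: list[tuple[str, str, ImageVolume, HomogeneousTransform]]
    seed: int

    def ground_truth(self, subject_id: str, timepoint: str) -> HomogeneousTransform:
        for sid, tp, _, gt in self.subjects:
            if sid == subject_id and tp == timepoint:
                return gt
        raise KeyError((subject_id, timepoint))


def _compartment_fractions(pts: np.ndarray) -> np.ndarray:
    """Analytic (csf, gm, wm) occupancy at world points (..., 3).

    Membership is computed from the normalized ellipsoidal radius with a
    half-pixel-wide linear ramp at each boundary so per-pixel values behave
    like partial-volume fractions.
    """
    pts = np.asarray(pts, float)
    rho = np.sqrt(np.sum((pts / _HEAD_AXES) ** 2, axis=-1))
    # approximate mm distance per unit rho
    scale = float(np.mean(_HEAD_AXES))
    w = 1.0 / scale  # ~1 mm soft edge in rho units

    def inside(boundary: float) -> np.ndarray:
        return np.clip((boundary - rho) / w * 0.5 + 0.5, 0.0, 1.0)

    head = inside(1.0)
    wm = inside(_RHO_WM)
    gm_plus = inside(_RHO_GM)

    # ventricles: two CSF ellipsoids left/right of midline
    vent = np.zeros_like(rho)
    for sx in (-1.0, 1.0):
        c = np.array([14.0 * sx, -6.0, 4.0])
        ax = np.array([7.0, 18.0, 9.0])
        r = np.sqrt(np.sum(((pts - c) / ax) ** 2, axis=-1))
        vent = np.maximum(vent, np.clip((1.0 - r) * ax.mean() / 1.0 * 0.5 + 0.5,
                                        0.0, 1.0))
    # asymmetric blobs: a GM island in the WM core and a WM spur in the ribbon
    def blob(center, axes):
        r = np.sqrt(np.sum(((pts - np.asarray(center)) / np.asarray(axes)) ** 2,
                           axis=-1))
        return np.clip((1.0 - r) * np.mean(axes) * 0.5 + 0.5, 0.0, 1.0)

    gm_island = blob((18.0, 24.0, -12.0), (9.0, 11.0, 8.0))
    wm_spur = blob((-26.0, -22.0, 14.0), (10.0, 8.0, 9.0))

    wm_f = np.minimum(wm, head)
    gm_f = np.clip(gm_plus - wm, 0.0, 1.0) * head
    # carve structures
    wm_f = wm_f * (1.0 - vent) * (1.0 - gm_island)
    gm_f = gm_f * (1.0 - vent) * (1.0 - wm_spur) + gm_island * wm * (1.0 - vent)
    wm_f = wm_f + wm_spur * np.clip(gm_plus - wm, 0.0, 1.0) * head * (1.0 - vent)
    csf_f = np.clip(head - wm_f - gm_f, 0.0, 1.0)
    return np.stack([csf_f, gm_f, wm_f], axis=-1)


def make_phantom(
    shape: tuple[int, int, int] = PROFILES["default"][0],
    spacing: float = PROFILES["default"][1],
    seed: int = 0,
    noise_sigma: float = 0.02,
) -> tuple[ImageVolume, dict[str, ImageVolume]]:
    """Build a template head volume and its GM/WM/CSF partial-volume maps.

    ``noise_sigma`` is additive Gaussian noise expressed as a fraction of
    the WM intensity (default 2%).  The same seed always returns the same
    volume bit for bit.
    """
    shape = tuple(int(n) for n in shape)
    if min(shape) < 16:
        raise ValueError(f"degenerate phantom shape {shape}")
    spacing = float(spacing)
    affine = np.eye(4)
    affine[:3, :3] = np.diag([spacing] * 3)
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * spacing

    ax = [affine[i, i] * np.arange(shape[i]) + affine[i, 3] for i in range(3)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([x, y, z], axis=-1)
    frac = _compartment_fractions(pts)

    img = (frac[..., 0] * _INTENSITY["csf"]
           + frac[..., 1] * _INTENSITY["gm"]
           + frac[..., 2] * _INTENSITY["wm"])

    rng = np.random.default_rng(seed)
    # mild smooth multiplicative bias field (low-order cosines)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    amps = rng.uniform(0.01, 0.03, size=3)
    fov = np.asarray(shape) * spacing
    bias = 1.0
    for i, (w, a, ph) in enumerate(zip((x, y, z), amps, phases)):
        bias = bias * (1.0 + a * np.cos(2 * np.pi * w / fov[i] + ph))
    img = img * bias
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma * _INTENSITY["wm"], size=shape)

    template = ImageVolume(img, affine)
    pve = {
        "csf": ImageVolume(frac[..., 0], affine),
        "gm": ImageVolume(frac[..., 1], affine),
        "wm": ImageVolume(frac[..., 2], affine),
    }
    return template, pve


def perturb_subject(
    template: ImageVolume,
    transform: HomogeneousTransform,
    noise_sigma: float = 0.02,
    seed: int = 0,
) -> tuple[ImageVolume, HomogeneousTransform]:
    """Create a "subject" scan: template pulled through a known transform.

    ``transform`` maps template world to subject world, so the returned
    image holds ``template(transform^-1(x))`` plus fresh Gaussian noise.
    Warns (with an estimated clipped fraction) if the head leaves the
    field of view.
    """
    moved = resample_trilinear(template, transform, template)
    head = template.data > 0.5 * _INTENSITY["csf"]
    if head.any():
        ii = np.argwhere(head).astype(float)
        world = template.index_to_world(ii)
        mapped = transform.apply(world)
        lo, hi = template.world_bounds()
        out = np.any((mapped < lo) | (mapped > hi), axis=1)
        frac = float(out.mean())
        if frac > 0:
            warnings.warn(
                f"perturbation clips ~{100 * frac:.1f}% of the head outside "
                "the field of view",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    data = moved.data
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma * _INTENSITY["wm"],
                                 size=data.shape)
    return ImageVolume(data, moved.affine), transform


def random_rigid(
    rng: np.random.Generator,
    max_translation: float = 15.0,
    max_rotation: float = 15.0,
) -> RigidTransform:
    """A uniform random rigid perturbation about the head center."""
    angles = rng.uniform(-max_rotation, max_rotation, size=3)
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform.from_parts(
        rotation=rotation_from_angulation(angles), translation=t
    )


def make_study(
    seed: int = 0,
    n_subjects: int = 3,
    n_timepoints: int = 1,
    profile: str = "quick",
    max_translation: float = 12.0,
    max_rotation: float = 12.0,
    scale_jitter: float = 0.0,
    noise_sigma: float = 0.02,
) -> PhantomStudy:
    """A full synthetic study: one template, several perturbed subjects.

    Per subject/timepoint an independent rigid pose (uniform within
    ``max_translation`` mm / ``max_rotation`` deg) is drawn; with
    ``scale_jitter > 0`` anisotropic scales in [1 - j, 1 + j] emulate
    anatomical size differences (9-dof ground truth).
    """
    shape, spacing = PROFILES[profile]
    rng = np.random.default_rng(seed)
    template, pve = make_phantom(shape, spacing, seed=seed,
                                 noise_sigma=noise_sigma)
    subjects = []
    for s in range(n_subjects):
        for t in range(n_timepoints):
            gt: HomogeneousTransform = random_rigid(
                rng, max_translation, max_rotation
            )
            if scale_jitter > 0:
                scales = rng.uniform(1 - scale_jitter, 1 + scale_jitter, size=3)
                gt = AffineTransform9.from_parts(
                    rotation=gt.matrix[:3, :3],
                    scales=scales,
                    translation=gt.matrix[:3, 3]
                    - gt.matrix[:3, :3] @ np.zeros(3),
                )
            img, _ = perturb_subject(
                template, gt, noise_sigma=noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            subjects.append((f"sub-{s + 1:02d}", f"tp{t + 1}", img, gt))
    return PhantomStudy(template=template, pve=pve, subjects=subjects,
                        seed=seed)


def save_study(study: PhantomStudy, outdir: str | Path) -> None:
    """Write a study to disk: NIfTI volumes plus a ground-truth JSON."""
    from . import io as avpio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    avpio.write_volume(study.template, outdir / "template.nii.gz")
    for name, vol in study.pve.items():
        avpio.write_volume(vol, outdir / f"pve_{name}.nii.gz")
    gt = {}
    for sid, tp, img, t in study.subjects:
        avpio.write_volume(img, outdir / f"{sid}_{tp}_t1.nii.gz")
        gt[f"{sid}/{tp}"] = t.matrix.tolist()
    (outdir / "ground_truth.json").write_text(
        json.dumps({"seed": study.seed, "transforms": gt}, indent=2)
    )
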