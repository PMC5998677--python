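"""Voxel prescriptions, scanner angulation angles, and homogeneous transforms.

A single-voxel MRS prescription is a cuboid defined by its dimensions (mm),
its center coordinate in the image's world frame (mm), and three scanner
angulation angles: T>S (rotation about x), T>C (rotation about y) and
Rotation (about z).  One Euler convention is used everywhere in the package,
for both building rotation matrices from console angles and decomposing
registration results back into console angles:

    R = Rz(rot) @ Ry(t_c) @ Rx(t_s)

i.e. an intrinsic x -> y -> z sequence applied about the voxel center.
All world coordinates are millimetres in the frame defined by the image
header affine; voxel indices are 0-based; grids use the half-open extent
``[origin, origin + shape * spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Angulation",
    "VoxelSpec",
    "RigidTransform",
    "AffineTransform9",
    "HomogeneousTransform",
    "GimbalLockError",
    "canonical_angle",
    "rotation_from_angulation",
    "angulation_from_rotation",
    "delta_pose",
    "voxel_corners",
]

_AXIS_PAIRS = {"L": 0, "R": 0, "A": 1, "P": 1, "S": 2, "I": 2}


class GimbalLockError(ValueError):
    """Raised when an Euler decomposition is degenerate (|T>C| ~ 90 deg)."""


def canonical_angle(deg: float) -> float:
    """Map an angle in degrees to the canonical range (-180, 180].

    Ties at +/-180 resolve to +180, matching the signed angles printed on
    scanner consoles.
    """
    r = (float(deg) + 180.0) % 360.0 - 180.0
    if r == -180.0:
        r = 180.0
    return r


@dataclass(frozen=True)
class Angulation:
    """Scanner console angulation: T>S about x, T>C about y, Rotation about z.

    All angles are degrees and are canonicalized to (-180, 180] on
    construction.
    """

    t_s: float
    t_c: float
    rot: float

    def __post_init__(self) -> None:
        for name in ("t_s", "t_c", "rot"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"angulation {name} must be finite, got {v!r}")
            object.__setattr__(self, name, canonical_angle(v))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.t_s, self.t_c, self.rot)

    def __sub__(self, other: "Angulation") -> np.ndarray:
        return np.asarray(self.as_tuple()) - np.asarray(other.as_tuple())


def _validate_orientation(label: str) -> str:
    label = str(label).upper()
    if len(label) != 3 or any(c not in _AXIS_PAIRS for c in label):
        raise ValueError(f"invalid orientation label {label!r}")
    if sorted(_AXIS_PAIRS[c] for c in label) != [0, 1, 2]:
        raise ValueError(
            f"orientation label {label!r} must take one letter from each of "
            "L/R, A/P and S/I"
        )
    return label


@dataclass(frozen=True)
class VoxelSpec:
    """A complete single-voxel prescription.

    Attributes
    ----------
    study, description : str
        Library keys; a template library holds one record per
        (study, description) pair.
    dims : tuple of float
        Voxel edge lengths (dx, dy, dz) in mm, all strictly positive.
    center : tuple of float
        Voxel center in world mm of the named image frame.
    angulation : Angulation
        Console rotation angles, degrees.
    orientation : str
        Axis-order label of the image frame, e.g. ``"LAS"``.
    """

    study: str
    description: str
    dims: tuple[float, float, float]
    center: tuple[float, float, float]
    angulation: Angulation
    orientation: str = "LAS"

    def __post_init__(self) -> None:
        dims = tuple(float(d) for d in self.dims)
        center = tuple(float(c) for c in self.center)
        if len(dims) != 3 or len(center) != 3:
            raise ValueError("dims and center must be length-3")
        if not all(np.isfinite(dims)) or not all(np.isfinite(center)):
            raise ValueError("dims and center must be finite")
        if min(dims) <= 0:
            raise ValueError(f"voxel dims must be strictly positive, got {dims}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "orientation", _validate_orientation(self.orientation))
        if not isinstance(self.angulation, Angulation):
            object.__setattr__(self, "angulation", Angulation(*self.angulation))

    @property
    def nominal_volume(self) -> float:
        """Volume of the unrotated cuboid, mm^3 (dx*dy*dz)."""
        return float(np.prod(self.dims))

    @property
    def rotation(self) -> np.ndarray:
        return rotation_from_angulation(self.angulation)

    @property
    def is_rotated(self) -> bool:
        """True unless all three angles are zero within 1e-6 deg."""
        return bool(np.max(np.abs(self.angulation.as_tuple())) > 1e-6)

    def with_pose(
        self,
        center: Sequence[float] | None = None,
        angulation: Angulation | None = None,
    ) -> "VoxelSpec":
        out = self
        if center is not None:
            out = replace(out, center=tuple(float(c) for c in center))
        if angulation is not None:
            out = replace(out, angulation=angulation)
        return out


def rotation_from_angulation(a: Angulation | Sequence[float]) -> np.ndarray:
    """3x3 rotation matrix for console angles, R = Rz(rot) @ Ry(t_c) @ Rx(t_s)."""
    if not isinstance(a, Angulation):
        a = Angulation(*a)
    ts, tc, rz = np.deg2rad(a.as_tuple())
    ca, sa = np.cos(ts), np.sin(ts)
    cb, sb = np.cos(tc), np.sin(tc)
    cc, sc = np.cos(rz), np.sin(rz)
    return np.array(
        [
            [cb * cc, cc * sa * sb - ca * sc, sa * sc + ca * cc * sb],
            [cb * sc, ca * cc + sa * sb * sc, ca * sb * sc - cc * sa],
            [-sb, cb * sa, ca * cb],
        ]
    )


def _check_rotation(m: np.ndarray, tol: float) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
    if not np.allclose(m.T @ m, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal within tolerance")
    if np.linalg.det(m) < 0:
        raise ValueError("matrix is a reflection (det < 0), not a rotation")
    return m


def angulation_from_rotation(m: np.ndarray, tol: float = 1e-6) -> Angulation:
    """Recover console angles from a rotation matrix.

    Inverts :func:`rotation_from_angulation`.  Raises
    :class:`GimbalLockError` when T>C is within 0.01 deg of +/-90 deg, where
    T>S and Rotation are no longer separable.
    """
    m = _check_rotation(m, tol)
    # R[2,0] = -sin(t_c)
    s = float(np.clip(-m[2, 0], -1.0, 1.0))
    tc = np.rad2deg(np.arcsin(s))
    if 90.0 - abs(tc) < 0.01:
        raise GimbalLockError(
            f"T>C = {tc:.4f} deg is within 0.01 deg of gimbal lock; "
            "T>S and Rotation are not separable for this orientation"
        )
    ts = np.rad2deg(np.arctan2(m[2, 1], m[2, 2]))
    rz = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
    return Angulation(ts, tc, rz)


def delta_pose(a: VoxelSpec, b: VoxelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Componentwise pose difference b - a: (delta translation mm, delta rotation deg).

    Both prescriptions must live in the same image frame (matching
    orientation labels).  This is the bookkeeping convention used when
    tabulating head-position changes relative to a template.
    """
    if a.orientation != b.orientation:
        raise ValueError(
            f"cannot difference poses across frames: {a.orientation!r} vs "
            f"{b.orientation!r}"
        )
    dt = np.asarray(b.center, float) - np.asarray(a.center, float)
    dr = b.angulation - a.angulation
    return dt, dr


def voxel_corners(spec: VoxelSpec) -> np.ndarray:
    """The 8 world-coordinate corners (mm) of the prescribed cuboid.

    corners = center + R @ (+/-dx/2, +/-dy/2, +/-dz/2)
    """
    h = np.asarray(spec.dims, float) / 2.0
    signs = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )
    return np.asarray(spec.center, float) + (signs * h) @ spec.rotation.T


class HomogeneousTransform:
    """A general invertible 4x4 homogeneous world-to-world transform (mm)."""

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError(f"expected 4x4, got {matrix.shape}")
        if not np.allclose(matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("last row must be [0, 0, 0, 1]")
        if abs(np.linalg.det(matrix[:3, :3])) < 1e-12:
            raise ValueError("singular linear part")
        self.matrix = matrix

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.linear.T + self.translation

    def compose(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        """self after other: (self @ other).apply(p) == self.apply(other.apply(p))."""
        return HomogeneousTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        return self.compose(other)

    def inverse(self) -> "HomogeneousTransform":
        return HomogeneousTransform(np.linalg.inv(self.matrix))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(\n{np.array_str(self.matrix, precision=4)})"


class RigidTransform(HomogeneousTransform):
    """6-dof world-to-world transform: proper rotation plus translation."""

    _TOL = 1e-8

    def __init__(self, matrix: np.ndarray):
        super().__init__(matrix)
        r = self.matrix[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=self._TOL):
            raise ValueError("rigid transform rotation is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=self._TOL):
            raise ValueError("rigid transform must have det(R) = +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_parts(
        cls,
        rotation: np.ndarray | None = None,
        translation: Sequence[float] = (0.0, 0.0, 0.0),
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Build R about ``center`` followed by ``translation``:
        p -> R (p - c) + c + t."""
        r = np.eye(3) if rotation is None else _check_rotation(rotation, 1e-7)
        c = np.asarray(center, float)
        t = np.asarray(translation, float)
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = c + t - r @ c
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    def compose(self, other: HomogeneousTransform) -> HomogeneousTransform:
        out = HomogeneousTransform(self.matrix @ other.matrix)
        if isinstance(other, RigidTransform):
            return RigidTransform(out.matrix)
        return out

    def inverse(self) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = self.rotation.T
        m[:3, 3] = -self.rotation.T @ self.translation
        return RigidTransform(m)


class AffineTransform9(HomogeneousTransform):
    """9-dof world-to-world transform: rotation * anisotropic scale + translation.

    The linear part must polar-decompose as an orthonormal rotation times a
    diagonal positive scale (no shear), within 1e-6.
    """

    _TOL = 1e-6

    def __init__(self, matrix: np.ndarray):
        super().__init__(matrix)
        self._rotation, self._scales = self._decompose(self.matrix[:3, :3])

    @classmethod
    def _decompose(cls, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # polar decomposition A = R P; require P diagonal positive
        u, s, vt = np.linalg.svd(a)
        r = u @ vt
        if np.linalg.det(r) < 0:
            raise ValueError("9-dof linear part contains a reflection")
        p = vt.T @ np.diag(s) @ vt
        scales = np.diag(p).copy()
        if np.any(scales <= 0):
            raise ValueError("9-dof scales must be strictly positive")
        if not np.allclose(p, np.diag(scales), atol=cls._TOL * max(1.0, s.max())):
            raise ValueError(
                "9-dof linear part has shear: polar factor is not diagonal"
            )
        return r, scales

    @classmethod
    def from_parts(
        cls,
        rotation: np.ndarray | None = None,
        scales: Sequence[float] = (1.0, 1.0, 1.0),
        translation: Sequence[float] = (0.0, 0.0, 0.0),
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "AffineTransform9":
        """p -> R diag(s) (p - c) + c + t, scales anchored at ``center``."""
        r = np.eye(3) if rotation is None else _check_rotation(rotation, 1e-7)
        s = np.asarray(scales, float)
        c = np.asarray(center, float)
        t = np.asarray(translation, float)
        a = r @ np.diag(s)
        m = np.eye(4)
        m[:3, :3] = a
        m[:3, 3] = c + t - a @ c
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self._rotation

    @property
    def scales(self) -> np.ndarray:
        return self._scales
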