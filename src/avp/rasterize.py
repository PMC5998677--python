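"""Partial-volume rasterization of a voxel prescription onto a fine grid.

A rotated cuboid never lands exactly on pixel boundaries, so edge pixels
take fractional occupancy values in (0, 1) — the "partial volume problem".
Masks here are rendered on a regular grid (default 0.5 mm isotropic) with
each pixel holding the fraction of its volume inside the cuboid, estimated
by regular subdivision supersampling (default 5x5x5 subsamples per pixel;
interior and exterior pixels are classified exactly and skipped).

The threshold table then reports, for a lattice of pixel-intensity
thresholds, the superlevel-set volume as a percentage of the nominal
(unrotated) voxel volume — "Percent Total Voxel" — which drives threshold
selection for all overlap metrics: pick the threshold closest to, without
exceeding, 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import VoxelSpec, voxel_corners

__all__ = [
    "Grid",
    "VoxelMask",
    "ThresholdTable",
    "DEFAULT_THRESHOLDS",
    "rasterize_voxel",
    "threshold_table",
    "select_threshold",
]

#: Candidate pixel-intensity thresholds, 0.05 ... 0.95 in steps of 0.05.
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    np.round(np.arange(1, 20) * 0.05, 2)
)


@dataclass(frozen=True)
class Grid:
    """A regular sampling grid in world millimetres.

    ``origin`` is the world coordinate of the corner of pixel (0, 0, 0);
    pixel (i, j, k) covers the half-open box
    ``origin + [i, i+1) * spacing ...`` and its center sits at
    ``origin + (index + 0.5) * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "LAS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        spacing = self.spacing
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        object.__setattr__(self, "spacing", tuple(float(s) for s in spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if min(self.shape) < 1:
            raise ValueError(f"degenerate grid shape {self.shape}")
        if min(self.spacing) <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def pixel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """Index -> world affine (pixel centers), suitable for NIfTI export."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.spacing)
        return a

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, float)
        return lo, lo + np.asarray(self.shape, float) * np.asarray(self.spacing)

    def axes(self) -> list[np.ndarray]:
        """Pixel-center coordinates along each world axis."""
        return [
            self.origin[i] + (np.arange(self.shape[i]) + 0.5) * self.spacing[i]
            for i in range(3)
        ]

    @classmethod
    def for_spec(
        cls,
        spec: VoxelSpec,
        spacing: float = 0.5,
        margin: float = 2.0,
    ) -> "Grid":
        """Smallest spacing-aligned grid containing the (rotated) voxel.

        The grid is laid out so the voxel center falls on a pixel-boundary
        lattice point: an unrotated voxel whose dimensions are multiples of
        the spacing then covers whole pixels exactly.
        """
        return cls.for_specs([spec], spacing=spacing, margin=margin)

    @classmethod
    def for_specs(
        cls,
        specs: Sequence[VoxelSpec],
        spacing: float = 0.5,
        margin: float = 2.0,
    ) -> "Grid":
        """A common grid containing every listed voxel, anchored on the first."""
        if not specs:
            raise ValueError("need at least one spec")
        s = float(spacing)
        anchor = np.asarray(specs[0].center, float)
        corners = np.concatenate([voxel_corners(sp) for sp in specs], axis=0)
        lo = corners.min(axis=0) - margin
        hi = corners.max(axis=0) + margin
        n_lo = np.ceil((anchor - lo) / s).astype(int)
        n_hi = np.ceil((hi - anchor) / s).astype(int)
        origin = anchor - n_lo * s
        shape = tuple(int(a + b) for a, b in zip(n_lo, n_hi))
        return cls(shape=shape, spacing=(s, s, s), origin=tuple(origin),
                   orientation=specs[0].orientation)


@dataclass
class VoxelMask:
    """Partial-volume occupancy of one voxel prescription on a grid.

    ``values`` lie in [0, 1]; their sum times the pixel volume conserves the
    nominal voxel volume to well under 1%.
    """

    values: np.ndarray
    grid: Grid
    source: VoxelSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("mask values do not match grid shape")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("mask values must lie in [0, 1]")

    def count_above(self, threshold: float) -> int:
        """Number of pixels with value strictly greater than ``threshold``."""
        return int(np.count_nonzero(self.values > threshold))

    def volume_above(self, threshold: float) -> float:
        """Superlevel-set volume in mm^3 at ``threshold``."""
        return self.count_above(threshold) * self.grid.pixel_volume

    @property
    def partial_volume_total(self) -> float:
        """sum(values) * pixel_volume, the mask's conserved volume in mm^3."""
        return float(self.values.sum() * self.grid.pixel_volume)


@dataclass
class ThresholdTable:
    """Per-threshold superlevel pixel counts, volumes and Percent Total Voxel."""

    thresholds: np.ndarray
    pixel_counts: np.ndarray
    volumes: np.ndarray
    percent_total: np.ndarray
    nominal_volume: float

    def row(self, threshold: float) -> tuple[float, int, float, float]:
        i = int(np.argmin(np.abs(self.thresholds - threshold)))
        if abs(self.thresholds[i] - threshold) > 1e-9:
            raise KeyError(f"threshold {threshold} not in table")
        return (
            float(self.thresholds[i]),
            int(self.pixel_counts[i]),
            float(self.volumes[i]),
            float(self.percent_total[i]),
        )


def _subsample_offsets(spacing: np.ndarray, subdivisions: int) -> np.ndarray:
    frac = (np.arange(subdivisions) + 0.5) / subdivisions - 0.5
    ox, oy, oz = np.meshgrid(frac * spacing[0], frac * spacing[1],
                             frac * spacing[2], indexing="ij")
    return np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)


def rasterize_voxel(
    spec: VoxelSpec, grid: Grid, subdivisions: int = 5
) -> VoxelMask:
    """Render ``spec`` into a partial-volume mask on ``grid``.

    Pixels wholly inside (outside) the rotated cuboid get value 1 (0)
    exactly; boundary pixels get the inside fraction of a regular
    ``subdivisions**3`` subsample lattice.  Raises if any voxel corner
    falls outside the grid extent.
    """
    if subdivisions < 1:
        raise ValueError("subdivisions must be >= 1")
    lo, hi = grid.extent
    for corner in voxel_corners(spec):
        if np.any(corner < lo - 1e-9) or np.any(corner > hi + 1e-9):
            raise ValueError(
                f"voxel corner {np.round(corner, 3).tolist()} lies outside the "
                f"grid extent [{lo.tolist()}, {hi.tolist()}]"
            )

    spacing = np.asarray(grid.spacing, float)
    half = np.asarray(spec.dims, float) / 2.0
    rot = spec.rotation
    center = np.asarray(spec.center, float)

    ax = grid.axes()
    x, y, z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([x, y, z], axis=-1).reshape(-1, 3) - center
    local = pts @ rot  # == R.T @ p for each point
    # slab coordinate: positive outside, negative inside
    slab = np.max(np.abs(local) - half, axis=1)

    r = 0.5 * float(np.linalg.norm(spacing))  # pixel half-diagonal
    values = np.zeros(pts.shape[0])
    values[slab <= -r] = 1.0
    boundary = (slab > -r) & (slab < r)

    if np.any(boundary):
        b_pts = pts[boundary]
        offsets = _subsample_offsets(spacing, subdivisions)
        inside = np.zeros(b_pts.shape[0])
        for off in offsets:
            l = (b_pts + off) @ rot
            inside += np.all(np.abs(l) <= half, axis=1)
        values[boundary] = inside / len(offsets)

    return VoxelMask(values.reshape(grid.shape), grid, source=spec)


def threshold_table(
    mask: VoxelMask,
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
    nominal_volume: float | None = None,
) -> ThresholdTable:
    """Superlevel pixel counts/volumes over a threshold lattice.

    ``percent_total`` is 100 * volume / nominal unrotated voxel volume
    ("Percent Total Voxel").  Membership uses the strict inequality
    value > threshold.
    """
    th = np.asarray(sorted(thresholds), dtype=float)
    if th.size == 0:
        raise ValueError("empty threshold list")
    if np.any(th <= 0) or np.any(th >= 1):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    if nominal_volume is None:
        if mask.source is None:
            raise ValueError("mask has no source spec; pass nominal_volume")
        nominal_volume = mask.source.nominal_volume
    counts = np.array([mask.count_above(t) for t in th])
    volumes = counts * mask.grid.pixel_volume
    return ThresholdTable(
        thresholds=th,
        pixel_counts=counts,
        volumes=volumes,
        percent_total=100.0 * volumes / nominal_volume,
        nominal_volume=float(nominal_volume),
    )


def select_threshold(table: ThresholdTable, rotated: bool) -> float:
    """Pick the working pixel-intensity threshold from a threshold table.

    For a rotated voxel: the threshold whose Percent Total Voxel is closest
    to, without exceeding, 100%.  If every row exceeds 100% the row with the
    smallest Percent Total Voxel is returned with a warning.  For an
    unrotated voxel the highest lattice threshold (0.95) is returned.
    """
    if table.thresholds.size == 0:
        raise ValueError("empty threshold table")
    if not rotated:
        return float(table.thresholds[-1])
    ok = table.percent_total <= 100.0
    if not np.any(ok):
        warnings.warn(
            "no threshold keeps Percent Total Voxel at or below 100%; "
            "returning the least-exceeding threshold",
            stacklevel=2,
        )
        i = int(np.argmin(table.percent_total))
        return float(table.thresholds[i])
    pct = np.where(ok, table.percent_total, -np.inf)
    i = int(np.argmax(pct))
    return float(table.thresholds[i])
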