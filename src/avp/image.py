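"""In-memory 3D anatomical volume with its header affine."""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """A 3D scalar image plus its index -> world (mm) affine.

    ``data[i, j, k]`` is the intensity of the pixel whose center sits at
    ``affine @ (i, j, k, 1)`` in world millimetres.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("non-invertible header affine")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Pixel edge lengths (mm) along the three index axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def orientation(self) -> str:
        """Axis-order label (e.g. 'LAS') derived from the affine."""
        return "".join(nib.orientations.aff2axcodes(self.affine))

    @property
    def world_center(self) -> np.ndarray:
        """World coordinate of the geometric center of the volume."""
        c_idx = (np.asarray(self.shape, float) - 1.0) / 2.0
        return self.affine[:3, :3] @ c_idx + self.affine[:3, 3]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates of the half-open field of view."""
        corners_idx = np.array(
            [[i, j, k] for i in (-0.5, self.shape[0] - 0.5)
             for j in (-0.5, self.shape[1] - 0.5)
             for k in (-0.5, self.shape[2] - 0.5)]
        )
        w = self.index_to_world(corners_idx)
        return w.min(axis=0), w.max(axis=0)
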