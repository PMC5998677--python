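"""Intensity-based rigid (6-dof) and rotation+scale (9-dof) registration.

The pipeline needs one thing from a registry: the world-to-world transform
mapping the moving image's frame onto the fixed image's frame.  That
contract is a callable ``backend(moving, fixed, dof, init) ->
RegistrationResult`` so established registries can be dropped in
(:class:`SimpleITKBackend` wraps one); the built-in reference backend
maximizes a 32-bin correlation-ratio similarity with trilinear
interpolation over a 4x / 2x / 1x multi-resolution pyramid — a coarse
rotation grid search for global orientation, then derivative-free Powell
refinement per level.  There is no stochastic step: identical inputs give
identical transforms.

Transforms are parameterized about the fixed image's world center;
9-dof adds three log-scales (rotation * diagonal scale, no shear).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .geometry import (
    AffineTransform9,
    HomogeneousTransform,
    RigidTransform,
    rotation_from_angulation,
)
from .image import ImageVolume
from .rasterize import Grid

__all__ = [
    "ImageVolume",
    "RegistrationConfig",
    "RegistrationResult",
    "DegenerateImageError",
    "correlation_ratio",
    "resample_trilinear",
    "register",
    "CorrelationRatioBackend",
    "SimpleITKBackend",
]


class DegenerateImageError(ValueError):
    """Raised when an image carries no registrable signal (zero variance)."""


@dataclass(frozen=True)
class RegistrationConfig:
    """Tunables of the built-in correlation-ratio backend.

    Attributes
    ----------
    bins : int
        Intensity bins of the fixed image for the correlation ratio.
    pyramid : tuple of int
        Shrink factors of the multi-resolution schedule, coarse to fine.
    coarse_range_deg, coarse_step_deg : float
        Extent and step of the per-axis rotation grid searched at the
        coarsest level when no initial transform is supplied.
    max_samples : int
        Cap on fixed-image sample points per level (deterministic stride).
    xtol, ftol : float
        Powell convergence tolerances at the finest level (relaxed by the
        shrink factor at coarser levels).
    """

    bins: int = 32
    pyramid: tuple[int, ...] = (4, 2, 1)
    coarse_range_deg: float = 30.0
    coarse_step_deg: float = 10.0
    max_samples: int = 16000
    xtol: float = 3e-4
    ftol: float = 1e-8


@dataclass
class RegistrationResult:
    """Outcome of a registration: transform plus convergence metadata.

    ``transform`` maps moving-image world coordinates to fixed-image world
    coordinates.  ``similarity`` is the final correlation ratio (or the
    backend's own similarity, rescaled to be increasing-better).
    """

    transform: HomogeneousTransform
    converged: bool = True
    similarity: float = float("nan")
    message: str = ""


class RegistrationBackend(Protocol):
    def __call__(
        self,
        moving: ImageVolume,
        fixed: ImageVolume,
        dof: int,
        init: HomogeneousTransform | None = None,
    ) -> RegistrationResult: ...


def correlation_ratio(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Correlation ratio eta^2(b | a): how well a's intensity bins predict b.

    1 - sum_k n_k Var_k(b) / (N Var(b)) over equal-width bins k of ``a``.
    Equals 1 when b is a deterministic function of a's bin, and ~0 for
    independent samples.  Returns 0 (with a warning) when b has zero
    variance.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size:
        raise ValueError("samples must have equal length")
    if a.size < 2 * bins:
        raise ValueError(f"need at least {2 * bins} samples for {bins} bins")
    var_b = b.var()
    if var_b <= 0:
        warnings.warn("zero variance in dependent sample; correlation ratio "
                      "defined as 0", stacklevel=2)
        return 0.0
    lo, hi = a.min(), a.max()
    if hi <= lo:
        warnings.warn("constant binning sample; correlation ratio defined "
                      "as 0", stacklevel=2)
        return 0.0
    idx = np.minimum((bins * (a - lo) / (hi - lo)).astype(int), bins - 1)
    n_k = np.bincount(idx, minlength=bins)
    s_k = np.bincount(idx, weights=b, minlength=bins)
    q_k = np.bincount(idx, weights=b * b, minlength=bins)
    nz = n_k > 0
    within = float(np.sum(q_k[nz] - s_k[nz] ** 2 / n_k[nz]))
    return 1.0 - within / (b.size * var_b)


def resample_trilinear(
    img: ImageVolume,
    transform: HomogeneousTransform | None,
    target: "Grid | ImageVolume",
) -> ImageVolume:
    """Resample ``img`` onto ``target`` through a world-to-world transform.

    ``transform`` maps img-world to target-world; each target pixel takes
    the trilinearly interpolated intensity of ``img`` at the pulled-back
    location of its center.  Out-of-field locations are 0.
    """
    if isinstance(target, Grid):
        t_shape = target.shape
        t_affine = target.affine
    else:
        t_shape = target.shape
        t_affine = target.affine
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in t_shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    world = idx @ t_affine[:3, :3].T + t_affine[:3, 3]
    if transform is not None:
        world = world @ np.linalg.inv(transform.matrix)[:3, :3].T \
            + np.linalg.inv(transform.matrix)[:3, 3]
    inv_a = np.linalg.inv(img.affine)
    src_idx = world @ inv_a[:3, :3].T + inv_a[:3, 3]
    out = ndimage.map_coordinates(
        img.data, src_idx.T, order=1, mode="constant", cval=0.0
    )
    return ImageVolume(out.reshape(t_shape), t_affine)


# ---------------------------------------------------------------------------
# built-in correlation-ratio backend


def _params_to_matrix(params: np.ndarray, dof: int, center: np.ndarray) -> np.ndarray:
    """(rx, ry, rz deg, tx, ty, tz [, log s]) -> 4x4 about ``center``."""
    r = rotation_from_angulation(params[:3])
    a = r if dof == 6 else r @ np.diag(np.exp(params[6:9]))
    m = np.eye(4)
    m[:3, :3] = a
    m[:3, 3] = center + params[3:6] - a @ center
    return m


def _matrix_to_params(matrix: np.ndarray, dof: int, center: np.ndarray) -> np.ndarray:
    from .geometry import angulation_from_rotation

    a = matrix[:3, :3]
    if dof == 9:
        u, s, vt = np.linalg.svd(a)
        rot = u @ vt
        scales = np.diag(vt.T @ np.diag(s) @ vt)
    else:
        u, _, vt = np.linalg.svd(a)
        rot = u @ vt
        scales = None
    ang = angulation_from_rotation(rot, tol=1e-5)
    t = matrix[:3, 3] - center + matrix[:3, :3] @ center
    out = [*ang.as_tuple(), *t]
    if dof == 9:
        out.extend(np.log(scales))
    return np.asarray(out, float)


class _Level:
    """Fixed-image samples and a smoothed moving image at one pyramid level."""

    def __init__(self, moving: ImageVolume, fixed: ImageVolume,
                 shrink: int, cfg: RegistrationConfig):
        sigma = shrink / 2.0 if shrink > 1 else 0.0
        fdata = fixed.data
        if sigma > 0:
            fdata = ndimage.gaussian_filter(fdata, sigma)
        sl = tuple(slice(shrink // 2, None, shrink) for _ in range(3))
        ii, jj, kk = np.meshgrid(
            *(np.arange(n)[s] for n, s in zip(fixed.shape, sl)), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        if idx.shape[0] > cfg.max_samples:
            stride = int(np.ceil(idx.shape[0] / cfg.max_samples))
            idx = idx[::stride]
        # jitter sample positions by a fixed pseudo-random subpixel offset:
        # pinned-to-lattice samples let the cost reward subpixel
        # misalignment (trilinear interpolation smooths the pulled-back
        # moving intensities, shrinking within-bin variance) whenever the
        # two images share pixel-level structure, e.g. self-registration
        jitter = np.random.default_rng(12345).uniform(-0.5, 0.5,
                                                      size=idx.shape)
        idx = np.clip(idx.astype(float) + jitter, 0.0,
                      np.asarray(fixed.shape, float) - 1.0)
        vals = ndimage.map_coordinates(fdata, idx.T, order=1)
        self.pts = idx @ fixed.affine[:3, :3].T + fixed.affine[:3, 3]
        self.n = vals.size
        lo, hi = vals.min(), vals.max()
        if hi <= lo:
            raise DegenerateImageError("fixed image is constant at this level")
        self.bin_idx = np.minimum(
            (cfg.bins * (vals - lo) / (hi - lo)).astype(int), cfg.bins - 1
        )
        self.n_k = np.bincount(self.bin_idx, minlength=cfg.bins)
        self.bins = cfg.bins

        mdata = moving.data
        if sigma > 0:
            mdata = ndimage.gaussian_filter(mdata, sigma)
        self.moving = mdata
        self.inv_moving_affine = np.linalg.inv(moving.affine)

    def cost(self, matrix: np.ndarray) -> float:
        """1 - correlation ratio of moving intensities given fixed bins."""
        inv = np.linalg.inv(matrix)
        pulled = self.pts @ inv[:3, :3].T + inv[:3, 3]
        src = pulled @ self.inv_moving_affine[:3, :3].T + self.inv_moving_affine[:3, 3]
        b = ndimage.map_coordinates(self.moving, src.T, order=1,
                                    mode="constant", cval=0.0)
        var_b = b.var()
        if var_b <= 0:
            return 1.0
        s_k = np.bincount(self.bin_idx, weights=b, minlength=self.bins)
        q_k = np.bincount(self.bin_idx, weights=b * b, minlength=self.bins)
        nz = self.n_k > 0
        within = np.sum(q_k[nz] - s_k[nz] ** 2 / self.n_k[nz])
        return float(within / (self.n * var_b))


def _centroid(img: ImageVolume) -> np.ndarray:
    w = img.data - img.data.min()
    thr = w.mean()
    w = np.where(w > thr, w, 0.0)
    if w.sum() <= 0:
        return img.world_center
    com = np.array(ndimage.center_of_mass(w))
    return img.affine[:3, :3] @ com + img.affine[:3, 3]


class CorrelationRatioBackend:
    """Built-in deterministic correlation-ratio registry."""

    def __init__(self, config: RegistrationConfig | None = None):
        self.config = config or RegistrationConfig()

    def __call__(
        self,
        moving: ImageVolume,
        fixed: ImageVolume,
        dof: int,
        init: HomogeneousTransform | None = None,
    ) -> RegistrationResult:
        if dof not in (6, 9):
            raise ValueError(f"dof must be 6 or 9, got {dof}")
        for name, img in (("moving", moving), ("fixed", fixed)):
            if img.data.var() <= 0:
                raise DegenerateImageError(f"{name} image has zero intensity "
                                           "variance")
        cfg = self.config
        center = fixed.world_center

        if dof == 9 and init is None:
            rigid = self(moving, fixed, dof=6)
            init = rigid.transform

        if init is not None:
            params = _matrix_to_params(init.matrix, dof, center)
        else:
            t0 = _centroid(fixed) - _centroid(moving)
            params = np.zeros(6)
            params[3:6] = t0

        pyramid = cfg.pyramid
        if init is not None and len(pyramid) > 1:
            pyramid = pyramid[1:]  # warm start: coarse global stage not needed
        levels = [_Level(moving, fixed, s, cfg) for s in pyramid]
        identity_cost = levels[-1].cost(np.eye(4))

        if init is None and dof == 6 and cfg.coarse_step_deg > 0:
            params = self._coarse_search(levels[0], params, center)

        for shrink, level in zip(pyramid, levels):
            fun = lambda p: level.cost(_params_to_matrix(p, dof, center))
            res = minimize(
                fun,
                params,
                method="Powell",
                options={
                    "xtol": cfg.xtol * shrink,
                    "ftol": cfg.ftol * shrink,
                    "maxiter": 200,
                },
            )
            params = res.x

        final_cost = levels[-1].cost(_params_to_matrix(params, dof, center))
        matrix = _params_to_matrix(params, dof, center)
        transform: HomogeneousTransform
        if dof == 6:
            transform = RigidTransform(matrix)
        else:
            transform = AffineTransform9(matrix)
        converged = final_cost < identity_cost + 1e-6
        msg = ""
        if not converged:
            msg = ("registration did not improve on the identity transform; "
                   "treat the result with suspicion")
            warnings.warn(msg, stacklevel=2)
        return RegistrationResult(
            transform=transform,
            converged=converged,
            similarity=1.0 - final_cost,
            message=msg,
        )

    def _coarse_search(self, level: _Level, params: np.ndarray,
                       center: np.ndarray) -> np.ndarray:
        cfg = self.config
        grid = np.arange(-cfg.coarse_range_deg, cfg.coarse_range_deg + 1e-9,
                         cfg.coarse_step_deg)
        best = params.copy()
        best_cost = level.cost(_params_to_matrix(params, 6, center))
        for rx in grid:
            for ry in grid:
                for rz in grid:
                    p = params.copy()
                    p[:3] = (rx, ry, rz)
                    c = level.cost(_params_to_matrix(p, 6, center))
                    if c < best_cost:
                        best_cost, best = c, p
        return best


class SimpleITKBackend:
    """Adapter running registration through SimpleITK (if installed).

    Used as an interchangeable backend behind the same contract; images are
    handed over in the package's own world frame, and the resampling
    transform SimpleITK returns (fixed -> moving points) is inverted into
    the contract's moving-world -> fixed-world convention.
    """

    def __init__(self, sampling_fraction: float = 0.5):
        self.sampling_fraction = sampling_fraction

    def __call__(
        self,
        moving: ImageVolume,
        fixed: ImageVolume,
        dof: int,
        init: HomogeneousTransform | None = None,
    ) -> RegistrationResult:
        import SimpleITK as sitk

        def to_sitk(img: ImageVolume) -> "sitk.Image":
            arr = np.ascontiguousarray(np.transpose(img.data, (2, 1, 0)))
            out = sitk.GetImageFromArray(arr.astype(np.float64))
            spacing = img.spacing
            direction = img.affine[:3, :3] / spacing
            out.SetSpacing(tuple(float(s) for s in spacing))
            out.SetOrigin(tuple(float(o) for o in img.affine[:3, 3]))
            out.SetDirection(tuple(direction.ravel()))
            return out

        f_img, m_img = to_sitk(fixed), to_sitk(moving)
        center = tuple(float(c) for c in fixed.world_center)
        if dof == 6:
            tx = sitk.Euler3DTransform()
            tx.SetCenter(center)
        else:
            tx = sitk.ScaleVersor3DTransform()
            tx.SetCenter(center)

        if init is not None:
            # initialize translation from the supplied transform
            inv = np.linalg.inv(init.matrix)
            tx.SetTranslation(tuple(
                (inv[:3, :3] @ np.asarray(center) + inv[:3, 3]) - np.asarray(center)
            ))

        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsCorrelation()
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(self.sampling_fraction)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsPowell(numberOfIterations=100, stepLength=1.0,
                                 valueTolerance=1e-9, stepTolerance=1e-6)
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
        reg.SetInitialTransform(tx, inPlace=True)
        reg.Execute(f_img, m_img)

        # sitk transform maps fixed-world -> moving-world (resampling);
        # invert to the contract's moving -> fixed.
        a = np.eye(4)
        mat = np.asarray(tx.GetMatrix()).reshape(3, 3)
        c = np.asarray(tx.GetCenter())
        t = np.asarray(tx.GetTranslation())
        a[:3, :3] = mat
        a[:3, 3] = c + t - mat @ c
        matrix = np.linalg.inv(a)
        transform: HomogeneousTransform
        try:
            transform = RigidTransform(matrix) if dof == 6 \
                else AffineTransform9(matrix)
        except ValueError:
            transform = HomogeneousTransform(matrix)
        return RegistrationResult(
            transform=transform,
            converged=True,
            similarity=float(-reg.GetMetricValue()),
            message=f"SimpleITK: {reg.GetOptimizerStopConditionDescription()}",
        )


def register(
    moving: ImageVolume,
    fixed: ImageVolume,
    dof: int = 6,
    backend: RegistrationBackend | None = None,
    init: HomogeneousTransform | None = None,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Estimate the moving-world -> fixed-world transform between two volumes.

    ``dof=6`` returns a :class:`~avp.geometry.RigidTransform`; ``dof=9`` a
    :class:`~avp.geometry.AffineTransform9` (rotation + positive anisotropic
    scale about the fixed image's center + translation).
    """
    if backend is None:
        backend = CorrelationRatioBackend(config)
    return backend(moving, fixed, dof, init=init)
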