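"""Forward model: mass-preserving elastic deformation and parallel-beam projection.

Sinograms are stored rows = projection angles, columns = detector position
(0-based; detector centre column = W // 2 on the odd-sized default grids).
Projection uses scikit-image's rotate-and-sum Radon transform with bilinear
interpolation; elastic frames are produced by an inverse-mapped bilinear
affine warp, renormalized so the total MAC of the specimen stays exactly
constant as it deforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import radon as _sk_radon

from .phantom import AngleGrid, MotionModel, Phantom

__all__ = ["Sinogram", "deform_frame", "project_elastic", "radon"]


@dataclass
class Sinogram:
    """Angle-by-detector array of parallel-beam line integrals."""

    data: np.ndarray
    angle_grid: AngleGrid
    detector_pitch: float = 1.0
    cor_col: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2-D")
        if self.data.shape[0] != len(self.angle_grid):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.angle_grid)} angles"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram data must be finite")
        if self.detector_pitch <= 0:
            raise ValueError("detector_pitch must be positive")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def center_col(self) -> float:
        return (self.width - 1) / 2.0

    def row_mass(self) -> np.ndarray:
        """Per-angle total attenuation (row sum x pitch); constant for any
        mass-preserving specimen."""
        return self.data.sum(axis=1) * self.detector_pitch

    def copy_with(self, **kw) -> "Sinogram":
        return replace(self, **kw)


def _scaling_matrix_rc(a: float, b: float, axis_angle_deg: float) -> np.ndarray:
    """Symmetric 2x2 scaling in (row, col) coordinates: factor ``a`` along
    the axis at ``axis_angle_deg`` (projection-angle convention, y up) and
    ``b`` perpendicular to it."""
    ps = np.radians(axis_angle_deg)
    R = np.array([[np.cos(ps), -np.sin(ps)], [np.sin(ps), np.cos(ps)]])
    S_xy = R @ np.diag([a, b]) @ R.T
    P = np.array([[0.0, -1.0], [1.0, 0.0]])  # (row, col) = P @ (x, y)
    return P @ S_xy @ P.T


def deform_frame(phantom_or_image, motion: MotionModel, i: int) -> np.ndarray:
    """Specimen frame at projection index ``i``.

    f_i(x) = f(A_i^{-1}(x - p) + p) / (a_i b_i) with A_i the anisotropic
    scaling about the deformation fixed point p; the density factor keeps
    the total MAC constant while the support scales.  Resampling is
    inverse-mapped bilinear; because bilinear minification does not
    conserve mass exactly, the frame is renormalized to the source's total
    MAC (the constant-mass assumption holds exactly by construction; the
    specimen is assumed to remain inside the field of view).
    """
    if isinstance(phantom_or_image, Phantom):
        image = phantom_or_image.image
    else:
        image = np.asarray(phantom_or_image, dtype=float)
    if not (0 <= i < len(motion)):
        raise IndexError(f"angle index {i} outside motion schedule of length {len(motion)}")
    a, b = float(motion.a[i]), float(motion.b[i])
    if a == 1.0 and b == 1.0:
        return image.copy()
    H, W = image.shape
    p = motion.center
    if p is None:
        p = ((H - 1) / 2.0, (W - 1) / 2.0)
    p = np.asarray(p, dtype=float)
    M = np.linalg.inv(_scaling_matrix_rc(a, b, motion.axis_angle_deg))
    offset = p - M @ p
    out = ndimage.affine_transform(image, M, offset=offset, order=1, mode="constant")
    out /= a * b
    total = out.sum()
    if total > 0:
        out *= image.sum() / total
    return out


def _project_one(image: np.ndarray, theta_deg: float) -> np.ndarray:
    return _sk_radon(image, theta=[theta_deg], circle=True)[:, 0]


def radon(image: np.ndarray, angle_grid: AngleGrid, detector_pitch: float = 1.0) -> Sinogram:
    """Parallel-beam Radon transform about the grid centre.

    A fixed point at (row, col) traces the sinusoid
    u(theta) = c + (col - c) cos(theta) - (row - c) sin(theta), c = W // 2.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("radon expects a square 2-D image")
    data = _sk_radon(image, theta=angle_grid.angles, circle=True).T
    return Sinogram(data, angle_grid, detector_pitch, cor_col=image.shape[1] // 2)


def project_elastic(
    phantom_or_image,
    motion: MotionModel,
    angle_grid: AngleGrid,
    detector_pitch: float = 1.0,
) -> Sinogram:
    """Elastic-type sinogram: row i projects the deformed frame at angle i.

    With rigid motion this is the plain Radon transform.  Because each
    frame preserves total MAC, every row of the output carries the same
    mass (up to interpolation error) even while the sinusoid amplitude
    shrinks with the specimen.
    """
    if isinstance(phantom_or_image, Phantom):
        image = phantom_or_image.image
    else:
        image = np.asarray(phantom_or_image, dtype=float)
    n = len(angle_grid)
    if len(motion) != n:
        raise ValueError(f"motion schedule length {len(motion)} != {n} angles")
    if np.all(motion.a == 1.0) and np.all(motion.b == 1.0):
        return radon(image, angle_grid, detector_pitch)
    rows = np.empty((n, image.shape[1]))
    for i, th in enumerate(angle_grid.angles):
        rows[i] = _project_one(deform_frame(image, motion, i), th)
    return Sinogram(rows, angle_grid, detector_pitch, cor_col=image.shape[1] // 2)
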