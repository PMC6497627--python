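"""Fixed-point trajectories, sinusoid fitting, and COR centering.

A material fixed point of a rigid (or rigid-converted) specimen traces
u(θ) = c + r·cos(θ − φ) across the sinogram, where c is the projected
rotation-axis column (COR), r the point's distance from the axis and φ its
azimuth.  Fitting that sinusoid to a tracked marker yields the COR and the
angle at which the trajectory crosses it; padding the detector axis then
puts the COR on the centre column as filtered back projection requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import AngleGrid
from .projector import Sinogram

__all__ = [
    "MarkerTrajectory",
    "TrajectoryFit",
    "TrackingError",
    "center_cor",
    "fit_trajectory",
    "point_trajectory_fit",
    "track_marker",
    "trajectory_value",
    "zero_crossing_angle",
]


class TrackingError(RuntimeError):
    """Marker lost in too many sinogram rows."""


@dataclass
class MarkerTrajectory:
    """Per-angle detector coordinate of a tracked fixed point."""

    u: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.u.shape != self.valid.shape or self.u.ndim != 1:
            raise ValueError("u and valid must be 1-D and equal length")

    def __len__(self) -> int:
        return len(self.u)


@dataclass(frozen=True)
class TrajectoryFit:
    """Sinusoid parameters u(θ) = c + r·cos(θ − φ)."""

    c: float  # COR offset, detector pixels (absolute column)
    r: float  # amplitude, pixels, >= 0
    phi_deg: float  # phase, degrees, in [0, 360)
    rms_residual: float = 0.0

    def __post_init__(self):
        if self.r < 0:
            raise ValueError("amplitude r must be >= 0")
        object.__setattr__(self, "phi_deg", float(self.phi_deg) % 360.0)

    def __call__(self, theta_deg) -> np.ndarray:
        return self.c + trajectory_value(self.r, self.phi_deg, theta_deg)


def trajectory_value(r: float, phi_deg: float, theta_deg) -> np.ndarray:
    """Detector offset r·cos(θ − φ) of a fixed point at projection angle θ."""
    return r * np.cos(np.radians(np.asarray(theta_deg, dtype=float) - phi_deg))


def point_trajectory_fit(row: float, col: float, width: int) -> TrajectoryFit:
    """Exact trajectory of a known image point under the projector's
    geometry: c = W//2, r = distance from the grid centre,
    φ = atan2(centre_row − row, col − centre_col)."""
    cen = width // 2
    X, Y = col - cen, row - cen
    return TrajectoryFit(float(cen), float(np.hypot(X, Y)), float(np.degrees(np.arctan2(-Y, X))))


def track_marker(
    sino: Sinogram,
    seed_window: tuple[int, int],
    half_width: int = 15,
    threshold_frac: float = 0.5,
    max_lost_frac: float = 0.10,
) -> MarkerTrajectory:
    """Follow one marker down the sinogram by windowed centroids.

    Row 0 searches ``seed_window`` (inclusive column interval); each later
    row searches a ±half_width window recentred on the previous estimate.
    Within the window, pixels above ``threshold_frac`` of the (min-
    subtracted) local maximum contribute to an intensity-weighted centroid;
    min subtraction makes the tracker tolerate a slowly varying background
    under the marker bump.  Rows with an empty window or zero local
    contrast are flagged invalid; losing more than ``max_lost_frac`` of the
    rows raises TrackingError.
    """
    lo, hi = seed_window
    if hi < lo:
        raise ValueError("seed window is empty")
    n, W = sino.data.shape
    u = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    prev = None
    for i in range(n):
        if prev is None:
            a, b = max(0, lo), min(W - 1, hi)
        else:
            a = max(0, int(round(prev)) - half_width)
            b = min(W - 1, int(round(prev)) + half_width)
        win = sino.data[i, a : b + 1]
        if win.size == 0:
            continue
        base = win.min()
        contrast = win.max() - base
        if contrast <= 0:
            continue
        # weights are the excess over the threshold level, so the centroid
        # varies continuously as the blob moves across pixel boundaries
        w = np.maximum(win - base - threshold_frac * contrast, 0.0)
        tot = w.sum()
        if tot <= 0:
            continue
        u[i] = a + float(np.arange(win.size) @ w) / tot
        valid[i] = True
        prev = u[i]
    lost = 1.0 - valid.mean()
    if lost > max_lost_frac:
        raise TrackingError(
            f"marker lost in {lost:.0%} of rows (limit {max_lost_frac:.0%})"
        )
    return MarkerTrajectory(u, valid)


def fit_trajectory(traj: MarkerTrajectory, grid: AngleGrid) -> TrajectoryFit:
    """Least-squares sinusoid through the valid samples.

    Linear model u(θ) = c + A·cosθ + B·sinθ; then r = √(A²+B²),
    φ = atan2(B, A).  Needs ≥ 3 valid samples at ≥ 3 distinct angles.
    """
    if len(traj) != len(grid):
        raise ValueError("trajectory and angle grid lengths differ")
    th = np.radians(grid.angles[traj.valid])
    u = traj.u[traj.valid]
    if u.size < 3 or np.unique(th).size < 3:
        raise ValueError("need >= 3 valid samples at >= 3 distinct angles")
    X = np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])
    coef, *_ = np.linalg.lstsq(X, u, rcond=None)
    c, A, B = coef
    resid = u - X @ coef
    r = float(np.hypot(A, B))
    phi = float(np.degrees(np.arctan2(B, A)))
    return TrajectoryFit(float(c), r, phi, float(np.sqrt(np.mean(resid**2))))


def zero_crossing_angle(fit: TrajectoryFit) -> float:
    """Projection angle in [0°, 180°) at which the trajectory crosses the COR.

    r·cos(θ − φ) = 0 at θ = φ ± 90°; folded into [0, 180) this is
    (φ + 90°) mod 180°.  Equivalently: (angle of the trajectory minimum
    − 90°) mod 180°, since the minimum sits at φ + 180°.
    """
    if fit.r <= 0:
        raise ValueError("crossing angle undefined for a zero-amplitude trajectory")
    return (fit.phi_deg + 90.0) % 180.0


def center_cor(sino: Sinogram, cor_col: float | None = None) -> Sinogram:
    """Pad zero detector columns so the COR lands on the centre column.

    p = round(W − 1 − 2·cor): pad p columns on the low side if p > 0, |p|
    on the high side if p < 0.  Data values are untouched, so mass and
    every nonzero pixel are preserved exactly.
    """
    if cor_col is None:
        cor_col = sino.cor_col
    if cor_col is None:
        raise ValueError("no COR supplied and none stored on the sinogram")
    W = sino.width
    if not (0 <= cor_col < W):
        raise ValueError(f"COR column {cor_col} outside detector [0, {W})")
    p = int(round(W - 1 - 2 * cor_col))
    if p == 0:
        return sino.copy_with(cor_col=float(cor_col))
    if p > 0:
        data = np.pad(sino.data, ((0, 0), (p, 0)))
        new_cor = cor_col + p
    else:
        data = np.pad(sino.data, ((0, 0), (0, -p)))
        new_cor = float(cor_col)
    return sino.copy_with(data=data, cor_col=float(new_cor))
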