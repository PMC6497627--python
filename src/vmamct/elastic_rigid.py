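"""Elastic-to-rigid sinogram conversion and scale-coefficient estimation.

A mass-preserving isotropic contraction by s turns the projection P of the
reference specimen into E(θ, τ) = (1/s)·P(θ, τ/s) about the projected
deformation centre, so the rigid-type row is recovered as s·E(θ, s·τ).
Anisotropic (elliptic) motion additionally warps the effective projection
angle: with θ̃ = θ − ψ, w = sqrt(a²cos²θ̃ + b²sin²θ̃) and
θ′ = ψ + atan2(b·sinθ̃, a·cosθ̃), the elastic row at θ is the rigid row at
θ′ rescaled by w.  Converted rows therefore sit on a non-uniform angle
grid and are resampled back to a uniform one.

Scale coefficients need not be known a priori: the ratio of the projected
separation of two fixed markers to its reference sinusoid recovers the
per-angle scale, one marker pair per principal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import AngleGrid, MotionModel
from .projector import Sinogram
from .trajectory import MarkerTrajectory, TrajectoryFit

__all__ = [
    "ScaleSeries",
    "WarpedRows",
    "convert_elliptic",
    "convert_regular",
    "estimate_scale_elliptic",
    "estimate_scale_regular",
    "resample_angles",
    "select_periodic",
]


@dataclass
class ScaleSeries:
    """Per-angle scale estimates; masked (invalid) entries are interpolated."""

    a: np.ndarray
    b: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.a.shape == self.b.shape == self.valid.shape) or self.a.ndim != 1:
            raise ValueError("a, b, valid must be 1-D and equal length")
        if np.any(self.a[self.valid] <= 0) or np.any(self.b[self.valid] <= 0):
            raise ValueError("valid scales must be positive")

    def __len__(self) -> int:
        return len(self.a)


@dataclass
class WarpedRows:
    """Rigid-type detector profiles attached to warped (non-uniform) angles."""

    rows: np.ndarray
    warped_angles: np.ndarray

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        self.warped_angles = np.asarray(self.warped_angles, dtype=float)
        if self.rows.shape[0] != self.warped_angles.shape[0]:
            raise ValueError("row count and warped angle count differ")


def _as_ab(scales, n: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalize MotionModel | ScaleSeries to per-angle (a, b, axis angle)."""
    if isinstance(scales, MotionModel):
        a, b, psi = scales.a, scales.b, scales.axis_angle_deg
    elif isinstance(scales, ScaleSeries):
        a, b, psi = scales.a, scales.b, 0.0
    else:
        raise TypeError("scales must be a MotionModel or ScaleSeries")
    if len(a) != n:
        raise ValueError(f"scale series length {len(a)} != {n} sinogram rows")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("scales must be positive")
    return np.asarray(a, float), np.asarray(b, float), float(psi)


def _center_cols(center_traj, angles: np.ndarray, width: int) -> np.ndarray:
    """Projected deformation-centre column per angle (defaults to the
    detector centre when no trajectory is supplied)."""
    if center_traj is None:
        return np.full(len(angles), (width - 1) / 2.0 if width % 2 else width // 2)
    if isinstance(center_traj, TrajectoryFit):
        return np.asarray(center_traj(angles), dtype=float)
    return np.asarray(center_traj, dtype=float)


def _rescale_rows(
    data: np.ndarray, s: np.ndarray, c_in: np.ndarray, c_out: np.ndarray | None = None
) -> np.ndarray:
    """Row i of the output samples s_i · E_i(c_in_i + s_i·(t − c_out_i)) on
    the integer detector grid t (linear interpolation, zero fill).

    c_in is the projected deformation centre in the elastic row (at angle
    θ_i); c_out is its position in the rigid row being produced — for the
    elliptic conversion that row lives at the warped angle θ′_i, where the
    centre projects to a slightly different column.
    """
    if c_out is None:
        c_out = c_in
    n, W = data.shape
    t = np.arange(W, dtype=float)
    out = np.empty_like(data)
    for i in range(n):
        pos = c_in[i] + s[i] * (t - c_out[i])
        out[i] = s[i] * np.interp(pos, t, data[i], left=0.0, right=0.0)
    return out


def convert_regular(
    sino_elastic: Sinogram,
    scales,
    center_traj: TrajectoryFit | np.ndarray | None = None,
) -> Sinogram:
    """Undo per-angle isotropic scaling: rigid row = s_i · E_i(s_i·τ + c_i).

    τ is measured from the projected deformation centre c_i (the fixed
    point's own sinusoid), so the rescaling happens about the motion's
    fixed point and per-row mass is preserved up to interpolation.
    Unit scales return the input unchanged, exactly.
    """
    a, b, _ = _as_ab(scales, sino_elastic.n_angles)
    if not np.allclose(a, b, rtol=0, atol=1e-12):
        raise ValueError("convert_regular requires isotropic scales (a_i == b_i)")
    if np.all(a == 1.0):
        return sino_elastic.copy_with(data=sino_elastic.data.copy())
    c = _center_cols(center_traj, sino_elastic.angle_grid.angles, sino_elastic.width)
    out = _rescale_rows(sino_elastic.data, a, c)
    return sino_elastic.copy_with(data=out)


def warped_angle(theta_deg, a, b, axis_angle_deg: float = 0.0) -> np.ndarray:
    """Effective rigid-frame projection angle θ′ for an elastic view at θ.

    θ′ = ψ + atan2(b·sin(θ−ψ), a·cos(θ−ψ)), taken on the branch nearest θ
    (the warp is a small perturbation for slowly drifting scales).
    """
    th = np.asarray(theta_deg, dtype=float)
    tht = np.radians(th - axis_angle_deg)
    raw = np.degrees(np.arctan2(np.asarray(b) * np.sin(tht), np.asarray(a) * np.cos(tht)))
    diff = (raw - np.degrees(tht) + 90.0) % 180.0 - 90.0
    return th + diff


def convert_elliptic(
    sino_elastic: Sinogram,
    motion,
    center_traj: TrajectoryFit | np.ndarray | None = None,
    axis_angle_deg: float | None = None,
) -> WarpedRows:
    """Undo per-angle anisotropic scaling.

    Row i becomes w_i · E_i(w_i·τ + c_i) attached to the warped angle θ′_i,
    with w_i = sqrt(a_i²cos²θ̃_i + b_i²sin²θ̃_i).  The warped-angle sequence
    must come out strictly increasing (dθ′/dθ = ab/w² > 0 at fixed scales);
    a non-monotone sequence is rejected rather than silently reordered.
    """
    a, b, psi = _as_ab(motion, sino_elastic.n_angles)
    if axis_angle_deg is not None:
        psi = float(axis_angle_deg)
    th = sino_elastic.angle_grid.angles
    tht = np.radians(th - psi)
    w = np.sqrt(a**2 * np.cos(tht) ** 2 + b**2 * np.sin(tht) ** 2)
    thp = warped_angle(th, a, b, psi)
    if np.any(np.diff(thp) <= 0):
        raise ValueError("warped-angle sequence is not strictly increasing")
    c_in = _center_cols(center_traj, th, sino_elastic.width)
    c_out = _center_cols(center_traj, thp, sino_elastic.width)
    rows = _rescale_rows(sino_elastic.data, w, c_in, c_out)
    return WarpedRows(rows, thp)


def resample_angles(
    wr: WarpedRows,
    target: AngleGrid,
    out_of_range: str = "raise",
) -> Sinogram:
    """Linear row-wise interpolation from warped angles to a uniform grid.

    Each target row blends the two bracketing warped rows per detector
    column.  Target angles outside the warped range raise by default;
    out_of_range="clamp" holds the nearest warped row instead (useful for
    the sub-step shortfall a contraction-only warp leaves at the last
    angle).
    """
    thp = wr.warped_angles
    if np.any(np.diff(thp) <= 0):
        raise ValueError("warped angles must be strictly increasing")
    tgt = target.angles
    if out_of_range == "raise":
        if tgt[0] < thp[0] or tgt[-1] > thp[-1]:
            raise ValueError(
                f"target angles [{tgt[0]}, {tgt[-1]}] exceed warped range "
                f"[{thp[0]:.4f}, {thp[-1]:.4f}]"
            )
        pos = tgt
    elif out_of_range == "clamp":
        pos = np.clip(tgt, thp[0], thp[-1])
    else:
        raise ValueError(f"unknown out_of_range policy {out_of_range!r}")
    hi = np.searchsorted(thp, pos, side="left").clip(1, len(thp) - 1)
    lo = hi - 1
    denom = thp[hi] - thp[lo]
    frac = ((pos - thp[lo]) / denom).clip(0.0, 1.0)[:, None]
    data = (1.0 - frac) * wr.rows[lo] + frac * wr.rows[hi]
    return Sinogram(data, target)


def select_periodic(n_frames: int, period: int) -> np.ndarray:
    """Indices {0, P, 2P, ...} < n — the frames at which a specimen with
    period-P motion presents the same shape, acting as a rigid specimen."""
    if period < 1:
        raise ValueError("period must be >= 1")
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    return np.arange(0, n_frames, period)


def _pair_scale(
    traj1: MarkerTrajectory,
    traj2: MarkerTrajectory,
    fit_ref: TrajectoryFit,
    grid: AngleGrid,
    cutoff: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-angle scale from a marker pair: s_i = Δu_i / Δu_ref(θ_i).

    Angles where the reference separation falls below ``cutoff`` of its
    amplitude are masked (ill-conditioned near the pair's crossing) and
    filled by linear interpolation over angle.
    """
    if len(traj1) != len(grid) or len(traj2) != len(grid):
        raise ValueError("trajectory and angle grid lengths differ")
    ref = np.asarray(fit_ref(grid.angles), dtype=float)
    if fit_ref.r <= 0:
        raise ValueError("reference separation has zero amplitude")
    valid = traj1.valid & traj2.valid & (np.abs(ref) >= cutoff * fit_ref.r)
    if valid.sum() < 2:
        raise ValueError("fewer than 2 valid unmasked angles for scale estimation")
    s = np.full(len(grid), np.nan)
    s[valid] = (traj1.u[valid] - traj2.u[valid]) / ref[valid]
    idx = np.arange(len(grid), dtype=float)
    s[~valid] = np.interp(idx[~valid], idx[valid], s[valid])
    return s, valid


def estimate_scale_regular(
    traj1: MarkerTrajectory,
    traj2: MarkerTrajectory,
    fit_ref: TrajectoryFit,
    grid: AngleGrid,
    cutoff: float = 0.2,
) -> ScaleSeries:
    """Isotropic scale series from two markers whose line passes through
    the deformation centre; ``fit_ref`` is the sinusoid of their separation
    in the reference (undeformed) frame."""
    s, valid = _pair_scale(traj1, traj2, fit_ref, grid, cutoff)
    return ScaleSeries(s, s.copy(), valid)


def estimate_scale_elliptic(
    major_pair: tuple[MarkerTrajectory, MarkerTrajectory],
    minor_pair: tuple[MarkerTrajectory, MarkerTrajectory],
    fit_ref_major: TrajectoryFit,
    fit_ref_minor: TrajectoryFit,
    grid: AngleGrid,
    cutoff: float = 0.2,
) -> ScaleSeries:
    """Anisotropic scale series from one marker pair on each principal
    axis; a_i and b_i are estimated independently, each with its own
    singular-angle mask."""
    a, va = _pair_scale(*major_pair, fit_ref_major, grid, cutoff)
    b, vb = _pair_scale(*minor_pair, fit_ref_minor, grid, cutoff)
    return ScaleSeries(a, b, va & vb)
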