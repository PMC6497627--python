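"""Virtual alignment: force a fixed point onto its ideal sinusoid.

Per-row translation errors (stage or specimen jitter) displace every row of
the sinogram by an unknown amount.  Shifting row i by
(c + r·cos(θ_i − φ)) − u_i, where u_i is the tracked fixed-point position
and the sinusoid is its least-squares fit, restores the locally aligned
pattern (LAP) for the section and with it the rigid-specimen consistency
conditions.  Sub-pixel shifts use linear interpolation with zero fill;
Fourier shifting is avoided because it rings at the sinogram's sharp
support edges.
"""

from __future__ import annotations

import numpy as np

from .projector import Sinogram
from .trajectory import MarkerTrajectory, TrajectoryFit, center_cor

__all__ = ["align_to_lap", "alignment_shifts", "apply_row_shifts", "inject_jitter"]


def alignment_shifts(traj: MarkerTrajectory, fit: TrajectoryFit, angles: np.ndarray) -> np.ndarray:
    """Per-row shift moving the tracked point onto its fitted sinusoid;
    rows where tracking failed get shifts interpolated from valid rows."""
    ideal = np.asarray(fit(angles), dtype=float)
    shifts = ideal - traj.u
    if not traj.valid.all():
        idx = np.arange(len(traj), dtype=float)
        if traj.valid.sum() == 0:
            raise ValueError("no valid trajectory samples to align on")
        shifts[~traj.valid] = np.interp(idx[~traj.valid], idx[traj.valid], shifts[traj.valid])
    return shifts


def apply_row_shifts(sino: Sinogram, shifts: np.ndarray) -> Sinogram:
    """Translate each row by its shift (linear interpolation, zero fill)."""
    shifts = np.asarray(shifts, dtype=float)
    n, W = sino.data.shape
    if shifts.shape != (n,):
        raise ValueError("one shift per sinogram row required")
    t = np.arange(W, dtype=float)
    out = np.empty_like(sino.data)
    for i in range(n):
        out[i] = np.interp(t - shifts[i], t, sino.data[i], left=0.0, right=0.0)
    return sino.copy_with(data=out)


def align_to_lap(
    sino: Sinogram,
    traj: MarkerTrajectory,
    fit: TrajectoryFit,
    recenter: bool = True,
) -> Sinogram:
    """Shift every row so the fixed point lies on its ideal sinusoid, then
    (optionally) pad the detector axis to put the fitted COR on the centre
    column.  Shifts beyond half the detector width are rejected as
    implausible jitter rather than applied."""
    shifts = alignment_shifts(traj, fit, sino.angle_grid.angles)
    if np.any(np.abs(shifts) > sino.width / 2):
        raise ValueError(
            f"alignment shift {np.abs(shifts).max():.1f} px exceeds half the "
            f"detector width ({sino.width / 2:.1f} px)"
        )
    out = apply_row_shifts(sino, shifts)
    out = out.copy_with(cor_col=float(fit.c))
    if recenter:
        out = center_cor(out, fit.c)
    return out


def inject_jitter(
    sino: Sinogram, max_shift: float, seed: int
) -> tuple[Sinogram, np.ndarray]:
    """Displace each row by an independent uniform draw in [−max_shift,
    max_shift] (seeded); returns the jittered sinogram and the true shifts.
    Test fixture emulating translation errors of the rotation stage."""
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(-max_shift, max_shift, size=sino.n_angles)
    if max_shift == 0:
        return sino.copy_with(data=sino.data.copy()), shifts
    return apply_row_shifts(sino, shifts), shifts
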