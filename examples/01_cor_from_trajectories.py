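"""Determine the centre of rotation from fiducial trajectories.

A dense marker traces u(θ) = c + r·cos(θ − φ) across the sinogram; the
constant c of the least-squares fit is the projected rotation axis (COR),
and the trajectory crosses the COR at (φ + 90°) mod 180° — equivalently
90° before the angle where it bottoms out.
"""

import numpy as np

from vmamct import (
    AngleGrid,
    MarkerTrajectory,
    fit_trajectory,
    trajectory_value,
    zero_crossing_angle,
)

grid = AngleGrid.uniform(1200, 0.15)  # 1200 projections, 0° .. 179.85°

for min_angle in (156.0, 172.0):
    u = 670.0 + trajectory_value(55.0, min_angle - 180.0, grid.angles)
    fit = fit_trajectory(MarkerTrajectory(u, np.ones(len(grid), bool)), grid)
    print(
        f"trajectory minimum at {min_angle:6.1f} deg -> "
        f"COR column c = {fit.c:7.2f} px, amplitude r = {fit.r:5.2f} px, "
        f"crosses the COR at {zero_crossing_angle(fit):5.1f} deg"
    )

# The crossing angle is where the marker passes through the rotation axis:
# only there does its detector position reveal the COR column directly.
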