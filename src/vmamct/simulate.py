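"""Build complete simulated acquisitions of the two-section study scene.

Bundles phantom construction, motion schedules, and forward projection
into one call so the CLI, the examples, and the end-to-end tests all run
the same scene: a two-disk specimen whose left section contracts
elliptically (vertical major axis) and whose right section contracts
isotropically, imaged over a uniform angle sweep.  Per-section sinograms
are produced independently (separating overlapping section projections
from mixed data is out of scope), along with markers-only companions used
as tracking targets, and optionally one sinogram per individual marker for
scale estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import (
    AngleGrid,
    Marker,
    MotionModel,
    Phantom,
    make_scale_series,
    make_two_section_phantom,
    study_two_section_config,
)
from .projector import Sinogram, project_elastic
from .trajectory import TrajectoryFit, point_trajectory_fit
from .vam import apply_row_shifts, inject_jitter

__all__ = ["StudyScene", "simulate_two_section_study"]


@dataclass
class StudyScene:
    """Everything one simulated acquisition produces."""

    phantom: Phantom
    grid: AngleGrid
    motions: dict[int, MotionModel]
    elastic: dict[int, Sinogram]
    marker_elastic: dict[int, Sinogram]  # single alignment marker per section
    center_fits: dict[int, TrajectoryFit]
    per_marker: dict[int, list[Sinogram]] = field(default_factory=dict)
    jitter_shifts: np.ndarray | None = None


def exact_marker_positions(
    marker: Marker, motion: MotionModel, grid: AngleGrid, width: int
) -> np.ndarray:
    """Noiseless detector positions of a deforming marker's centre.

    The marker centre q moves to p + A_i(q − p) at frame i and projects to
    u_i = c + X_i·cosθ_i − Y_i·sinθ_i (c = grid centre column).  The ground
    truth that tracked trajectories approximate.
    """
    from .projector import _scaling_matrix_rc

    p = np.asarray(motion.center, dtype=float)
    q = np.array([marker.row, marker.col], dtype=float)
    cen = width // 2
    th = np.radians(grid.angles)
    u = np.empty(len(grid))
    for i in range(len(grid)):
        A = _scaling_matrix_rc(motion.a[i], motion.b[i], motion.axis_angle_deg)
        qi = p + A @ (q - p)
        X, Y = qi[1] - cen, qi[0] - cen
        u[i] = cen + X * np.cos(th[i]) - Y * np.sin(th[i])
    return u


def _render_marker(shape, m: Marker) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    out = np.zeros(shape)
    out[(rr - m.row) ** 2 + (cc - m.col) ** 2 <= m.radius**2] = m.mac
    return out


def simulate_two_section_study(
    grid_side: int = 255,
    n_angles: int = 1200,
    angle_step_deg: float = 0.15,
    rate_regular: float = 0.00054,
    rate_elliptic_major: float = 0.00054,
    rate_elliptic_minor: float = 0.00036,
    elliptic_axis_deg: float = 90.0,
    section_mac: float = 1.0,
    marker_mac: float = 3.0,
    marker_radius_px: float = 4.0,
    jitter_px: float = 0.0,
    seed: int = 0,
    per_marker: bool = False,
) -> StudyScene:
    """Simulate the two-section acquisition.

    Defaults mirror the study conditions: 1200 projections at 0.15°,
    elliptic contraction 0.054 %/step (major, vertical) x 0.036 %/step
    (minor), regular contraction 0.054 %/step, both compounded per step.
    Nonzero ``jitter_px`` adds seeded uniform per-row translation errors —
    identically to every sinogram of the scene, as one physical stage
    error would.
    """
    cfg = study_two_section_config(
        (grid_side, grid_side), section_mac, marker_mac, marker_radius_px
    )
    phantom = make_two_section_phantom(cfg)
    grid = AngleGrid.uniform(n_angles, angle_step_deg)

    centers = {lab: phantom.section_centroid(lab) for lab in (1, 2)}
    motions = {
        1: make_scale_series(
            "elliptic",
            rate_elliptic_major,
            rate_elliptic_minor,
            n_angles,
            axis_angle_deg=elliptic_axis_deg,
            center=centers[1],
        ),
        2: make_scale_series(
            "regular", rate_regular, rate_regular, n_angles, center=centers[2]
        ),
    }
    center_fits = {
        lab: point_trajectory_fit(*centers[lab], grid_side) for lab in (1, 2)
    }

    elastic, marker_elastic, per_marker_sinos = {}, {}, {}
    for lab in (1, 2):
        sec_img = phantom.section_image(lab)
        # alignment tracking target: the section's FIRST marker rendered
        # alone — a multi-marker sinogram has trajectory crossings that
        # corrupt windowed tracking near the crossing angles
        align_mk = [m for m in phantom.markers if m.section == lab][0]
        mk_img = _render_marker(phantom.shape, align_mk)
        elastic[lab] = project_elastic(sec_img, motions[lab], grid)
        marker_elastic[lab] = project_elastic(mk_img, motions[lab], grid)
        if per_marker:
            per_marker_sinos[lab] = [
                project_elastic(_render_marker(phantom.shape, m), motions[lab], grid)
                for m in phantom.markers
                if m.section == lab
            ]

    shifts = None
    if jitter_px > 0:
        _, shifts = inject_jitter(elastic[1], jitter_px, seed)
        for d in (elastic, marker_elastic):
            for lab in d:
                d[lab] = apply_row_shifts(d[lab], shifts)
        for lab in per_marker_sinos:
            per_marker_sinos[lab] = [
                apply_row_shifts(s, shifts) for s in per_marker_sinos[lab]
            ]
    return StudyScene(
        phantom, grid, motions, elastic, marker_elastic, center_fits,
        per_marker_sinos, shifts,
    )
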