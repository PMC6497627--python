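"""Multi-section orchestration: convert, align, reconstruct, combine.

Each section of a combined elastic specimen is processed independently —
its elastic-type sinogram is converted to rigid type (Step 1), virtually
aligned onto the locally aligned pattern (Step 2), and reconstructed by
filtered back projection (Step 3) — and the per-section reconstructions
are then merged through disjoint region-of-interest masks drawn on the
reference frame (Step 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elastic_rigid import (
    ScaleSeries,
    convert_elliptic,
    convert_regular,
    estimate_scale_elliptic,
    estimate_scale_regular,
    resample_angles,
)
from .phantom import AngleGrid, MotionModel
from .projector import Sinogram
from .recon import ReconSlice, fbp
from .trajectory import (
    MarkerTrajectory,
    TrajectoryFit,
    center_cor,
    fit_trajectory,
    track_marker,
)
from .vam import align_to_lap, alignment_shifts, apply_row_shifts

__all__ = [
    "PipelineError",
    "SectionConfig",
    "SectionInput",
    "SectionResult",
    "VmamConfig",
    "combine_rois",
    "run_vmam",
]


class PipelineError(RuntimeError):
    """A pipeline step failed; the message names the offending section."""


@dataclass
class SectionInput:
    """Per-section measured data: the section's elastic sinogram and,
    optionally, a markers-only elastic sinogram used as tracking target
    for the alignment step (the simulator emits both; for external data
    the marker sinogram may be a background-subtracted copy)."""

    elastic: Sinogram
    marker_elastic: Sinogram | None = None


@dataclass
class SectionConfig:
    """How one section is converted and aligned.

    motion: known MotionModel; None means estimate scales from the marker
    pairs in ``scale_pairs`` (one (traj1, traj2, separation fit) triple for
    regular motion, [major, minor] triples for elliptic).
    center_fit: sinusoid of the section's deformation fixed point.
    vam_seed: column window locating the alignment marker at the first
    angle of the marker sinogram; None skips the per-row alignment and
    only centres the COR.
    """

    label: int
    kind: str  # rigid | regular | elliptic
    roi_mask: np.ndarray
    center_fit: TrajectoryFit | None = None
    motion: MotionModel | None = None
    scale_pairs: list | None = None
    axis_angle_deg: float = 0.0
    vam_seed: tuple[int, int] | None = None
    smooth_scales: int = 0  # moving-average window (angles) on estimated scales

    def __post_init__(self):
        if self.kind not in ("rigid", "regular", "elliptic"):
            raise ValueError(f"unknown section kind {self.kind!r}")
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)


@dataclass
class VmamConfig:
    sections: list[SectionConfig]
    target_grid: AngleGrid
    filter_name: str = "ramp"

    def __post_init__(self):
        labels = [s.label for s in self.sections]
        if len(set(labels)) != len(labels):
            raise ValueError("section labels must be unique")


@dataclass
class SectionResult:
    label: int
    rigid: Sinogram
    lap: Sinogram
    recon: ReconSlice
    roi_mask: np.ndarray
    scales: ScaleSeries | None = None
    shifts_rms: float = 0.0
    log: dict = field(default_factory=dict)


def _estimate_scales(cfg: SectionConfig, grid: AngleGrid) -> ScaleSeries:
    if not cfg.scale_pairs:
        raise PipelineError(
            f"section {cfg.label}: no motion model and no marker pairs to estimate from"
        )
    if cfg.kind == "regular":
        t1, t2, ref = cfg.scale_pairs[0]
        return estimate_scale_regular(t1, t2, ref, grid)
    major, minor = cfg.scale_pairs
    return estimate_scale_elliptic(
        (major[0], major[1]), (minor[0], minor[1]), major[2], minor[2], grid
    )


def _scales_from_motion(motion: MotionModel) -> ScaleSeries:
    return ScaleSeries(motion.a.copy(), motion.b.copy(), np.ones(len(motion), bool))


def _convert_section(
    cfg: SectionConfig, sino: Sinogram, scales: ScaleSeries, target: AngleGrid, psi: float
) -> Sinogram:
    if cfg.kind == "rigid":
        return sino.copy_with(data=sino.data.copy())
    if cfg.kind == "regular":
        iso = ScaleSeries(scales.a, scales.a.copy(), scales.valid)
        return convert_regular(sino, iso, cfg.center_fit)
    wr = convert_elliptic(sino, scales, cfg.center_fit, axis_angle_deg=psi)
    return resample_angles(wr, target, out_of_range="clamp")


def _match_frame(image: np.ndarray, side: int) -> np.ndarray:
    """Crop/pad a reconstruction (centre W'//2) back onto the reference
    grid (centre side//2) so ROI masks line up."""
    cur = image.shape[0]
    if cur == side:
        return image
    start = cur // 2 - side // 2
    out = np.zeros((side, side))
    r0, r1 = max(0, start), min(cur, start + side)
    o0 = max(0, -start)
    out[o0 : o0 + (r1 - r0), o0 : o0 + (r1 - r0)] = image[r0:r1, r0:r1]
    return out


def run_vmam(
    inputs: dict[int, SectionInput | Sinogram],
    config: VmamConfig,
) -> tuple[ReconSlice, list[SectionResult]]:
    """Steps 1–4 for every section, then ROI combination.

    Returns the combined slice on the reference-frame grid together with
    the per-section intermediates (rigid sinogram, LAP sinogram,
    reconstruction, mask, estimated scales, alignment residuals).
    """
    results: list[SectionResult] = []
    side = config.sections[0].roi_mask.shape[0]
    for cfg in config.sections:
        try:
            inp = inputs[cfg.label]
        except KeyError:
            raise PipelineError(f"section {cfg.label}: no input sinogram supplied")
        if isinstance(inp, Sinogram):
            inp = SectionInput(inp)
        grid = inp.elastic.angle_grid
        try:
            # Step 1: elastic -> rigid
            if cfg.kind == "rigid":
                scales = None
            elif cfg.motion is not None:
                scales = _scales_from_motion(cfg.motion)
            else:
                scales = _estimate_scales(cfg, grid)
                if cfg.smooth_scales > 1:
                    # tracked-marker ratios are noisy near the singular
                    # angles; the true schedule is smooth in angle
                    from scipy.ndimage import uniform_filter1d

                    scales = ScaleSeries(
                        uniform_filter1d(scales.a, cfg.smooth_scales, mode="nearest"),
                        uniform_filter1d(scales.b, cfg.smooth_scales, mode="nearest"),
                        scales.valid,
                    )
            psi = cfg.motion.axis_angle_deg if cfg.motion is not None else cfg.axis_angle_deg
            rigid = _convert_section(cfg, inp.elastic, scales, config.target_grid, psi) \
                if scales is not None else _convert_section(cfg, inp.elastic, None, config.target_grid, 0.0)
            marker_rigid = None
            if inp.marker_elastic is not None:
                marker_rigid = (
                    _convert_section(cfg, inp.marker_elastic, scales, config.target_grid, psi)
                    if scales is not None
                    else inp.marker_elastic
                )
            # Step 2: VAM -> LAP
            if cfg.vam_seed is not None and marker_rigid is not None:
                traj = track_marker(marker_rigid, cfg.vam_seed)
                fit = fit_trajectory(traj, rigid.angle_grid)
                shifts = alignment_shifts(traj, fit, rigid.angle_grid.angles)
                lap = align_to_lap(rigid, traj, fit)
                shifts_rms = float(np.sqrt(np.mean(shifts**2)))
            else:
                cor = rigid.cor_col if rigid.cor_col is not None else rigid.center_col
                lap = center_cor(rigid, cor)
                shifts_rms = 0.0
            # Step 3: FBP
            rec = fbp(lap, filter_name=config.filter_name)
            rec = ReconSlice(_match_frame(rec.image, side), rec.pixel_size)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"section {cfg.label}: {exc}") from exc
        results.append(
            SectionResult(
                cfg.label, rigid, lap, rec, cfg.roi_mask, scales, shifts_rms,
                log={"kind": cfg.kind, "shifts_rms": shifts_rms},
            )
        )
    # Step 4: ROI combination
    combined = combine_rois([r.recon for r in results], [r.roi_mask for r in results])
    return combined, results


def combine_rois(slices: list[ReconSlice], masks: list[np.ndarray]) -> ReconSlice:
    """Merge per-section reconstructions: each output pixel takes the value
    of the unique mask covering it, zero elsewhere.  Overlapping masks are
    a hard configuration error, never averaged."""
    if len(slices) != len(masks) or not slices:
        raise ValueError("need one mask per slice")
    shape = slices[0].image.shape
    cover = np.zeros(shape, dtype=int)
    out = np.zeros(shape)
    for sl, m in zip(slices, masks):
        m = np.asarray(m, dtype=bool)
        if m.shape != shape or sl.image.shape != shape:
            raise ValueError("slice/mask shapes differ")
        cover += m
        out[m] = sl.image[m]
    n_overlap = int((cover > 1).sum())
    if n_overlap:
        raise ValueError(f"ROI masks overlap on {n_overlap} pixels")
    return ReconSlice(out, slices[0].pixel_size)
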