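# Methods

## Model and assumptions

The package treats single-slice parallel-beam tomography of a specimen
composed of disjoint *sections*, each deforming by a per-view affine
scaling about a fixed point (the deformation centre `p`):

```
x  ↦  p + A_i (x − p),    A_i = R(ψ) diag(a_i, b_i) R(ψ)ᵀ
```

with per-view scales `a_i` (major axis, orientation `ψ`) and `b_i`
(minor).  `a_i = b_i` is *regular* (isotropic) motion; `a_i = b_i = 1` is
rigid; *periodic* motion is handled purely by frame selection (taking
every P-th view, at which the specimen presents the same shape).

Two assumptions carry the whole method:

1. a common layer (one detector row / one slice) contains the same
   material cross-section at every view — all operations here are 2-D;
2. the total mass attenuation (MAC) of the specimen is conserved as it
   deforms: the deformed frame is `f(A⁻¹(x−p)+p)/(a·b)`.

Under these, the elastic-type projection row at view i relates to the
reference (undeformed) projection `P` by

```
E_i(θ_i, τ) = (1/w_i) · P(θ'_i, τ/w_i)           (offsets τ from the
w_i  = √(a_i²cos²θ̃ + b_i²sin²θ̃),  θ̃ = θ_i − ψ     projected centre)
θ'_i = ψ + atan2(b_i sinθ̃, a_i cosθ̃)
```

which reduces to `w = s`, `θ' = θ` for isotropic motion.  Both identities
are verified numerically in the test suite against an independent
brute-force projector (supersampled bilinear line integrals) at <2 %
relative L2 on 64-px images, and the angle warp satisfies
`dθ'/dθ = ab/w² > 0`, so the warped-angle sequence is strictly increasing
for slowly drifting scales (violations are rejected, never reordered).

Conversion inverts the identity row by row: the rigid-type row samples
`w_i · E_i(c(θ_i) + w_i·(t − c(θ'_i)))` on the integer detector grid,
where `c(θ)` is the projected deformation centre's sinusoid — the
rescaling must happen about the motion's fixed point, and the output row
lives at the warped angle, where that centre projects to a slightly
different column (using one centre for both sides costs ~1.5 px of error
at the study geometry).  Elliptic rows are then linearly interpolated
(row-wise, per detector column) from the warped angles back onto the
uniform grid.

## Coordinate and angle conventions

Sinograms are stored rows = angles (degrees, ascending in [0, 180)),
columns = detector, 0-based.  Projection is scikit-image's rotate-and-sum
Radon transform; its rotation centre is column `W // 2`, so default grids
are odd-sided (255, 129, 65) to make that coincide with the detector
centre `(W−1)/2`.  With this convention a point at `(row, col)` traces

```
u(θ) = c + (col − c)·cosθ − (row − c)·sinθ,   c = W // 2,
```

i.e. amplitude `r = √(X² + Y²)` and phase `φ = atan2(c − row, col − c)`;
the axis orientation `ψ` uses the same angular convention.  A trajectory
crosses the COR at `(φ + 90°) mod 180°` — 90° before the angle where it
bottoms out, which is how the worked examples (minimum 156° → crossing
66°; 172° → 82°) follow.  COR centering pads zero columns on one side
(`p = round(W − 1 − 2·cor)`, low side for p > 0) rather than cropping, so
data values are untouched; FBP refuses sinograms whose stored COR is more
than 0.51 px off the centre column.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| grid_side | 255 px | phantom/detector width (odd; pixel pitch 1, nominally 4 µm) |
| n_angles / step | 1200 / 0.15° | the study's sweep, ending at 179.85° |
| rate_regular | 0.054 %/step | isotropic contraction, compounded: `s_i = (1−rate)^i` |
| rate_elliptic | 0.054 / 0.036 %/step | major (vertical, ψ = 90°) / minor rates |
| section MAC / marker MAC | 1.0 / 3.0 | uniform section value; fiducial disks of radius 4 px |
| tracking window / threshold | ±15 px / 50 % | centroid window half-width; threshold as fraction of window contrast |
| scale-estimation cutoff | \|cos\| < 0.2 | singular-angle mask around the marker pair's crossing |
| HLCC tolerance | 0.5 pxᵏ | order-k residual normalized by total mass |
| retention / high-MAC ratio | 80 % / 10× background | spread-experiment counting rule |

Contraction is compounded per view ("contracts whenever the angle
varies"); over 1200 steps at 0.054 %/step the linear size falls to 0.52×,
a deliberately severe deformation.  A linear-in-angle schedule would stay
within 0.1 % of the geometric one only for the first ~50 views; the
geometric reading is used throughout.

## Numerical choices

- **Deformed frames** use an inverse-mapped bilinear affine warp with the
  `1/(a·b)` density factor, then an exact renormalization to the source's
  total MAC.  Bilinear minification alone loses up to ~3 % of mass at the
  strongest contractions (aliasing on few-pixel features); renormalizing
  enforces the constant-mass assumption exactly while keeping pointwise
  fidelity.  Forward mass splatting was evaluated and rejected: exactly
  mass-preserving but its deposit kernel blurs enough to violate the 2 %
  scaling-identity bound.  The specimen must stay inside the field of
  view.
- **Marker tracking** recentres a ±15 px window on the previous row's
  estimate and takes the intensity centroid of the excess over the
  threshold level (window minimum + 50 % of the window contrast).  Using
  the *excess* rather than a hard cut keeps the centroid continuous as
  the blob crosses pixel boundaries (bias ~0.03 px versus ~0.2 px).
  Trajectories of two markers in one sinogram always cross somewhere;
  tracking targets are therefore single-marker sinograms (the simulator
  emits them; for real data a background-subtracted crop serves).  Rows
  with no window contrast are flagged invalid; >10 % lost rows is a
  tracking failure.
- **Sinusoid fits** are ordinary linear least squares in
  `(1, cosθ, sinθ)`, unweighted, requiring ≥3 valid samples at ≥3
  distinct angles; `φ` is reported in [0, 360), crossing angles folded to
  [0, 180).
- **Row shifts** (jitter injection and alignment) use linear
  interpolation with zero fill; Fourier shifting rings at the sinogram's
  sharp support edges.  Shifts beyond half the detector width are
  rejected as implausible.
- **Scale estimation** divides the measured pair separation by its
  reference sinusoid; angles where the reference falls below 20 % of its
  amplitude are masked and filled by linear interpolation over angle.
  With noiseless trajectories the estimate is exact to machine precision;
  with tracked trajectories, 0.05 px of centroid noise is amplified ~20×
  at the mask boundary (~5 % scale error there), so the pipeline can
  optionally smooth estimated series with a moving average (window 41
  views in the examples) — the true schedule is smooth in angle.
- **Angle resampling** is linear between bracketing warped rows, no
  extrapolation.  A contraction-only warp ends ~0.04° short of the last
  uniform angle at the study rates, so the pipeline uses the "clamp"
  policy (hold the nearest row for target angles outside the warped
  range); the default policy is to raise.
- **FBP** is scikit-image's `iradon` (Ram-Lak default, optional Hann),
  linear back-projection interpolation, output side = detector width,
  zeroed outside the inscribed circle.
- **ROI combination** is a hard-error overlap policy: sections are
  disjoint by construction and silent averaging would hide configuration
  mistakes.  Masks are defined on the reference frame (θ = 0 geometry) —
  the natural target of the rigid conversion.

## What the simulator emulates — and what it does not

The generator reproduces the study geometry (sweep, rates, two sections,
dense fiducials) with uniform-MAC sections on a clean background and an
ideal parallel beam.  It does not model flat-field drift, photon noise,
detector blur, beam hardening, ring artifacts, axial (through-plane)
contraction, or the textured real-slice background; per-section sinograms
are produced independently rather than separated from mixed projections.
Passing tests therefore demonstrate the correctness of the conversion /
alignment / combination machinery under its stated assumptions, not
robustness to those physical effects.

Problem sizes: unit tests run desk-scale scenes (129-px grid, 360 views,
rates scaled to preserve the total contraction); the acceptance tests run
the study conditions proper (255-px grid, 1200 views at 0.15°, rates
0.054 %/0.036 %) and the 64-px oracle comparisons.  The spread experiment
uses matched sampling (views ≈ detector width), where reconstruction
noise is small compared with the per-cycle blur being measured.

## Known limitations

- Single slice only: no 3-D stacking logic beyond a trivial loop, no
  rotation-axis tilt correction (which needs two fixed points across
  layers), and no axial deformation.
- Motion must be (or be convertible to) per-view affine scaling about a
  fixed point; general non-affine deformation is out of scope.
- A high-MAC region placed exactly on the rotation axis barely blurs
  under repeated reconstruction (rotation interpolation vanishes there),
  so its survival count plateaus; off-axis regions keep degrading — the
  spread experiment's strict per-cycle decrease holds for the total count
  over regions.
- Elastic-type sinograms of severely contracted states upsample sparse
  rows by up to ~2×; conversion accuracy (~1 % relative L2 at study
  scale) is interpolation-limited.
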