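"""Convert elastic-type sinograms of a contracting specimen to rigid type.

A specimen contracting isotropically by s per view yields rows
E(θ, τ) = (1/s)·P(θ, τ/s) of the reference projection P; rescaling each
row about the projected deformation centre recovers P.  Anisotropic
(elliptic) contraction additionally warps the effective projection angle,
so converted rows are resampled back onto the uniform grid.
"""

import numpy as np

from vmamct import (
    convert_elliptic,
    convert_regular,
    radon,
    resample_angles,
    simulate_two_section_study,
)

# study conditions scaled to a 129-px desk grid: same total contraction
scene = simulate_two_section_study(
    grid_side=129, n_angles=360, angle_step_deg=0.5,
    rate_regular=0.0018, rate_elliptic_major=0.0018, rate_elliptic_minor=0.0012,
)

rel = lambda a, b: np.linalg.norm(a - b) / np.linalg.norm(b)

for lab, kind in ((2, "regular"), (1, "elliptic")):
    ref = radon(scene.phantom.section_image(lab), scene.grid)
    elastic = scene.elastic[lab]
    if kind == "regular":
        rigid = convert_regular(elastic, scene.motions[lab], scene.center_fits[lab])
    else:
        warped = convert_elliptic(elastic, scene.motions[lab], scene.center_fits[lab])
        rigid = resample_angles(warped, scene.grid, out_of_range="clamp")
    print(f"{kind:8s} section: elastic vs rigid reference {100 * rel(elastic.data, ref.data):5.1f} %"
          f"  -> converted vs reference {100 * rel(rigid.data, ref.data):5.2f} %")
# The elastic sinogram differs from the rigid one by tens of percent; the
# conversion brings it back to the interpolation-noise level (~1 %).
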