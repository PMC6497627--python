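"""Full multi-section pipeline on the two-section study scene.

Each section (one contracting elliptically, one isotropically) gets its
own elastic-to-rigid conversion, virtual alignment and reconstruction;
the per-section slices are then combined through disjoint ROI masks.
A negative control with the two motion models swapped shows the
reconstruction degrade.
"""

import numpy as np

from vmamct import (
    MotionModel,
    SectionConfig,
    SectionInput,
    VmamConfig,
    run_vmam,
    simulate_two_section_study,
)

scene = simulate_two_section_study(
    grid_side=129, n_angles=360, angle_step_deg=0.5,
    rate_regular=0.0018, rate_elliptic_major=0.0018, rate_elliptic_minor=0.0012,
)


def seed_window(lab):
    m = [mk for mk in scene.phantom.markers if mk.section == lab][0]
    return (int(m.col) - 12, int(m.col) + 12)


def config(motions):
    return VmamConfig(
        [
            SectionConfig(1, "elliptic", scene.phantom.section_mask(1),
                          scene.center_fits[1], motions[1], vam_seed=seed_window(1)),
            SectionConfig(2, "regular", scene.phantom.section_mask(2),
                          scene.center_fits[2], motions[2], vam_seed=seed_window(2)),
        ],
        scene.grid,
    )


inputs = {lab: SectionInput(scene.elastic[lab], scene.marker_elastic[lab])
          for lab in (1, 2)}
mask = scene.phantom.section_labels > 0
peak = scene.phantom.image.max()

combined, results = run_vmam(inputs, config(scene.motions))
rmse = np.sqrt(np.mean((combined.image[mask] - scene.phantom.image[mask]) ** 2))
print(f"correct motion models: combined RMSE {100 * rmse / peak:.1f} % of peak MAC")
for r in results:
    print(f"  section {r.label}: alignment shift rms {r.shifts_rms:.3f} px")

swapped = {
    1: MotionModel("elliptic", scene.motions[2].a, scene.motions[2].a.copy(),
                   90.0, scene.motions[1].center),
    2: MotionModel("regular", scene.motions[1].b, scene.motions[1].b.copy(),
                   0.0, scene.motions[2].center),
}
bad, _ = run_vmam(inputs, config(swapped))
rmse_bad = np.sqrt(np.mean((bad.image[mask] - scene.phantom.image[mask]) ** 2))
print(f"swapped motion models:  combined RMSE {100 * rmse_bad / peak:.1f} % of peak MAC")
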