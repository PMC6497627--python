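import numpy as np
import pytest
from scipy import ndimage

from vmamct import AngleGrid, radon, simulate_two_section_study


def rel_l2(a, b):
    return np.linalg.norm(a - b) / np.linalg.norm(b)


@pytest.fixture(scope="session")
def small_scene():
    """Coarse two-section acquisition: 129-px grid, 360 angles at 0.5°,
    per-step rates scaled up so the total contraction over the sweep
    matches the fine-grid study conditions."""
    return simulate_two_section_study(
        grid_side=129,
        n_angles=360,
        angle_step_deg=0.5,
        rate_regular=0.0018,
        rate_elliptic_major=0.0018,
        rate_elliptic_minor=0.0012,
        per_marker=True,
    )


@pytest.fixture(scope="session")
def small_refs(small_scene):
    """Rigid reference sinograms of each section (ground truth for the
    elastic-to-rigid round trip)."""
    return {
        lab: radon(small_scene.phantom.section_image(lab), small_scene.grid)
        for lab in (1, 2)
    }


@pytest.fixture(scope="session")
def disk_image():
    """Smoothed centered disk on a 129-px grid, plus its grid."""
    W = 129
    cen = W // 2
    yy, xx = np.mgrid[0:W, 0:W]
    img = np.zeros((W, W))
    img[(yy - cen) ** 2 + (xx - cen) ** 2 < 40**2] = 1.0
    return ndimage.gaussian_filter(img, 1.5), AngleGrid.uniform(240, 0.75)
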