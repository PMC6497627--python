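"""Filtered back projection of centered rigid-type sinograms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon

from .projector import Sinogram

__all__ = ["NotCenteredError", "ReconSlice", "fbp"]


class NotCenteredError(ValueError):
    """FBP refused because the COR is not on the detector centre column."""


@dataclass
class ReconSlice:
    """Reconstructed 2-D MAC map (square grid, side = detector width)."""

    image: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or self.image.shape[0] != self.image.shape[1]:
            raise ValueError("reconstruction must be square")


def fbp(sino: Sinogram, filter_name: str = "ramp", cor_tol: float = 0.51) -> ReconSlice:
    """Ramp- (or Hann-) filtered back projection.

    Requires the COR on the centre column within ``cor_tol`` pixels —
    back-projecting about a displaced axis smears every feature into an
    arc, so an off-centre sinogram is an error, not a warning.  Values
    outside the inscribed circle of the output grid are zeroed.
    """
    if filter_name not in ("ramp", "hann"):
        raise ValueError(f"unknown filter {filter_name!r}")
    cor = sino.cor_col if sino.cor_col is not None else sino.center_col
    if abs(cor - sino.center_col) > cor_tol:
        raise NotCenteredError(
            f"COR at column {cor:.2f} but detector centre is {sino.center_col:.2f}; "
            "apply center_cor first"
        )
    image = iradon(
        sino.data.T,
        theta=sino.angle_grid.angles,
        filter_name=filter_name,
        interpolation="linear",
        circle=True,
        output_size=sino.width,
    )
    return ReconSlice(image, pixel_size=sino.detector_pitch)
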