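"""Helgason–Ludwig consistency checks on sinograms.

Valid parallel-beam data satisfy moment conditions: the order-k detector
moment of the projections, taken about the COR, is a trigonometric
polynomial of degree k in the projection angle.  Order 0 is mass
conservation (constant across angles); order 1 says the projected centre
of mass traces a sinusoid.  Translation errors of the stage or specimen
break these conditions, which is what the virtual alignment repairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projector import Sinogram

__all__ = ["ConsistencyReport", "check_hlcc", "hlcc_moment"]


def hlcc_moment(sino: Sinogram, k: int, cor_col: float | None = None) -> np.ndarray:
    """Order-k detector moment per angle: H_k(θ_i) = Σ_t (t−cor)^k · data[i,t] · pitch."""
    if k < 0:
        raise ValueError("moment order must be >= 0")
    if cor_col is None:
        cor_col = sino.cor_col if sino.cor_col is not None else sino.center_col
    t = np.arange(sino.width) - cor_col
    return sino.data @ (t**k) * sino.detector_pitch


def _trig_poly_design(theta_rad: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(theta_rad)]
    for m in range(1, degree + 1):
        cols += [np.cos(m * theta_rad), np.sin(m * theta_rad)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class ConsistencyReport:
    """Per-order HLCC residuals, normalized by total mass (units px^k)."""

    orders: tuple[int, ...]
    residuals: tuple[float, ...]
    passed: tuple[bool, ...]
    tol: float

    @property
    def all_passed(self) -> bool:
        return all(self.passed)

    def residual(self, k: int) -> float:
        return self.residuals[self.orders.index(k)]


def check_hlcc(sino: Sinogram, k_max: int = 1, tol: float = 0.5) -> ConsistencyReport:
    """Fit each moment series with its degree-k trigonometric polynomial.

    The reported order-k residual is the RMS misfit divided by the mean
    order-0 moment (total mass), so it reads as an equivalent detector
    error in pixels^k; order k passes iff residual < tol.  An all-zero
    sinogram has zero residual at every order and passes trivially.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    th = np.radians(sino.angle_grid.angles)
    mass = hlcc_moment(sino, 0)
    scale = float(np.abs(mass).mean())
    orders, residuals, passed = [], [], []
    for k in range(k_max + 1):
        H = hlcc_moment(sino, k)
        X = _trig_poly_design(th, k)
        coef, *_ = np.linalg.lstsq(X, H, rcond=None)
        rms = float(np.sqrt(np.mean((H - X @ coef) ** 2)))
        res = rms / scale if scale > 0 else 0.0
        orders.append(k)
        residuals.append(res)
        passed.append(res < tol)
    return ConsistencyReport(tuple(orders), tuple(residuals), tuple(passed), tol)
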