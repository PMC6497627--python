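"""Synthetic specimens, fiducial fixtures, and elastic motion schedules.

Phantoms are 2-D maps of mass-attenuation-coefficient (MAC) values on a
square pixel grid, partitioned into labelled sections.  Dense fiducial
markers ("high-MAC areas") embedded in a section serve as trackable fixed
points.  Motion schedules describe per-projection-angle affine scalings
(regular = isotropic, elliptic = anisotropic about a principal axis) of each
section about a deformation fixed point.

Grids default to odd side lengths so the rotation centre ``W // 2`` used by
the projector coincides with the detector centre ``(W - 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AngleGrid",
    "Marker",
    "MotionModel",
    "Phantom",
    "PhantomConfig",
    "SectionSpec",
    "make_high_mac_fixture",
    "make_scale_series",
    "make_two_section_phantom",
]


class ConfigError(ValueError):
    """Raised for invalid phantom or motion configurations."""


@dataclass(frozen=True)
class AngleGrid:
    """Ascending projection angles in degrees within [0, 180)."""

    angles: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ConfigError("angle grid must be a nonempty 1-D sequence")
        if np.any(np.diff(a) <= 0):
            raise ConfigError("angles must be strictly increasing")
        if a[0] < 0 or a[-1] >= 180:
            raise ConfigError("angles must lie in [0, 180)")
        object.__setattr__(self, "angles", a)

    @classmethod
    def uniform(cls, n: int, step: float, start: float = 0.0) -> "AngleGrid":
        return cls(start + step * np.arange(n))

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def step(self) -> float | None:
        """Uniform step in degrees, or None for a nonuniform grid."""
        d = np.diff(self.angles)
        if d.size == 0:
            return None
        if np.allclose(d, d[0], rtol=0, atol=1e-9):
            return float(d[0])
        return None


@dataclass(frozen=True)
class Marker:
    """A dense fiducial disk inside a section (positions in pixels)."""

    row: float
    col: float
    radius: float
    mac: float
    section: int


@dataclass
class Phantom:
    """2-D MAC map with disjoint labelled section masks and markers."""

    image: np.ndarray
    section_labels: np.ndarray
    markers: list[Marker] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        self.section_labels = np.asarray(self.section_labels, dtype=np.int32)
        if self.image.shape != self.section_labels.shape:
            raise ConfigError("image and section_labels shapes differ")
        if np.any(self.image < 0):
            raise ConfigError("MAC values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def section_mask(self, label: int) -> np.ndarray:
        return self.section_labels == label

    def section_centroid(self, label: int) -> tuple[float, float]:
        """(row, col) centroid of a section mask — the default deformation
        fixed point of that section."""
        rr, cc = np.nonzero(self.section_mask(label))
        if rr.size == 0:
            raise ConfigError(f"section {label} is empty")
        return float(rr.mean()), float(cc.mean())

    def section_image(self, label: int, include_markers: bool = True) -> np.ndarray:
        """MAC map restricted to one section (zero elsewhere)."""
        out = np.where(self.section_mask(label), self.image, 0.0)
        if not include_markers:
            for m in self.markers:
                if m.section == label:
                    mask = _disk_mask(self.shape, m.row, m.col, m.radius)
                    # restore the section's own MAC under the marker
                    sec = [s for s in self.meta.get("sections", []) if s.label == label]
                    base = sec[0].mac if sec else 0.0
                    out[mask] = base
        return out

    def marker_image(self, label: int | None = None) -> np.ndarray:
        """Markers rendered alone on a zero background (optionally one
        section's markers) — the tracking target for scale estimation."""
        out = np.zeros(self.shape)
        for m in self.markers:
            if label is None or m.section == label:
                out[_disk_mask(self.shape, m.row, m.col, m.radius)] = m.mac
        return out


@dataclass
class MotionModel:
    """Per-angle affine scaling of a section about a fixed point.

    ``a`` scales along the major axis (orientation ``axis_angle_deg``,
    measured in the same angular convention as projection angles), ``b``
    along the minor axis.  kind: rigid | regular | elliptic | periodic.
    """

    kind: str
    a: np.ndarray
    b: np.ndarray
    axis_angle_deg: float = 0.0
    center: tuple[float, float] | None = None  # (row, col); None = section centroid
    period: int | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.kind not in ("rigid", "regular", "elliptic", "periodic"):
            raise ConfigError(f"unknown motion kind {self.kind!r}")
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ConfigError("scale series a, b must be 1-D and equal length")
        if np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ConfigError("scales must be positive")
        if self.kind == "rigid" and not (np.all(self.a == 1) and np.all(self.b == 1)):
            raise ConfigError("rigid motion requires unit scales")
        if self.kind == "regular" and not np.allclose(self.a, self.b, rtol=0, atol=0):
            raise ConfigError("regular motion requires a_i == b_i")
        if self.kind == "periodic" and (self.period is None or self.period < 1):
            raise ConfigError("periodic motion requires period >= 1")

    def __len__(self) -> int:
        return len(self.a)

    @classmethod
    def rigid(cls, n_angles: int) -> "MotionModel":
        return cls("rigid", np.ones(n_angles), np.ones(n_angles))


@dataclass(frozen=True)
class SectionSpec:
    """Disk- or ellipse-shaped section of uniform MAC."""

    label: int
    center: tuple[float, float]  # (row, col)
    radii: tuple[float, float]  # (radius_row, radius_col); equal for a disk
    mac: float = 1.0

    @classmethod
    def disk(cls, label, center, radius, mac=1.0):
        return cls(label, center, (radius, radius), mac)


@dataclass
class PhantomConfig:
    shape: tuple[int, int] = (255, 255)
    sections: list[SectionSpec] = field(default_factory=list)
    markers: list[Marker] = field(default_factory=list)


def _disk_mask(shape, row, col, radius) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def make_two_section_phantom(config: PhantomConfig) -> Phantom:
    """Rasterize a multi-section phantom; sections must not overlap.

    A pixel belongs to a section iff its centre satisfies the section's
    ellipse inequality.  Marker MAC overwrites the section MAC inside the
    marker disk.  An empty config yields an all-zero phantom.
    """
    image = np.zeros(config.shape)
    labels = np.zeros(config.shape, dtype=np.int32)
    seen: set[int] = set()
    for spec in config.sections:
        if spec.label <= 0:
            raise ConfigError("section labels must be positive")
        if spec.label in seen:
            raise ConfigError(f"duplicate section label {spec.label}")
        seen.add(spec.label)
        mask = _ellipse_mask(config.shape, spec.center, spec.radii)
        if np.any(labels[mask] != 0):
            raise ConfigError(f"section {spec.label} overlaps an earlier section")
        labels[mask] = spec.label
        image[mask] = spec.mac
    for m in config.markers:
        mask = _disk_mask(config.shape, m.row, m.col, m.radius)
        if not np.all(labels[mask] == m.section):
            raise ConfigError(
                f"marker at ({m.row},{m.col}) extends outside section {m.section}"
            )
        image[mask] = m.mac
    return Phantom(image, labels, list(config.markers), {"sections": list(config.sections)})


def make_high_mac_fixture(
    n_pixels_per_region: int,
    n_regions: int = 2,
    placement: str = "center+edge",
    shape: tuple[int, int] = (255, 255),
    support_radius: float | None = None,
    background_mac: float = 1.0,
    high_mac_ratio: float = 10.0,
) -> Phantom:
    """Uniform support disk carrying small high-MAC pixel regions.

    Each region is the ``n_pixels_per_region`` lattice pixels nearest
    (Euclidean) to its designated centre, ties broken by (row, col) order —
    an approximately disk-shaped, exactly-sized patch.  With
    placement="center+edge" region centres alternate between the grid
    centre and a point near the support edge.  Region masks are stored in
    ``section_labels`` (labels 1..n_regions).
    """
    if n_pixels_per_region < 1:
        raise ConfigError("n_pixels_per_region must be >= 1")
    if n_regions < 1:
        raise ConfigError("n_regions must be >= 1")
    if placement not in ("center", "edge", "center+edge"):
        raise ConfigError(f"unknown placement {placement!r}")
    H, W = shape
    cen = (H // 2, W // 2)
    if support_radius is None:
        support_radius = 0.45 * min(H, W)
    image = np.full(shape, 0.0)
    support = _disk_mask(shape, cen[0], cen[1], support_radius)
    image[support] = background_mac
    high_mac = background_mac * high_mac_ratio

    def region_center(k: int) -> tuple[float, float]:
        edge_pt = (cen[0], cen[1] + 0.8 * support_radius)
        if placement == "center+edge":
            base = cen if k % 2 == 0 else edge_pt
        else:
            base = cen if placement == "center" else edge_pt
        # separate same-placement regions vertically so they never overlap
        off = 4.0 * np.ceil(np.sqrt(n_pixels_per_region)) * (k // 2 if placement == "center+edge" else k)
        return (base[0] + off, base[1])

    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[0:H, 0:W]
    for k in range(n_regions):
        r0, c0 = region_center(k)
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        order = np.lexsort((cc.ravel(), rr.ravel(), d2.ravel()))
        picked = order[:n_pixels_per_region]
        if np.any(labels.ravel()[picked] != 0):
            raise ConfigError("high-MAC regions overlap; reduce size or count")
        labels.ravel()[picked] = k + 1
        image.ravel()[picked] = high_mac
    return Phantom(
        image,
        labels,
        meta={"background_mac": background_mac, "high_mac": high_mac, "support_radius": support_radius},
    )


def make_scale_series(
    kind: str,
    per_step_rate_major: float,
    per_step_rate_minor: float | None = None,
    n_angles: int = 1200,
    axis_angle_deg: float = 0.0,
    center: tuple[float, float] | None = None,
    period: int | None = None,
) -> MotionModel:
    """Compounded per-step contraction schedule.

    a_i = (1 − rate_major)**i, b_i = (1 − rate_minor)**i for projection
    index i — the section contracts by the per-step rate at every angle
    increment.  rate 0 gives a rigid schedule.  Rates are fractions per
    step (e.g. 0.00054 for a 0.054 %/step contraction).
    """
    if per_step_rate_minor is None:
        per_step_rate_minor = per_step_rate_major
    for r in (per_step_rate_major, per_step_rate_minor):
        if not (0 <= r < 1):
            raise ConfigError("per-step rates must lie in [0, 1)")
    if n_angles < 1:
        raise ConfigError("n_angles must be >= 1")
    if kind == "regular" and per_step_rate_major != per_step_rate_minor:
        raise ConfigError("regular motion requires equal rates")
    i = np.arange(n_angles)
    a = (1.0 - per_step_rate_major) ** i
    b = (1.0 - per_step_rate_minor) ** i
    if kind == "rigid" and (per_step_rate_major or per_step_rate_minor):
        raise ConfigError("rigid motion requires zero rates")
    return MotionModel(kind, a, b, axis_angle_deg, center, period)


def study_two_section_config(
    shape: tuple[int, int] = (255, 255),
    section_mac: float = 1.0,
    marker_mac: float = 3.0,
    marker_radius: float = 4.0,
    with_markers: bool = True,
) -> PhantomConfig:
    """Two-disk specimen emulating the reference experiment: an elliptic
    section (left) whose markers sit on both principal axes and a regular
    section (right) with two markers collinear with its centre."""
    H, W = shape
    r = 0.16 * min(H, W)
    cy = H // 2
    cxl, cxr = int(0.28 * W), int(0.72 * W)
    d = 0.6 * r
    sections = [
        SectionSpec.disk(1, (cy, cxl), r, section_mac),
        SectionSpec.disk(2, (cy, cxr), r, section_mac),
    ]
    markers = []
    if with_markers:
        markers = [
            # elliptic section: pair on the major (vertical) axis ...
            Marker(cy - d, cxl, marker_radius, marker_mac, 1),
            Marker(cy + d, cxl, marker_radius, marker_mac, 1),
            # ... and pair on the minor (horizontal) axis
            Marker(cy, cxl - d, marker_radius, marker_mac, 1),
            Marker(cy, cxl + d, marker_radius, marker_mac, 1),
            # regular section: two markers collinear with its centre
            Marker(cy, cxr - d, marker_radius, marker_mac, 2),
            Marker(cy, cxr + d, marker_radius, marker_mac, 2),
        ]
    return PhantomConfig(shape, sections, markers)
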