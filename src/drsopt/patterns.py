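"""Excitation/detection surface patterns and laser-safety checks.

Patterns are simple shapes (point, line/rectangle, disk, circle outline) on
the sample surface, restricted to the 10 × 10 mm² search area centred over
the implant.  Sources carry a power (mW); the maximum permissible exposure
(MPE) for skin at 785 nm continuous illumination is 3 mW/mm², evaluated on
the true illuminated area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely.geometry as geom

__all__ = [
    "SurfacePattern",
    "point_source",
    "line_source",
    "rectangle_detector",
    "point_detector",
    "power_density",
    "mpe_check",
    "MPE_SKIN_MW_MM2",
    "SEARCH_HALF_EXTENT_MM",
]

#: ANSI skin MPE for continuous 785 nm illumination (mW/mm²).
MPE_SKIN_MW_MM2 = 3.0

#: Half-extent of the 10 × 10 mm² search area on the surface (mm).
SEARCH_HALF_EXTENT_MM = 5.0


@dataclass(frozen=True)
class SurfacePattern:
    """A surface illumination or collection shape.

    ``shape`` ∈ {"point", "line", "rectangle", "disk", "circle"}.  Lines and
    rectangles have ``length`` along the y axis and ``width`` along x (the
    paper's line illumination runs along y).  ``diameter`` applies to points,
    ``radius`` to disks and circle outlines; a circle outline also has a
    stroke ``width``.  ``power_mw`` is meaningful for sources only.
    """

    shape: str
    center: tuple[float, float] = (0.0, 0.0)
    diameter: float = 0.1
    length: float = 10.0
    width: float = 2.0
    radius: float = 2.0
    role: str = "source"
    power_mw: float = 45.0
    sampling_step: float = 0.5

    _SHAPES = ("point", "line", "rectangle", "disk", "circle")

    def __post_init__(self) -> None:
        if self.shape not in self._SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.role not in ("source", "detector"):
            raise ValueError(f"role must be 'source' or 'detector', got {self.role!r}")
        if self.power_mw < 0:
            raise ValueError("power must be nonnegative")

    # -- geometry ---------------------------------------------------------

    @property
    def area(self) -> float:
        """Illuminated / collecting area in mm² (true shape area)."""
        if self.shape == "point":
            return np.pi * (self.diameter / 2.0) ** 2
        if self.shape in ("line", "rectangle"):
            return self.length * self.width
        if self.shape == "disk":
            return np.pi * self.radius**2
        # circle outline of stroke `width`
        return 2.0 * np.pi * self.radius * self.width

    def polygon(self):
        """Shapely footprint, for containment/disjointness checks."""
        cx, cy = self.center
        if self.shape == "point":
            return geom.Point(cx, cy).buffer(self.diameter / 2.0, quad_segs=32)
        if self.shape in ("line", "rectangle"):
            return geom.box(cx - self.width / 2.0, cy - self.length / 2.0,
                            cx + self.width / 2.0, cy + self.length / 2.0)
        if self.shape == "disk":
            return geom.Point(cx, cy).buffer(self.radius, quad_segs=64)
        ring = geom.Point(cx, cy).buffer(self.radius, quad_segs=64).exterior
        return ring.buffer(self.width / 2.0, quad_segs=16)

    def within_search_area(self, half_extent: float = SEARCH_HALF_EXTENT_MM) -> bool:
        return self.polygon().within(geom.box(-half_extent, -half_extent,
                                              half_extent, half_extent))

    def disjoint_from(self, other: "SurfacePattern") -> bool:
        return not self.polygon().intersects(other.polygon())

    def sample_points(self) -> np.ndarray:
        """(n, 2) surface sample points representing the pattern in the solver."""
        cx, cy = self.center
        step = self.sampling_step
        if self.shape == "point":
            return np.array([[cx, cy]])
        if self.shape in ("line", "rectangle"):
            xs = _centered(self.width, step) + cx
            ys = _centered(self.length, step) + cy
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            return np.column_stack([X.ravel(), Y.ravel()])
        if self.shape == "disk":
            ax = _centered(2 * self.radius, step)
            X, Y = np.meshgrid(ax + cx, ax + cy, indexing="ij")
            m = (X - cx) ** 2 + (Y - cy) ** 2 <= self.radius**2
            return np.column_stack([X[m], Y[m]])
        n = max(8, int(round(2 * np.pi * self.radius / step)))
        th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([cx + self.radius * np.cos(th),
                                cy + self.radius * np.sin(th)])

    def moved(self, center: tuple[float, float]) -> "SurfacePattern":
        return replace(self, center=center)


def _centered(extent: float, step: float) -> np.ndarray:
    """Cell-centred sample coordinates spanning [-extent/2, extent/2]."""
    n = max(1, int(round(extent / step)))
    d = extent / n
    return -extent / 2.0 + (np.arange(n) + 0.5) * d


# -- presets ---------------------------------------------------------------


def point_source(center=(0.0, 0.0), power_mw: float = 45.0,
                 diameter: float = 0.1) -> SurfacePattern:
    """The point-point instrument's excitation spot (0.1 mm diameter)."""
    return SurfacePattern("point", center=center, diameter=diameter,
                          power_mw=power_mw, role="source")


def line_source(center=(0.0, 0.0), length: float = 10.0, width: float = 2.0,
                power_mw: float = 45.0) -> SurfacePattern:
    """Line illumination along y.

    The modelled line is 10 × 2 mm²; the built instrument's Powell-lens line
    is 10 × 1.5 mm² (``width=1.5``), which at 45 mW sits exactly at the skin
    MPE.  Both are presets of this constructor.
    """
    return SurfacePattern("line", center=center, length=length, width=width,
                          power_mw=power_mw, role="source")


def point_detector(center=(0.0, 0.0), side: float = 0.1) -> SurfacePattern:
    """The 0.1 × 0.1 mm² point detector (a square collection aperture)."""
    return SurfacePattern("rectangle", center=center, length=side, width=side,
                          role="detector", power_mw=0.0, sampling_step=side)


def rectangle_detector(center=(0.0, 0.0), length: float = 10.0,
                       width: float = 2.0) -> SurfacePattern:
    return SurfacePattern("rectangle", center=center, length=length,
                          width=width, role="detector", power_mw=0.0)


# -- safety ----------------------------------------------------------------


def power_density(pattern: SurfacePattern) -> float:
    """Source power density in mW/mm² over the true illuminated area."""
    if pattern.area <= 0:
        raise ValueError("pattern area must be positive")
    return pattern.power_mw / pattern.area


def mpe_check(pattern: SurfacePattern,
              mpe: float = MPE_SKIN_MW_MM2) -> tuple[bool, float]:
    """(passes, margin) of the skin-MPE constraint; margin = mpe − density."""
    density = power_density(pattern)
    margin = mpe - density
    return bool(density <= mpe + 1e-12), margin
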