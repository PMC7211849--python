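"""Wing planform descriptors from an outline polygon.

Span b is the extent of the outline along the base-to-tip span axis, area
S comes from the polygon itself, aspect ratio is AR = b^2 / S, and the
distribution of area toward the tip is summarized by the non-dimensional
radius of the second moment of wing area,

    r2_hat = sqrt( S2 / (S b^2) ),   S2 = integral c(r) r^2 dr,

with c(r) the chord at span station r measured from the wing base. A
rectangular planform gives r2_hat = 1/sqrt(3); a linearly tapering chord
gives 1/sqrt(6); higher values mean more area carried distally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

__all__ = [
    "WingOutline",
    "WingGeometry",
    "planform_metrics",
    "second_moment",
    "chord_distribution",
]


@dataclass
class WingOutline:
    """Simple (non-self-intersecting) closed polygon with a span axis."""

    polygon: np.ndarray  # (n, 2) ordered vertices, mm
    span_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("polygon must be an (n>=3, 2) vertex array")
        self.span_axis = np.asarray(self.span_axis, float)
        norm = np.linalg.norm(self.span_axis)
        if norm == 0:
            raise ValueError("span_axis must be nonzero")
        self.span_axis = self.span_axis / norm
        shp = Polygon(self.polygon)
        if not shp.is_valid or not shp.is_simple:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if shp.area <= 0:
            raise ValueError("polygon has zero area")
        self._shape = shp

    @property
    def shape(self) -> Polygon:
        return self._shape


@dataclass
class WingGeometry:
    span_b: float  # mm
    area_S: float  # mm^2
    aspect_ratio_AR: float
    r2_hat: float | None = None
    chord_profile: np.ndarray | None = None  # (n, 2): (r, c(r))


def _span_extent(outline: WingOutline) -> tuple[float, float]:
    proj = outline.polygon @ outline.span_axis
    return float(proj.min()), float(proj.max())


def planform_metrics(outline: WingOutline, n_strips: int = 500) -> WingGeometry:
    """Span, area, aspect ratio, chord profile and second-moment radius."""
    lo, hi = _span_extent(outline)
    b = hi - lo
    S = float(outline.shape.area)
    geom = WingGeometry(span_b=b, area_S=S, aspect_ratio_AR=b**2 / S)
    r, c = chord_distribution(outline, n_strips)
    geom.chord_profile = np.column_stack([r, c])
    geom.r2_hat = second_moment(outline, n_strips)
    return geom


def chord_distribution(
    outline: WingOutline, n: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Chord length c(r) at n midpoint span stations from base to tip.

    The chord at station r is the total length of the intersection of the
    outline with the line perpendicular to the span axis at that station.
    """
    if n < 1:
        raise ValueError("need at least one station")
    lo, hi = _span_extent(outline)
    b = hi - lo
    u = outline.span_axis
    v = np.array([-u[1], u[0]])  # chord direction
    # anchor for the perpendicular lines: centre of projections onto v
    proj_v = outline.polygon @ v
    v0, v1 = proj_v.min() - 1.0, proj_v.max() + 1.0
    dr = b / n
    r = (np.arange(n) + 0.5) * dr
    chords = np.empty(n)
    for i, ri in enumerate(r):
        base = (lo + ri) * u
        line = LineString([base + v0 * v, base + v1 * v])
        inter = outline.shape.intersection(line)
        chords[i] = float(inter.length)
    return r, chords


def second_moment(outline: WingOutline, n_strips: int = 500) -> float:
    """Non-dimensional radius of the second moment of wing area.

    Midpoint-rule strip integration of c(r) r^2 from the wing base,
    normalized as sqrt(S2 / (S b^2)) so the result lies in (0, 1).
    """
    if n_strips < 10:
        raise ValueError("need at least 10 strips")
    lo, hi = _span_extent(outline)
    b = hi - lo
    r, c = chord_distribution(outline, n_strips)
    if np.all(c == 0):
        raise ValueError("zero chord everywhere: outline degenerate along span")
    dr = b / n_strips
    S2 = float(np.sum(c * r**2) * dr)
    S = float(outline.shape.area)
    return float(np.sqrt(S2 / (S * b**2)))
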