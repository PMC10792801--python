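"""Planar geometry for landmark-based vertebral morphometry.

Radiographic tracings define "planes" by two named landmarks; every
measurement in this package reduces to angles between rays and
perpendicular point-to-line distances.  A plane is always treated as the
*infinite* line through its two defining points, never as the segment:
perpendicular feet routinely fall outside the traced border (common for
the concavity depth on short lower borders), and a distance-to-segment
would kink at the endpoints.

Coordinates live in the anatomical frame: millimetres, +x anterior,
+y superior (mathematical y-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ANGLE_DEGENERACY_TOL_DEG",
    "GeometryError",
    "Point2D",
    "LineSeg",
    "angle_at_vertex",
    "perp_distance",
]

#: Rays whose included angle is within this many degrees of 0 or 180 are
#: rejected as degenerate: such configurations are anatomically impossible
#: for vertebral borders and indicate corrupt input.
ANGLE_DEGENERACY_TOL_DEG = 1e-9


class GeometryError(ValueError):
    """Degenerate geometric configuration (coincident points, zero-length ray)."""


@dataclass(frozen=True)
class Point2D:
    """A 2D landmark position in mm (+x anterior, +y superior)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite coordinate ({self.x}, {self.y})")


@dataclass(frozen=True)
class LineSeg:
    """A directed line defined by two distinct points (the radiographic "plane")."""

    p1: Point2D
    p2: Point2D

    def __post_init__(self) -> None:
        if self.p1.x == self.p2.x and self.p1.y == self.p2.y:
            raise GeometryError("degenerate line: defining points coincide")

    @property
    def length(self) -> float:
        return math.hypot(self.p2.x - self.p1.x, self.p2.y - self.p1.y)

    def unit_direction(self) -> tuple[float, float]:
        """Unit vector from p1 toward p2."""
        n = self.length
        return (self.p2.x - self.p1.x) / n, (self.p2.y - self.p1.y) / n


def angle_at_vertex(vertex: Point2D, a: Point2D, b: Point2D) -> float:
    """Angle in degrees between rays vertex->a and vertex->b.

    Computed as the arc-cosine of the normalised dot product, so the
    result is symmetric in ``a`` and ``b``, lies in the open interval
    (0, 180), and is invariant under rigid motions and uniform scaling.

    Raises
    ------
    GeometryError
        If either ray has zero length, or the rays are (numerically)
        collinear: the included angle is within
        :data:`ANGLE_DEGENERACY_TOL_DEG` of 0 or 180 degrees.
    """
    ax, ay = a.x - vertex.x, a.y - vertex.y
    bx, by = b.x - vertex.x, b.y - vertex.y
    na = math.hypot(ax, ay)
    nb = math.hypot(bx, by)
    if na == 0.0 or nb == 0.0:
        raise GeometryError("zero-length ray at angle vertex")
    c = (ax * bx + ay * by) / (na * nb)
    c = max(-1.0, min(1.0, c))
    deg = math.degrees(math.acos(c))
    if deg < ANGLE_DEGENERACY_TOL_DEG or deg > 180.0 - ANGLE_DEGENERACY_TOL_DEG:
        raise GeometryError(f"degenerate angle {deg!r} deg: rays are collinear")
    return deg


def perp_distance(p: Point2D, line: LineSeg, signed: bool = False) -> float:
    """Perpendicular distance (mm) from ``p`` to the infinite line.

    With ``signed=True`` the distance is positive when ``p`` lies on the
    *left* of the directed line ``p1 -> p2`` (the caller orients the line
    so that the anatomically meaningful side is left).  Unsigned distance
    is the absolute value.
    """
    # cross product of the direction with (p - p1), divided by |direction|
    dx = line.p2.x - line.p1.x
    dy = line.p2.y - line.p1.y
    cross = dx * (p.y - line.p1.y) - dy * (p.x - line.p1.x)
    d = cross / math.hypot(dx, dy)
    return d if signed else abs(d)
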