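"""Exact 3D primitives and the geometric operators the measurements reduce to.

Vectors and points are plain ``numpy`` arrays of shape ``(3,)`` in
millimetres.  :class:`Line3` and :class:`Plane3` normalise their direction /
normal on construction and enforce the unit-length invariant.  Every
length-valued operator is rigid-motion invariant and scales linearly under
uniform scaling; every angle-valued operator is additionally scale
invariant (property-tested).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import COLLINEAR_REL_TOL, COS_CLAMP_TOL, PARALLEL_TOL_RAD, TIE_TOL, UNIT_TOL
from .errors import (
    DegenerateFitError,
    DegenerateGeometryError,
    EmptyGeometryError,
    InvalidTriangleError,
    NonParallelPlanesError,
)

Vec3 = np.ndarray  # shape (3,), float64, finite


def as_vec3(v) -> Vec3:
    """Coerce to a finite float64 ``(3,)`` array."""
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise DegenerateGeometryError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise DegenerateGeometryError("non-finite vector component")
    return a


def normalize(v) -> Vec3:
    v = as_vec3(v)
    n = float(np.linalg.norm(v))
    if n <= 0.0:
        raise DegenerateGeometryError("cannot normalize a zero vector")
    return v / n


@dataclass(frozen=True)
class Line3:
    """A line through ``point`` with unit ``direction``."""

    point: Vec3
    direction: Vec3

    def __post_init__(self):
        object.__setattr__(self, "point", as_vec3(self.point))
        object.__setattr__(self, "direction", normalize(self.direction))
        assert abs(np.linalg.norm(self.direction) - 1.0) < UNIT_TOL


@dataclass(frozen=True)
class Plane3:
    """A plane through ``point`` with unit ``normal``."""

    point: Vec3
    normal: Vec3

    def __post_init__(self):
        object.__setattr__(self, "point", as_vec3(self.point))
        object.__setattr__(self, "normal", normalize(self.normal))


@dataclass
class TriMesh:
    """Triangle surface: ``vertices`` (n, 3) float, ``faces`` (m, 3) int.

    Invariants: at least one face, all indices valid, no face repeats a
    vertex.  The mesh need not be watertight or connected; measurements
    only ever scan vertices and walk the edge graph.
    """

    vertices: np.ndarray
    faces: np.ndarray = field(default=None)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) < 1:
            raise EmptyGeometryError("mesh has no faces")
        if len(self.vertices) < 3:
            raise EmptyGeometryError("mesh has fewer than 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise DegenerateGeometryError("non-finite mesh vertex")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise DegenerateGeometryError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise DegenerateGeometryError("a face repeats a vertex")

    def __len__(self) -> int:
        return len(self.vertices)


def angle_from_sides(a: float, b: float, c: float) -> float:
    """Law-of-cosines angle (degrees) opposite side ``c`` in triangle (a, b, c).

    The triangle inequality is closed: degenerate (collinear) triangles give
    0 or 180 exactly.  ``|cos|`` may exceed 1 by at most ``COS_CLAMP_TOL``
    (clamped); a larger excess means the sides do not form a triangle.
    """
    if a <= 0 or b <= 0 or c < 0:
        raise InvalidTriangleError(f"non-positive side in ({a}, {b}, {c})")
    cos = (a * a + b * b - c * c) / (2.0 * a * b)
    if abs(cos) > 1.0 + COS_CLAMP_TOL:
        raise InvalidTriangleError(
            f"sides ({a}, {b}, {c}) violate the triangle inequality (cos={cos:.3g})"
        )
    return math.degrees(math.acos(min(1.0, max(-1.0, cos))))


def angle_between_directions(u, v) -> float:
    """Angle (degrees, in [0, 180]) between two nonzero vectors."""
    un, vn = normalize(u), normalize(v)
    cos = float(np.dot(un, vn))
    return math.degrees(math.acos(min(1.0, max(-1.0, cos))))


def skew_line_distance(l1: Line3, l2: Line3) -> float:
    """Length of the common perpendicular between two lines (mm, >= 0).

    For (anti-)parallel lines this reduces to the point-to-line distance.
    Symmetric in its arguments.
    """
    n = np.cross(l1.direction, l2.direction)
    sin = float(np.linalg.norm(n))  # directions are unit vectors
    dp = l2.point - l1.point
    if sin < PARALLEL_TOL_RAD:
        return float(np.linalg.norm(np.cross(dp, l1.direction)))
    return abs(float(np.dot(dp, n))) / sin


def point_line_distance(p, line: Line3) -> float:
    return float(np.linalg.norm(np.cross(as_vec3(p) - line.point, line.direction)))


def parallel_plane_separation(p1: Plane3, p2: Plane3) -> float:
    """Perpendicular distance between parallel planes (orientation agnostic)."""
    sin = float(np.linalg.norm(np.cross(p1.normal, p2.normal)))
    if sin > PARALLEL_TOL_RAD:
        raise NonParallelPlanesError(
            f"plane normals differ by {math.degrees(math.asin(min(1.0, sin))):.4g} deg"
        )
    return abs(float(np.dot(p2.point - p1.point, p1.normal)))


def extreme_vertex_index(vertices: np.ndarray, direction) -> int:
    """Index of the vertex maximising the dot product with ``direction``.

    Ties within ``TIE_TOL`` (after normalising the direction) resolve to the
    lowest index, so the result is reproducible for a fixed vertex order.
    """
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    if len(vertices) == 0:
        raise EmptyGeometryError("no vertices to scan")
    d = normalize(direction)
    support = vertices @ d
    return int(np.nonzero(support >= support.max() - TIE_TOL)[0][0])


def extreme_point_along(mesh: TriMesh, direction) -> Vec3:
    """The mesh vertex farthest along ``direction`` (lowest index on ties)."""
    return mesh.vertices[extreme_vertex_index(mesh.vertices, direction)].copy()


def project_point_to_plane(p, plane: Plane3) -> Vec3:
    p = as_vec3(p)
    return p - float(np.dot(p - plane.point, plane.normal)) * plane.normal


def fit_plane_least_squares(points, orient=None) -> Plane3:
    """Total-least-squares plane through >= 3 non-collinear points.

    The plane passes through the centroid; its normal is the direction of
    least variance.  If ``orient`` is given the normal is flipped so that
    ``normal . orient >= 0`` (used to pin the sign to the anterior axis of
    the active anatomical frame).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise DegenerateFitError(f"plane fit needs >= 3 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= COLLINEAR_REL_TOL * max(s[0], 1.0):
        raise DegenerateFitError("points are collinear; plane is underdetermined")
    normal = vt[2]
    if orient is not None and float(np.dot(normal, as_vec3(orient))) < 0.0:
        normal = -normal
    return Plane3(centroid, normal)


def principal_inplane_direction(points, plane: Plane3) -> Vec3:
    """Unit direction of largest in-plane variance of ``points`` on ``plane``."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    centered = pts - pts.mean(axis=0)
    inplane = centered - np.outer(centered @ plane.normal, plane.normal)
    _, s, vt = np.linalg.svd(inplane, full_matrices=False)
    if s[0] <= 0.0:
        raise DegenerateFitError("no in-plane spread")
    return vt[0]
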