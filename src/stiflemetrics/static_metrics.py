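"""The six static measurement procedures of the stifle profile.

Segment lengths are in-plane landmark distances, the flexion angle is the
law-of-cosines knee angle in the sagittal plane, the extensor moment arm is
the common perpendicular between the transepicondylar axis and the extensor
line of action, the tuberosity metrics come from three parallel planes on
the tibial model, and pennation is the acute law-of-cosines angle between
an aponeurosis axis and a fascicle line.  Everything is a pure function of
landmarks, meshes and the anatomical frame.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .anatomy import AnatomicalFrame, LandmarkSet, in_plane_distance
from .config import PARALLEL_TOL_RAD, RunConfig
from .errors import (
    DegenerateGeometryError,
    DegenerateTuberosityError,
    IncompleteProfileError,
    RegionError,
)
from .geometry import (
    Line3,
    Plane3,
    TriMesh,
    angle_from_sides,
    extreme_vertex_index,
    fit_plane_least_squares,
    normalize,
    parallel_plane_separation,
    principal_inplane_direction,
    project_point_to_plane,
    skew_line_distance,
)


@dataclass(frozen=True)
class TpTtResult:
    """Three-plane tuberosity metrics.

    d1 = tuberosity apex plane to anterior cortex plane (mm);
    d2 = anterior cortex plane to posterior plateau plane (mm);
    tp_tt_ratio = d2 / d1; tt_projection_index = scale * d1 / tibial length.
    """

    d1: float
    d2: float
    tp_tt_ratio: float
    tt_projection_index: float

    def __post_init__(self):
        if self.d1 <= 0 or self.d2 < 0:
            raise DegenerateTuberosityError(f"d1={self.d1}, d2={self.d2}")


#: Field order mirrors the study's summary-table columns.
METRIC_FIELDS = (
    "tl",
    "fl",
    "flexion_angle",
    "qca",
    "qca_fl",
    "moment_arm",
    "tt_projection_index",
    "tp_tt_ratio",
    "pennation_vl",
    "pennation_rf",
)


@dataclass(frozen=True)
class LimbMetrics:
    """One limb's static profile: the ten summary-table columns.

    Units: tl/fl/moment_arm in mm; angles in degrees; qca in cm^2;
    qca_fl in cm^2 * m; the tuberosity ratio and projection index are
    dimensionless.  Values are stored at full precision; reporting
    rounding happens only at serialization.
    """

    tl: float
    fl: float
    flexion_angle: float
    qca: float
    qca_fl: float
    moment_arm: float
    tt_projection_index: float
    tp_tt_ratio: float
    pennation_vl: float
    pennation_rf: float

    def __post_init__(self):
        for name in ("tl", "fl", "qca", "qca_fl", "moment_arm",
                     "tt_projection_index", "tp_tt_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("flexion_angle",):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"{name} must lie in (0, 180), got {v}")
        for name in ("pennation_vl", "pennation_rf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name} must lie in [0, 90], got {v}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# segment lengths and flexion
# ---------------------------------------------------------------------------

def femoral_length(landmarks: LandmarkSet, frame: AnatomicalFrame) -> float:
    """Greater trochanter to intercondylar notch, on the sagittal plane (mm)."""
    return in_plane_distance(
        landmarks.point("greater_trochanter"),
        landmarks.point("intercondylar_notch"),
        frame.sagittal_normal,
    )


def tibial_length(landmarks: LandmarkSet, frame: AnatomicalFrame) -> float:
    """Tibial plateau to lateral malleolus, on the coronal plane (mm)."""
    return in_plane_distance(
        landmarks.point("tibial_plateau_ref"),
        landmarks.point("lateral_malleolus"),
        frame.coronal_normal,
    )


def flexion_angle(landmarks: LandmarkSet, frame: AnatomicalFrame) -> float:
    """Included femur-tibia midshaft angle at the knee, in the sagittal plane.

    All three points are projected onto the sagittal plane and the knee
    angle recovered with the law of cosines; full extension is 180 deg.
    """
    sag = Plane3(frame.origin, frame.sagittal_normal)
    f = project_point_to_plane(landmarks.point("femur_midshaft_proximal"), sag)
    k = project_point_to_plane(landmarks.point("knee_center"), sag)
    t = project_point_to_plane(landmarks.point("tibia_midshaft_distal"), sag)
    a = float(np.linalg.norm(f - k))
    b = float(np.linalg.norm(t - k))
    if a <= 0 or b <= 0:
        raise DegenerateGeometryError("projected midshaft point coincides with the knee")
    return angle_from_sides(a, b, float(np.linalg.norm(f - t)))


# ---------------------------------------------------------------------------
# moment arm
# ---------------------------------------------------------------------------

def transepicondylar_axis(landmarks: LandmarkSet) -> Line3:
    """Flexion-extension axis: medial to lateral collateral-ligament sulcus."""
    m = landmarks.point("medial_sulcus")
    l = landmarks.point("lateral_sulcus")
    if np.allclose(m, l):
        raise DegenerateGeometryError("sulci coincide; axis undefined")
    return Line3(m, l - m)


def extensor_line_of_action(
    landmarks: LandmarkSet, frame: AnatomicalFrame | None = None
) -> Line3:
    """Line of action of the extensor mechanism.

    A least-squares plane is fitted to the extensor path points (quadriceps
    tendon down to the tuberosity insertion); the line of action runs
    through their centroid along the in-plane direction of largest
    variance, oriented proximal-positive when a frame is supplied.
    """
    pts = landmarks.get("extensor_path_points")
    orient = frame.anterior if frame is not None else None
    plane = fit_plane_least_squares(pts, orient=orient)
    direction = principal_inplane_direction(pts, plane)
    if frame is not None and float(direction @ frame.proximal) < 0.0:
        direction = -direction
    return Line3(plane.point, direction)


def moment_arm(axis: Line3, line_of_action: Line3) -> float:
    """Perpendicular (common-perpendicular) distance between the two lines."""
    return skew_line_distance(axis, line_of_action)


def moment_arm_torque_effective(axis: Line3, line_of_action: Line3) -> float:
    """Torque-effective arm |((p - a) x f) . a_hat| about the axis.

    Secondary diagnostic: the moment per unit force a pull along the line
    of action produces about the axis.  Equals the common-perpendicular
    distance when the two lines are orthogonal.
    """
    r = line_of_action.point - axis.point
    return abs(float(np.cross(r, line_of_action.direction) @ axis.direction))


# ---------------------------------------------------------------------------
# tuberosity / plateau plane metrics
# ---------------------------------------------------------------------------

def geodesic_region(mesh: TriMesh, seed_points, radius: float) -> np.ndarray:
    """Vertex indices within geodesic ``radius`` (mm) of the seed landmark.

    The seed snaps to its nearest mesh vertex; distances run along the edge
    graph, so the region never leaks across gaps between components.
    """
    seeds = np.asarray(seed_points, dtype=float).reshape(-1, 3)
    v = mesh.vertices
    seed_idx = np.unique(
        [int(np.argmin(((v - s) ** 2).sum(axis=1))) for s in seeds]
    )
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    lengths = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    graph = coo_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(len(v), len(v)),
    ).tocsr()
    dist = dijkstra(graph, directed=False, indices=seed_idx, limit=radius)
    region = np.nonzero(np.isfinite(dist).any(axis=0))[0]
    if len(region) == 0:
        raise RegionError("landmark-seeded region is empty")
    return region


def tp_tt_metrics(
    tibia: TriMesh,
    landmarks: LandmarkSet,
    frame: AnatomicalFrame,
    tl: float,
    config: RunConfig | None = None,
) -> TpTtResult:
    """Three parallel anterior-normal planes on the tibial model.

    P1 passes through the most anterior vertex of the tuberosity region,
    P2 through the anterior-cortex landmark, P3 through the posteriormost
    vertex of the plateau region; d1 = sep(P1, P2), d2 = sep(P2, P3).
    Regions are landmark-seeded geodesic submeshes so whole-mesh extremes
    (malleolus, condyles) cannot be caught.
    """
    cfg = config or RunConfig()
    if tl <= 0:
        raise ValueError("tibial length must be positive")
    ant = frame.anterior

    tt_region = geodesic_region(
        tibia, landmarks.get("tt_anterior_region"), cfg.region_radius_mm
    )
    tt_verts = tibia.vertices[tt_region]
    p1_point = tt_verts[extreme_vertex_index(tt_verts, ant)]

    plateau_region = geodesic_region(
        tibia, landmarks.get("tibial_plateau_ref"), cfg.region_radius_mm
    )
    pl_verts = tibia.vertices[plateau_region]
    p3_point = pl_verts[extreme_vertex_index(pl_verts, -ant)]

    p1 = Plane3(p1_point, ant)
    p2 = Plane3(landmarks.point("anterior_cortex_ref"), ant)
    p3 = Plane3(p3_point, ant)
    d1 = parallel_plane_separation(p1, p2)
    d2 = parallel_plane_separation(p2, p3)
    if d1 <= PARALLEL_TOL_RAD:
        raise DegenerateTuberosityError("tuberosity apex lies on the cortex plane")
    return TpTtResult(
        d1=d1,
        d2=d2,
        tp_tt_ratio=d2 / d1,
        tt_projection_index=cfg.index_scale * d1 / tl,
    )


# ---------------------------------------------------------------------------
# pennation
# ---------------------------------------------------------------------------

def pennation_angle(aponeurosis: Line3, fascicle: Line3) -> float:
    """Acute angle between the aponeurosis axis and a fascicle line (deg).

    Unit segments are taken along each direction from the closest-approach
    midpoint, the triangle is closed, and the law of cosines applied;
    angles above 90 fold to their supplement since pennation is
    conventionally acute.  Parallel lines give 0 (not an error).
    """
    sin = float(np.linalg.norm(np.cross(aponeurosis.direction, fascicle.direction)))
    if sin < PARALLEL_TOL_RAD:
        return 0.0
    c = float(np.linalg.norm(aponeurosis.direction - fascicle.direction))
    theta = angle_from_sides(1.0, 1.0, c)
    return 180.0 - theta if theta > 90.0 else theta


def pennation_from_landmarks(landmarks: LandmarkSet, muscle: str) -> float:
    """Pennation angle from the ``<muscle>_aponeurosis`` / ``_fascicle`` pairs."""
    apo = landmarks.get(f"{muscle}_aponeurosis")
    fas = landmarks.get(f"{muscle}_fascicle")
    if len(apo) < 2 or len(fas) < 2:
        raise DegenerateGeometryError(f"{muscle} aponeurosis/fascicle need 2 points each")
    return pennation_angle(Line3(apo[0], apo[1] - apo[0]), Line3(fas[0], fas[1] - fas[0]))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_limb_metrics(**components) -> LimbMetrics:
    """Build a complete :class:`LimbMetrics`; missing fields are an error.

    Accepts exactly the ten metric field names as keyword arguments and
    raises :class:`IncompleteProfileError` naming every absent or None
    component.
    """
    unknown = set(components) - set(METRIC_FIELDS)
    if unknown:
        raise ValueError(f"unknown metric fields: {sorted(unknown)}")
    missing = [f for f in METRIC_FIELDS if components.get(f) is None]
    if missing:
        raise IncompleteProfileError(missing)
    return LimbMetrics(**{f: float(components[f]) for f in METRIC_FIELDS})
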