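"""Anatomical landmarks and the coordinate frame realising the body planes.

The original measurements were taken in CAD views; here the sagittal,
coronal and axial planes are made explicit by a landmark-derived
right-handed frame (anterior, proximal, lateral), so every in-plane
distance is reproducible.  Left limbs are handled by flipping the lateral
axis during frame construction, which makes all downstream metrics
side-agnostic with a single code path.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import UNIT_TOL
from .errors import DegenerateFrameError, MissingLandmarkError
from .geometry import Vec3, as_vec3, normalize

#: Landmarks every limb must supply (the measurement surface of the pipeline).
REQUIRED_LANDMARKS = (
    "greater_trochanter",
    "lesser_trochanter",
    "intercondylar_notch",
    "medial_sulcus",
    "lateral_sulcus",
    "femur_midshaft_proximal",
    "knee_center",
    "tibia_midshaft_distal",
    "tibial_plateau_ref",
    "lateral_malleolus",
    "tt_anterior_region",
    "anterior_cortex_ref",
    "extensor_path_points",
)

#: Names allowed to carry more than one point.
MULTI_POINT_NAMES = frozenset(
    {"tt_anterior_region", "extensor_path_points"}
    | {f"{m}_{part}" for m in ("vl", "rf", "vi", "vm") for part in ("aponeurosis", "fascicle")}
)

SIDES = ("left", "right")


@dataclass
class LandmarkSet:
    """Named anatomical points in a common frame (mm).

    Each entry is stored as an ``(n, 3)`` array; most landmarks are single
    points (n = 1), while ``extensor_path_points`` (>= 3 points) and the
    per-muscle aponeurosis/fascicle pairs are small point sets.  Unknown
    names are preserved and ignored by the measurements.
    """

    points: dict = field(default_factory=dict)
    side: str = "right"

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        self.points = {
            name: np.asarray(val, dtype=float).reshape(-1, 3)
            for name, val in self.points.items()
        }
        for name, arr in self.points.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite coordinate in landmark {name!r}")

    # -- access ---------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self.points

    def point(self, name: str) -> Vec3:
        """The single point for ``name`` (centroid if a small set)."""
        arr = self.get(name)
        return arr[0].copy() if len(arr) == 1 else arr.mean(axis=0)

    def get(self, name: str) -> np.ndarray:
        if name not in self.points:
            raise MissingLandmarkError([name])
        return self.points[name]

    def names(self):
        return sorted(self.points)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        """Check the required-name contract; list *all* missing names."""
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.points]
        if missing:
            raise MissingLandmarkError(missing)
        if np.allclose(self.point("medial_sulcus"), self.point("lateral_sulcus")):
            raise DegenerateFrameError("medial and lateral sulci coincide")
        if len(self.get("extensor_path_points")) < 3:
            raise DegenerateFrameError("extensor_path_points needs >= 3 points")

    # -- transforms -----------------------------------------------------
    def transformed(self, rotation: np.ndarray, translation) -> "LandmarkSet":
        """Rigidly transformed copy (x -> R x + t)."""
        r = np.asarray(rotation, dtype=float)
        t = as_vec3(translation)
        return LandmarkSet(
            {n: arr @ r.T + t for n, arr in self.points.items()}, side=self.side
        )

    def scaled(self, s: float) -> "LandmarkSet":
        return LandmarkSet({n: arr * s for n, arr in self.points.items()}, side=self.side)

    def mirrored_x(self) -> "LandmarkSet":
        """Mirror across the x = 0 plane, swapping the recorded side."""
        other = "left" if self.side == "right" else "right"
        return LandmarkSet(
            {n: arr * np.array([-1.0, 1.0, 1.0]) for n, arr in self.points.items()},
            side=other,
        )


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal triad (anterior, proximal, lateral) + origin.

    Sagittal plane: normal = lateral; coronal: normal = anterior;
    axial: normal = proximal.
    """

    origin: Vec3
    anterior: Vec3
    proximal: Vec3
    lateral: Vec3

    def __post_init__(self):
        for name in ("origin", "anterior", "proximal", "lateral"):
            object.__setattr__(self, name, as_vec3(getattr(self, name)))
        axes = np.stack([self.anterior, self.proximal, self.lateral])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-8):
            raise DegenerateFrameError("frame axes are not orthonormal")
        if np.linalg.det(axes) < 0:
            raise DegenerateFrameError("frame is left-handed")

    @property
    def sagittal_normal(self) -> Vec3:
        return self.lateral

    @property
    def coronal_normal(self) -> Vec3:
        return self.anterior

    @property
    def axial_normal(self) -> Vec3:
        return self.proximal

    def to_frame(self, p) -> Vec3:
        """Coordinates of ``p`` as (anterior, proximal, lateral) components."""
        d = as_vec3(p) - self.origin
        return np.array([d @ self.anterior, d @ self.proximal, d @ self.lateral])


def build_frame(landmarks: LandmarkSet, side: str | None = None) -> AnatomicalFrame:
    """Anatomical frame from the knee, femoral shaft and condylar sulci.

    proximal = unit(femur_midshaft_proximal - knee_center); lateral = the
    component of (lateral_sulcus - medial_sulcus) orthogonal to proximal
    (sign-flipped for left limbs so "lateral" is consistent);
    anterior = proximal x lateral; origin = knee_center.
    """
    side = landmarks.side if side is None else side
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    knee = landmarks.point("knee_center")
    proximal = normalize(landmarks.point("femur_midshaft_proximal") - knee)
    lat_raw = landmarks.point("lateral_sulcus") - landmarks.point("medial_sulcus")
    if side == "left":
        lat_raw = -lat_raw
    lat_perp = lat_raw - float(lat_raw @ proximal) * proximal
    if np.linalg.norm(lat_perp) <= UNIT_TOL * max(1.0, np.linalg.norm(lat_raw)):
        raise DegenerateFrameError("sulcus line is collinear with the femoral axis")
    lateral = normalize(lat_perp)
    anterior = np.cross(proximal, lateral)
    return AnatomicalFrame(knee, anterior, proximal, lateral)


def in_plane_distance(a, b, plane_normal) -> float:
    """Length of (b - a) projected into the plane with the given normal.

    Always <= the Euclidean distance, with equality iff the segment is
    parallel to the plane.
    """
    d = as_vec3(b) - as_vec3(a)
    n = normalize(plane_normal)
    along = float(d @ n)
    return math.sqrt(max(float(d @ d) - along * along, 0.0))
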