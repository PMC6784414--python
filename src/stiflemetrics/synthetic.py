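"""Parametric synthetic hindlimb with analytically known metric values.

No imaging data were deposited with the original study, so validation
runs on a stylized macropod-like hindlimb built from primitives: a femur
shaft with condylar spheres carrying the collateral-ligament sulci, a
tibia with a plateau slab and a prominent anterior tuberosity wedge, a
patella-free planar extensor strap from the trochanter region to the
tuberosity apex, ellipsoidal muscle bellies voxelized into a label mask,
and fascicle/aponeurosis line pairs.  Every parameter that a measurement
should recover is placed so its true value is exact by construction
(tuberosity apex and plateau face are mesh vertices, the strap is offset
so its line of action sits exactly ``extensor_offset`` mm from the
transepicondylar axis, ...), which makes end-to-end parameter recovery a
meaningful test of the measurement code rather than of the generator.

The limb is built in the canonical right-side frame: origin at the knee
centre, +x lateral, +y anterior, +z proximal.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .anatomy import LandmarkSet
from .config import RunConfig
from .errors import SpecValidationError
from .geometry import TriMesh, normalize
from .muscle_metrics import DEFAULT_LABEL_CODES, VoxelMask, slab_indices
from .static_metrics import LimbMetrics

# fixed construction constants (mm), independent of the tunable spec
NOTCH_Z = 15.0       # intercondylar notch height above the knee centre
CORTEX_Y = 14.0      # anterior cortex plane of the proximal tibia
SULCUS_Z = 8.0       # sulcus height above the knee centre
TT_APEX_Z = -20.0    # tuberosity apex height (below the knee)
SHAFT_RADIUS_FEMUR = 12.0
SHAFT_RADIUS_TIBIA = 13.0
STRAP_HALF_WIDTH = 8.0
STRAP_N_ALONG = 11   # path-point grid: 11 stations x 3 across


@dataclass(frozen=True)
class MuscleBelly:
    """Ellipsoidal muscle belly: centre and semi-axes in frame mm."""

    center: tuple
    semi_axes: tuple


def _default_bellies(fl_true: float) -> dict:
    """Four quadriceps bellies plus sartorius, pairwise disjoint.

    Bellies are laid out side by side along the lateral axis (deliberately
    stylized: analytic disjointness matters more than anatomical packing)
    and centred near the coronal slab so the mid-femur slices cut all
    four quadriceps.
    """
    z_mid = NOTCH_Z + fl_true / 2.0
    return {
        "RF": MuscleBelly((-45.0, 2.0, z_mid), (13.0, 16.0, 58.0)),
        "VL": MuscleBelly((-15.0, -2.0, z_mid), (13.0, 16.0, 54.0)),
        "VI": MuscleBelly((15.0, 2.0, z_mid), (13.0, 16.0, 53.0)),
        "VM": MuscleBelly((45.0, -2.0, z_mid), (13.0, 16.0, 56.0)),
        "SA": MuscleBelly((0.0, 36.0, z_mid), (9.0, 7.0, 50.0)),
    }


@dataclass
class SyntheticLimbSpec:
    """Generator parameters; defaults follow the study's median profile.

    ``fl_true``/``tl_true``/``flexion_true``/``extensor_offset`` and the
    pennation angles default to the published medians; the tuberosity
    projection (30 mm) and plateau depth (54 mm) give the median TP:TT
    ratio of 1.8 at a geometrically plausible scale.  ``tibia_sagittal_fraction``
    splays the tibial axis out of the sagittal plane so that the coronal
    tibial length and the sagittal flexion angle can both hit their true
    values simultaneously.
    """

    fl_true: float = 200.7
    tl_true: float = 400.4
    flexion_true: float = 74.1
    condyle_radius: float = 19.0
    sulcus_separation: float = 42.0
    tt_projection: float = 30.0
    plateau_depth: float = 54.0
    extensor_offset: float = 28.9
    pennation_vl: float = 27.4
    pennation_rf: float = 28.6
    muscles: dict = field(default=None)
    voxel_spacing: tuple = (0.8, 2.5, 0.8)  # lateral, anterior, proximal mm
    tibia_sagittal_fraction: float = 0.5
    mesh_size: float = 4.0
    landmark_noise_sigma: float = 0.0
    seed: int = 0
    side: str = "right"

    def __post_init__(self):
        if self.muscles is None:
            self.muscles = _default_bellies(self.fl_true)
        self.validate()

    def validate(self) -> None:
        pos = {
            "fl_true": self.fl_true, "tl_true": self.tl_true,
            "condyle_radius": self.condyle_radius,
            "sulcus_separation": self.sulcus_separation,
            "tt_projection": self.tt_projection, "plateau_depth": self.plateau_depth,
            "extensor_offset": self.extensor_offset, "mesh_size": self.mesh_size,
        }
        bad = [k for k, v in pos.items() if v <= 0]
        if bad:
            raise SpecValidationError(f"non-positive parameters: {bad}")
        if not 0.0 < self.flexion_true < 180.0:
            raise SpecValidationError("flexion_true must lie in (0, 180)")
        for name in ("pennation_vl", "pennation_rf"):
            if not 0.0 < getattr(self, name) < 90.0:
                raise SpecValidationError(f"{name} must lie in (0, 90)")
        if any(s <= 0 for s in self.voxel_spacing):
            raise SpecValidationError("voxel spacing must be positive")
        if self.landmark_noise_sigma < 0:
            raise SpecValidationError("landmark noise sigma must be >= 0")
        if not 0.0 < self.tibia_sagittal_fraction <= 1.0:
            raise SpecValidationError("tibia_sagittal_fraction must lie in (0, 1]")
        if self.plateau_depth <= 10.0:
            raise SpecValidationError("plateau_depth too small for the plateau slab")
        # the tuberosity wedge and plateau must fit on the proximal tibia
        if self.tt_projection + self.plateau_depth >= self.tl_true / 2.0:
            raise SpecValidationError(
                "tt_projection + plateau_depth exceed what the tibia accommodates"
            )
        if self.side not in ("left", "right"):
            raise SpecValidationError("side must be 'left' or 'right'")

    # -- derived geometry ------------------------------------------------
    @property
    def trochanter_z(self) -> float:
        return NOTCH_Z + self.fl_true

    def tibia_direction(self) -> np.ndarray:
        """Unit tibial axis: sagittal component at the flexion angle."""
        m = self.tibia_sagittal_fraction
        th = math.radians(self.flexion_true)
        x = math.sqrt(max(1.0 - m * m, 0.0))
        return np.array([x, m * math.sin(th), m * math.cos(th)])

    def tibia_shaft_length(self) -> float:
        """Geometric shaft length whose coronal projection equals tl_true."""
        d = self.tibia_direction()
        inplane = math.sqrt(d[0] ** 2 + d[2] ** 2)
        return self.tl_true / inplane


@dataclass
class SyntheticLimb:
    """Generated bundle: meshes, mask, landmarks and the analytic truth."""

    spec: SyntheticLimbSpec
    femur: TriMesh
    tibia: TriMesh
    extensor: TriMesh
    mask: VoxelMask
    landmarks: LandmarkSet
    truth: LimbMetrics


# ---------------------------------------------------------------------------
# mesh primitives
# ---------------------------------------------------------------------------

def _to_trimesh_obj(vertices, faces) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def _subdivided(mesh: trimesh.Trimesh, max_edge: float) -> trimesh.Trimesh:
    v, f = trimesh.remesh.subdivide_to_size(mesh.vertices, mesh.faces, max_edge=max_edge)
    return _to_trimesh_obj(v, f)


def _box(bounds_min, bounds_max, max_edge: float) -> trimesh.Trimesh:
    lo, hi = np.asarray(bounds_min, float), np.asarray(bounds_max, float)
    box = trimesh.creation.box(extents=hi - lo)
    box.apply_translation((lo + hi) / 2.0)
    return _subdivided(box, max_edge)

def _pyramid(apex, base_corners, max_edge: float) -> trimesh.Trimesh:
    """Rectangular pyramid; the apex stays an exact vertex after subdivision."""
    v = np.vstack([apex, base_corners])
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 4], [0, 4, 1], [1, 3, 2], [1, 4, 3]])
    return _subdivided(_to_trimesh_obj(v, f), max_edge)


def _concat(meshes) -> TriMesh:
    m = trimesh.util.concatenate(meshes)
    return TriMesh(np.asarray(m.vertices, float), np.asarray(m.faces, np.int64))


def _femur_mesh(spec: SyntheticLimbSpec) -> TriMesh:
    shaft = trimesh.creation.cylinder(
        radius=SHAFT_RADIUS_FEMUR,
        segment=[[0, 0, NOTCH_Z], [0, 0, spec.trochanter_z]],
        sections=24,
    )
    s = spec.sulcus_separation / 2.0
    r = spec.condyle_radius
    condyles = []
    for sign in (-1.0, 1.0):
        sph = trimesh.creation.icosphere(subdivisions=2, radius=r)
        # sulcus point sits on the condyle surface
        sph.apply_translation([sign * (s - r), 0.0, SULCUS_Z])
        condyles.append(sph)
    troch = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    troch.apply_translation([0.0, -8.0, spec.trochanter_z])
    return _concat([shaft, *condyles, troch])


def _tibia_mesh(spec: SyntheticLimbSpec) -> TriMesh:
    d = spec.tibia_direction()
    length = spec.tibia_shaft_length()
    shaft = trimesh.creation.cylinder(
        radius=SHAFT_RADIUS_TIBIA,
        segment=[8.0 * d, length * d],
        sections=24,
    )
    y_pd = CORTEX_Y - spec.plateau_depth
    plateau = _box(
        (-18.0, y_pd, -8.0), (18.0, CORTEX_Y - 4.0, 0.0), spec.mesh_size
    )
    apex = np.array([0.0, CORTEX_Y + spec.tt_projection, TT_APEX_Z])
    base = np.array([
        [-8.0, CORTEX_Y - 2.0, TT_APEX_Z - 8.0],
        [8.0, CORTEX_Y - 2.0, TT_APEX_Z - 8.0],
        [8.0, CORTEX_Y - 2.0, TT_APEX_Z + 8.0],
        [-8.0, CORTEX_Y - 2.0, TT_APEX_Z + 8.0],
    ])
    wedge = _pyramid(apex, base, spec.mesh_size)
    return _concat([shaft, plateau, wedge])


def _strap_geometry(spec: SyntheticLimbSpec):
    """Path-point grid and ribbon mesh for the extensor strap.

    The strap runs in a sagittal-parallel plane from an origin point near
    the greater trochanter to the tuberosity apex, then the whole plane is
    translated along the common-perpendicular direction until its central
    axis sits exactly ``extensor_offset`` mm from the transepicondylar
    axis (which runs along +x through the sulci).
    """
    origin = np.array([0.0, 18.0, spec.trochanter_z])
    apex = np.array([0.0, CORTEX_Y + spec.tt_projection, TT_APEX_Z])
    e = normalize(apex - origin)            # e_x = 0: perpendicular to the axis
    d = np.array([0.0, -e[2], e[1]])        # x_hat x e, unit, anterior-positive
    medial_sulcus = np.array([-spec.sulcus_separation / 2.0, 0.0, SULCUS_Z])
    c0 = 0.5 * (origin + apex)
    shift = spec.extensor_offset - float((c0 - medial_sulcus) @ d)
    center = c0 + shift * d
    half_len = 0.45 * float(np.linalg.norm(apex - origin))
    u = np.linspace(-half_len, half_len, STRAP_N_ALONG)
    v = np.array([-STRAP_HALF_WIDTH, 0.0, STRAP_HALF_WIDTH])
    pts = (center[None, None, :]
           + u[:, None, None] * e[None, None, :]
           + v[None, :, None] * np.array([1.0, 0.0, 0.0])[None, None, :])
    path_points = pts.reshape(-1, 3)
    # ribbon mesh over the 11 x 3 grid
    nu, nv = len(u), len(v)
    grid_idx = np.arange(nu * nv).reshape(nu, nv)
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a, b = grid_idx[i, j], grid_idx[i, j + 1]
            c, dd = grid_idx[i + 1, j], grid_idx[i + 1, j + 1]
            faces.append([a, b, dd])
            faces.append([a, dd, c])
    mesh = TriMesh(path_points.copy(), np.asarray(faces, np.int64))
    return path_points, mesh


def _landmarks(spec: SyntheticLimbSpec, path_points: np.ndarray) -> LandmarkSet:
    s = spec.sulcus_separation / 2.0
    d = spec.tibia_direction()
    length = spec.tibia_shaft_length()
    y_pd = CORTEX_Y - spec.plateau_depth
    plateau_ref = np.array([0.0, y_pd, -4.0])   # centre of the posterior face
    apex = np.array([0.0, CORTEX_Y + spec.tt_projection, TT_APEX_Z])
    z_mid = NOTCH_Z + spec.fl_true / 2.0
    a_vl = math.radians(spec.pennation_vl)
    a_rf = math.radians(spec.pennation_rf)
    pts = {
        "greater_trochanter": [0.0, 0.0, spec.trochanter_z],
        "lesser_trochanter": [0.0, -12.0, spec.trochanter_z - 25.0],
        "intercondylar_notch": [0.0, 0.0, NOTCH_Z],
        "medial_sulcus": [-s, 0.0, SULCUS_Z],
        "lateral_sulcus": [s, 0.0, SULCUS_Z],
        "femur_midshaft_proximal": [0.0, 0.0, NOTCH_Z + spec.fl_true / 2.0],
        "knee_center": [0.0, 0.0, 0.0],
        "tibia_midshaft_distal": 0.5 * length * d,
        "tibial_plateau_ref": plateau_ref,
        "lateral_malleolus": plateau_ref + length * d,
        "tt_anterior_region": apex,
        "anterior_cortex_ref": [0.0, CORTEX_Y, -10.0],
        "extensor_path_points": path_points,
        "vl_aponeurosis": [[10.0, -5.0, z_mid], [35.0, -5.0, z_mid]],
        "vl_fascicle": [[12.0, -2.0, z_mid],
                        [12.0 + 25.0 * math.cos(a_vl), -2.0 + 25.0 * math.sin(a_vl), z_mid]],
        "rf_aponeurosis": [[-35.0, 20.0, z_mid], [-10.0, 20.0, z_mid]],
        "rf_fascicle": [[-33.0, 22.0, z_mid],
                        [-33.0 + 25.0 * math.cos(a_rf), 22.0 + 25.0 * math.sin(a_rf), z_mid]],
    }
    return LandmarkSet(pts, side="right")


# ---------------------------------------------------------------------------
# voxel mask
# ---------------------------------------------------------------------------

def _mask_grid_geometry(spec: SyntheticLimbSpec):
    """Voxel-grid origin, spacing and dims covering all bellies + margin.

    Grid axes: 0 lateral (x), 1 anterior (y), 2 proximal (z).
    """
    margin = 5.0
    centers = np.array([b.center for b in spec.muscles.values()])
    semis = np.array([b.semi_axes for b in spec.muscles.values()])
    lo = (centers - semis).min(axis=0) - margin
    hi = (centers + semis).max(axis=0) + margin
    sp = np.asarray(spec.voxel_spacing, float)
    dims = np.ceil((hi - lo) / sp).astype(int) + 1
    origin = lo + sp / 2.0
    return origin, sp, dims


def _build_mask(spec: SyntheticLimbSpec) -> VoxelMask:
    origin, sp, dims = _mask_grid_geometry(spec)
    ax = [origin[i] + sp[i] * np.arange(dims[i]) for i in range(3)]
    x = ax[0][:, None, None]
    y = ax[1][None, :, None]
    z = ax[2][None, None, :]
    labels = np.zeros(tuple(dims), dtype=np.int16)
    for name, belly in spec.muscles.items():
        cx, cy, cz = belly.center
        a, b, c = belly.semi_axes
        inside = (((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2) <= 1.0
        labels[inside] = DEFAULT_LABEL_CODES[name]
    return VoxelMask(
        labels=labels,
        spacing=tuple(sp),
        origin=tuple(float(o) for o in origin),
        axis_order=("lateral", "anterior", "proximal"),
        label_codes=dict(DEFAULT_LABEL_CODES),
    )


def _analytic_qca(spec: SyntheticLimbSpec, config: RunConfig) -> float:
    """Exact mean quadriceps section area over the mid-femur slab (cm^2).

    The slab convention (which slices the measurement will visit) is shared
    arithmetic; the areas themselves are exact ellipse sections, so the
    recovery test isolates the voxel-counting error.
    """
    origin, sp, _ = _mask_grid_geometry(spec)
    ax = 1  # anterior grid axis: coronal slices
    center = int(np.floor((0.0 - origin[ax]) / sp[ax] + 0.5))  # midpoint at y = 0
    slices = slab_indices(center, config.n_slices, config.slab_even_extra)
    y = origin[ax] + sp[ax] * np.asarray(slices, float)
    qca_mm2 = 0.0
    for name in ("RF", "VL", "VI", "VM"):
        cx, cy, cz = spec.muscles[name].center
        a, b, c = spec.muscles[name].semi_axes
        frac = 1.0 - ((y - cy) / b) ** 2
        qca_mm2 += float(np.mean(np.pi * a * c * np.clip(frac, 0.0, None)))
    return qca_mm2 / 100.0


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def ground_truth(spec: SyntheticLimbSpec,
                 config: RunConfig | None = None) -> LimbMetrics:
    """The analytically implied value of every metric for ``spec``."""
    cfg = config or RunConfig()
    qca = _analytic_qca(spec, cfg)
    return LimbMetrics(
        tl=spec.tl_true,
        fl=spec.fl_true,
        flexion_angle=spec.flexion_true,
        qca=qca,
        qca_fl=qca * spec.fl_true / 1000.0,
        moment_arm=spec.extensor_offset,
        tt_projection_index=cfg.index_scale * spec.tt_projection / spec.tl_true,
        tp_tt_ratio=spec.plateau_depth / spec.tt_projection,
        pennation_vl=spec.pennation_vl,
        pennation_rf=spec.pennation_rf,
    )


def _mirror_mesh_x(mesh: TriMesh) -> TriMesh:
    v = mesh.vertices * np.array([-1.0, 1.0, 1.0])
    f = mesh.faces[:, ::-1].copy()  # restore outward winding
    return TriMesh(v, f)


def _mirror_mask_lateral(mask: VoxelMask) -> VoxelMask:
    ax = mask.grid_axis("lateral")
    n = mask.labels.shape[ax]
    o = list(mask.origin)
    o[ax] = -(mask.origin[ax] + (n - 1) * mask.spacing[ax])
    return VoxelMask(
        np.flip(mask.labels, axis=ax).copy(), mask.spacing, tuple(o),
        mask.axis_order, dict(mask.label_codes)
    )


def perturb_landmarks(landmarks: LandmarkSet, sigma: float, seed: int) -> LandmarkSet:
    """Displace every landmark point by iid isotropic Gaussian noise (mm).

    ``sigma = 0`` returns an identical copy; a fixed seed gives
    reproducible displacements.  Models the repeatability of manual point
    placement.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return LandmarkSet({n: a.copy() for n, a in landmarks.points.items()},
                           side=landmarks.side)
    rng = np.random.default_rng(seed)
    return LandmarkSet(
        {n: a + rng.normal(0.0, sigma, size=a.shape)
         for n, a in landmarks.points.items()},
        side=landmarks.side,
    )


def generate_limb(spec: SyntheticLimbSpec, with_mask: bool = True,
                  config: RunConfig | None = None) -> SyntheticLimb:
    """Generate the full synthetic limb bundle for ``spec``.

    Deterministic: the same spec (including seed) yields byte-identical
    meshes, masks and landmarks.  ``with_mask=False`` skips voxelization
    (and sets the truth QCA from a throwaway grid) for callers that only
    need the landmark/mesh metrics.
    """
    spec.validate()
    cfg = config or RunConfig()
    path_points, extensor = _strap_geometry(spec)
    femur = _femur_mesh(spec)
    tibia = _tibia_mesh(spec)
    landmarks = _landmarks(spec, path_points)
    mask = _build_mask(spec) if with_mask else None
    truth = ground_truth(spec, cfg)
    if spec.side == "left":
        femur, tibia, extensor = (
            _mirror_mesh_x(femur), _mirror_mesh_x(tibia), _mirror_mesh_x(extensor)
        )
        landmarks = landmarks.mirrored_x()   # flips side to "left"
        if mask is not None:
            mask = _mirror_mask_lateral(mask)
    if spec.landmark_noise_sigma > 0:
        landmarks = perturb_landmarks(landmarks, spec.landmark_noise_sigma, spec.seed)
    if mask is None:
        mask = VoxelMask(np.zeros((1, 1, 1), np.int16), spec.voxel_spacing)
    return SyntheticLimb(spec, femur, tibia, extensor, mask, landmarks, truth)


def random_spec(seed: int, sigma: float = 0.0, side: str = "right") -> SyntheticLimbSpec:
    """A randomized spec over the study-plausible parameter ranges.

    Segment lengths, flexion, extensor offset (20-40 mm), tuberosity and
    plateau dimensions, sulcus separation and pennation angles are drawn
    uniformly over ranges bracketing the published per-limb values.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform
    fl = u(180.0, 215.0)
    bellies = {}
    for name, belly in _default_bellies(fl).items():
        cx, cy, cz = belly.center
        bellies[name] = MuscleBelly(
            (cx, cy + u(-3.0, 3.0), cz + u(-5.0, 5.0)),
            tuple(s * u(0.88, 1.12) for s in belly.semi_axes),
        )
    return SyntheticLimbSpec(
        fl_true=fl,
        tl_true=u(380.0, 425.0),
        flexion_true=u(65.0, 90.0),
        condyle_radius=u(16.0, 22.0),
        sulcus_separation=u(36.0, 48.0),
        tt_projection=u(24.0, 36.0),
        plateau_depth=u(42.0, 62.0),
        extensor_offset=u(20.0, 40.0),
        pennation_vl=u(18.0, 46.0),
        pennation_rf=u(18.0, 46.0),
        muscles=bellies,
        landmark_noise_sigma=sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
        side=side,
    )
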