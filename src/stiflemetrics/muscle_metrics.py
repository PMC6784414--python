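"""Slice-based muscle cross-sectional areas and the quadriceps volume proxy.

A labelled voxel volume (one integer code per muscle) is sampled over a
slab of coronal slices centred at the femoral midlength; per-slice areas
are voxel counts times the in-plane voxel area, and the quadriceps
cross-sectional area (QCA) is the sum of the four vastus/rectus means.
QCA times femoral length approximates the quadriceps volume (cm^2 * m).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import AnatomicalFrame, LandmarkSet
from .config import RunConfig
from .errors import EmptySeriesError, OutOfVolumeError
from .geometry import as_vec3

#: Default label codes for the segmentable muscles.
DEFAULT_LABEL_CODES = {"RF": 1, "VL": 2, "VI": 3, "VM": 4, "SA": 5}

#: Anatomical axis names a grid axis may map to.
ANATOMICAL_AXES = ("anterior", "proximal", "lateral")


@dataclass
class VoxelMask:
    """Labelled 3D volume with per-axis spacing, in anatomical-frame space.

    ``axis_order[i]`` names the anatomical axis grid axis ``i`` runs along;
    ``origin[i]`` is the coordinate of the centre of voxel (0, 0, 0) along
    that same anatomical axis, relative to the frame origin.  Anchoring
    the grid to the anatomical frame keeps every
    area measurement rigid-motion invariant: the mask never needs to be
    resampled when the limb is posed differently.
    """

    labels: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    axis_order: tuple = ("lateral", "anterior", "proximal")
    label_codes: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_CODES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(f"labels must be integer-typed, got {self.labels.dtype}")
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if sorted(self.axis_order) != sorted(ANATOMICAL_AXES):
            raise ValueError(f"axis_order must permute {ANATOMICAL_AXES}")
        present = set(np.unique(self.labels)) - {0}
        declared = set(self.label_codes.values())
        if not present <= declared:
            raise ValueError(f"undeclared label codes present: {sorted(present - declared)}")

    # -- axis helpers ---------------------------------------------------
    def grid_axis(self, anatomical: str) -> int:
        return self.axis_order.index(anatomical)

    @property
    def coronal_axis(self) -> int:
        """Grid axis normal to the coronal plane (the anterior axis)."""
        return self.grid_axis("anterior")

    def inplane_voxel_area_mm2(self, slice_axis: int | None = None) -> float:
        ax = self.coronal_axis if slice_axis is None else slice_axis
        return float(np.prod([s for i, s in enumerate(self.spacing) if i != ax]))

    def slice_index_containing(self, coordinate: float, axis: int) -> int:
        """Index of the slice whose centre interval contains ``coordinate``."""
        j = int(np.floor((coordinate - self.origin[axis]) / self.spacing[axis] + 0.5))
        if not 0 <= j < self.labels.shape[axis]:
            raise OutOfVolumeError(
                f"coordinate {coordinate:.2f} mm maps to slice {j}, "
                f"outside [0, {self.labels.shape[axis]}) on axis {axis}"
            )
        return j

    def scaled(self, s: float) -> "VoxelMask":
        """Uniformly scaled copy (same labels, spacing and origin scaled)."""
        return VoxelMask(
            self.labels, tuple(sp * s for sp in self.spacing),
            tuple(o * s for o in self.origin), self.axis_order, dict(self.label_codes)
        )


@dataclass(frozen=True)
class MuscleSliceSeries:
    """Per-slice areas (cm^2) of one muscle over a slice-index range."""

    label: int
    slice_indices: tuple
    areas_cm2: tuple

    def __post_init__(self):
        if len(self.slice_indices) != len(self.areas_cm2):
            raise ValueError("indices and areas differ in length")
        idx = np.asarray(self.slice_indices)
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("slice indices must be strictly increasing")
        if any(a < 0 for a in self.areas_cm2):
            raise ValueError("areas must be non-negative")


def slab_indices(center_index: int, n_slices: int, extra: str = "distal"):
    """The ``n_slices`` slice indices centred on ``center_index``.

    For even ``n_slices`` one side gets the extra slice: ``"distal"``
    (default) puts it on the higher-index side (centre 50, n=10 ->
    46..55), ``"proximal"`` on the lower.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if extra == "distal":
        lo = center_index - (n_slices - 1) // 2
    elif extra == "proximal":
        lo = center_index - n_slices // 2
    else:
        raise ValueError("extra must be 'distal' or 'proximal'")
    return list(range(lo, lo + n_slices))


def midfemur_slab(
    frame: AnatomicalFrame,
    landmarks: LandmarkSet,
    mask: VoxelMask,
    n_slices: int | None = None,
    config: RunConfig | None = None,
):
    """Coronal slice-index range centred at the femoral midlength.

    The midlength point is the midpoint of the greater trochanter and the
    knee centre; the slab is the ``n_slices`` coronal slices centred on
    the slice containing it (extra slice per the config convention).
    """
    cfg = config or RunConfig()
    n = cfg.n_slices if n_slices is None else n_slices
    mid = 0.5 * (
        as_vec3(landmarks.point("greater_trochanter"))
        + as_vec3(landmarks.point("knee_center"))
    )
    ant, prox, lat = frame.to_frame(mid)
    coords = {"anterior": ant, "proximal": prox, "lateral": lat}
    axis = mask.coronal_axis
    center = mask.slice_index_containing(coords[mask.axis_order[axis]], axis)
    return slab_indices(center, n, cfg.slab_even_extra)


def slice_areas(mask: VoxelMask, label: int, slices) -> MuscleSliceSeries:
    """Per-slice cross-sectional area of one label over coronal slices (cm^2)."""
    if label not in mask.label_codes.values():
        raise ValueError(f"label {label} is not in the declared code set")
    axis = mask.coronal_axis
    n = mask.labels.shape[axis]
    slices = list(slices)
    for j in slices:
        if not 0 <= j < n:
            raise IndexError(f"slice {j} out of range [0, {n})")
    area_vox = mask.inplane_voxel_area_mm2()
    counts = [int((np.take(mask.labels, j, axis=axis) == label).sum()) for j in slices]
    return MuscleSliceSeries(
        label=int(label),
        slice_indices=tuple(slices),
        areas_cm2=tuple(c * area_vox / 100.0 for c in counts),
    )


def mean_csa(series: MuscleSliceSeries) -> float:
    """Mean cross-sectional area across the slab (cm^2)."""
    if len(series.areas_cm2) == 0:
        raise EmptySeriesError("no slices in series")
    return float(np.mean(series.areas_cm2))


def total_qca(rf: float, vl: float, vi: float, vm: float) -> float:
    """Total quadriceps cross-sectional area: RF + VL + VI + VM (cm^2)."""
    parts = (rf, vl, vi, vm)
    if any(p < 0 for p in parts):
        raise ValueError(f"negative cross-sectional area in {parts}")
    return float(sum(parts))


def qca_fl(qca: float, fl: float) -> float:
    """Quadriceps volume proxy: QCA (cm^2) times femoral length (mm) / 1000.

    The femur length converts mm -> m so the proxy lands in cm^2 * m, the
    unit the profile table reports.
    """
    if qca < 0:
        raise ValueError("qca must be non-negative")
    if fl <= 0:
        raise ValueError("femoral length must be positive")
    return qca * (fl / 1000.0)
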