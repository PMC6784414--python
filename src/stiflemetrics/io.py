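"""Readers and writers for the on-disk formats.

Meshes travel as STL (either dialect) via ``trimesh``; label volumes as
NIfTI via ``nibabel`` with a JSON sidecar declaring the label code map
and grid-axis-to-anatomical-axis mapping; landmarks as a flat JSON
name -> [x, y, z] (or list-of-points) map in millimetres.  All distances
on disk are millimetres; report units (cm^2, cm^2 * m) appear only in
serialized profiles.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from .anatomy import LandmarkSet
from .errors import MaskReadError, MeshReadError
from .geometry import TriMesh
from .muscle_metrics import VoxelMask


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def read_mesh(path) -> TriMesh:
    """Read an STL file (binary or ASCII) into a validated TriMesh.

    Units are assumed millimetres.  Duplicate vertices are merged within
    1e-6 mm so both STL dialects of the same surface load identically.
    """
    path = Path(path)
    if not path.is_file():
        raise MeshReadError(f"mesh file not found: {path}")
    try:
        m = trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # trimesh raises a zoo of parse errors
        raise MeshReadError(f"cannot parse STL {path}: {exc}") from exc
    if not isinstance(m, trimesh.Trimesh) or len(m.faces) == 0:
        raise MeshReadError(f"no triangles parsed from {path} (malformed or empty STL)")
    m.merge_vertices(digits_vertex=6)
    return TriMesh(np.asarray(m.vertices, float), np.asarray(m.faces, np.int64))


def write_mesh(mesh: TriMesh, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False).export(path)
    return path


# ---------------------------------------------------------------------------
# label masks
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_mask(path) -> VoxelMask:
    """Read an integer NIfTI label volume plus its JSON sidecar.

    The sidecar must declare ``label_codes`` (name -> integer) and
    ``axis_order`` (three anatomical axis names); voxel spacing comes from
    the NIfTI header and the grid origin from the affine translation.
    """
    path = Path(path)
    if not path.is_file():
        raise MaskReadError(f"mask file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.is_file():
        raise MaskReadError(f"missing label-code sidecar: {sidecar}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        raise MaskReadError(f"label volume must be integer-typed, got {data.dtype}")
    meta = json.loads(sidecar.read_text())
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelMask(
        labels=data,
        spacing=spacing,
        origin=origin,
        axis_order=tuple(meta["axis_order"]),
        label_codes={k: int(v) for k, v in meta["label_codes"].items()},
    )


def write_mask(mask: VoxelMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), affine), str(path))
    _sidecar_path(path).write_text(
        json.dumps(
            {"axis_order": list(mask.axis_order), "label_codes": mask.label_codes,
             "units": "mm"},
            indent=2,
        )
    )
    return path


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    """Read the landmark JSON: units, side, and a flat name -> points map.

    Coordinates are kept exactly as stored (left limbs are handled by the
    frame construction, not rewritten here); unknown names are preserved.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"landmark file not found: {path}")
    doc = json.loads(path.read_text())
    units = doc.get("units", "mm")
    if units != "mm":
        raise ValueError(f"landmark units must be mm, got {units!r}")
    lms = LandmarkSet(doc["landmarks"], side=doc.get("side", "right"))
    lms.validate()
    return lms


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "units": "mm",
        "side": landmarks.side,
        "landmarks": {
            name: (arr[0].tolist() if len(arr) == 1 else arr.tolist())
            for name, arr in landmarks.points.items()
        },
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# structured logging
# ---------------------------------------------------------------------------

class JsonLinesLog:
    """Append-only JSON-lines log of geometric intermediates.

    The original measurements were manual CAD reads; logging every
    landmark, axis and plane the pipeline used is the automated
    replacement for that audit trail.  Timestamps are omitted so repeated
    runs are byte-identical.
    """

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = self.path.open("w")

    def event(self, kind: str, **payload) -> None:
        self._fh.write(json.dumps({"event": kind, **payload}, sort_keys=True) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
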