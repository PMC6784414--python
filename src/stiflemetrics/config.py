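"""Numerical tolerances and the run configuration.

All tolerances used by the geometric operators live here as named module
constants; nothing in the library hard-codes a magic epsilon.  Units are
millimetres for lengths, radians for angular tolerances, degrees for
reported angles.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

#: |cos| may exceed 1 by at most this before a triangle is rejected.
COS_CLAMP_TOL = 1e-9
#: Extreme-point ties: vertices whose support value is within this of the
#: maximum are tied; the lowest vertex index wins.
TIE_TOL = 1e-9
#: Directions within this angle (radians) are treated as parallel.
PARALLEL_TOL_RAD = 1e-6
#: Unit-vector invariant tolerance for Line3/Plane3 and frame axes.
UNIT_TOL = 1e-9
#: Vertex deduplication radius when reading meshes (mm).
MESH_MERGE_TOL = 1e-6
#: Relative singular-value threshold below which a point set is collinear.
COLLINEAR_REL_TOL = 1e-9


@dataclass
class RunConfig:
    """Pipeline configuration with the documented defaults.

    Attributes
    ----------
    n_slices:
        Number of coronal slices in the mid-femur slab ("approximately 10").
    region_radius_mm:
        Geodesic radius of the landmark-seeded tuberosity/plateau submeshes.
    index_scale:
        Multiplier applied to D1/TL for the tuberosity projection index
        (100 gives the percent-like convention).
    report_decimals:
        Decimal places of the half-away-from-zero reporting rounding, applied
        only at serialization.
    slab_even_extra:
        Side receiving the extra slice for an even slab ("distal" = the
        higher slice index, "proximal" = the lower).
    seed:
        Seed for any stochastic step (synthetic generation, perturbation).
    """

    n_slices: int = 10
    region_radius_mm: float = 15.0
    index_scale: float = 100.0
    report_decimals: int = 1
    slab_even_extra: str = "distal"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))
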