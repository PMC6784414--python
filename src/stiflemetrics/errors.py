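"""Exception hierarchy.

Every error raised by the library derives from :class:`StifleError`, so
callers (and the CLI) can distinguish domain failures from programming
errors with a single except clause.
"""


class StifleError(Exception):
    """Base class for all stiflemetrics errors."""


class InvalidTriangleError(StifleError):
    """Side lengths are non-positive or violate the triangle inequality."""


class DegenerateGeometryError(StifleError):
    """A direction, line or plane is degenerate (zero-length vector, ...)."""


class NonParallelPlanesError(StifleError):
    """Plane separation requested for planes whose normals are not parallel."""


class EmptyGeometryError(StifleError):
    """A mesh (or vertex region) with no vertices where one is required."""


class DegenerateFitError(StifleError):
    """Plane fit requested on fewer than three points or a collinear set."""


class MissingLandmarkError(StifleError):
    """Required landmark names are absent; carries the full missing list."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"missing required landmarks: {', '.join(self.missing)}")


class DegenerateFrameError(StifleError):
    """Landmarks do not span a frame (sulci collinear with the femur axis)."""


class DegenerateTuberosityError(StifleError):
    """Tibial-tuberosity apex coincides with the anterior cortex plane (D1 = 0)."""


class RegionError(StifleError):
    """A landmark-seeded mesh region is empty."""


class OutOfVolumeError(StifleError):
    """A reference point falls outside the voxel-mask extent."""


class EmptySeriesError(StifleError):
    """A slice series with no slices where at least one is required."""


class IncompleteProfileError(StifleError):
    """A limb profile is missing component metrics; names the missing fields."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"incomplete limb profile, missing: {', '.join(self.missing)}")


class SpecValidationError(StifleError):
    """A synthetic-limb parameter set is geometrically inconsistent."""


class MeshReadError(StifleError):
    """An STL file could not be parsed."""


class MaskReadError(StifleError):
    """A label volume could not be read or is not integer-typed."""
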