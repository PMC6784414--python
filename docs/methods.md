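# Methods

## Measurement model

The pipeline automates a static morphometric protocol originally carried
out by hand in CAD views on CT/MRI-derived surface models of the
kangaroo stifle. Everything reduces to a small set of exact geometric
operators (`geometry`): law-of-cosines angles, common-perpendicular
distances between lines, separations of parallel planes, support
(extreme) vertices of a mesh along a direction, point-to-plane
projections, and total-least-squares plane fits. All lengths are
millimetres; angles cross module boundaries only in degrees.

### The anatomical frame

The original protocol referred measurements to "sagittal", "coronal" and
"axial" views without defining them algorithmically. To make in-plane
distances reproducible, an explicit right-handed frame (anterior,
proximal, lateral) is derived from landmarks: proximal is the unit
vector from the knee centre to the proximal femoral midshaft, lateral is
the inter-sulcus direction orthogonalized against proximal, anterior
completes the triad. Sagittal, coronal and axial planes have lateral,
anterior and proximal normals respectively. This is one defensible
realization of the protocol's viewing planes, not a claim about how the
original measurements were oriented; since the frame is landmark-derived
it is exactly rigid-motion equivariant, which makes every downstream
metric pose-invariant (property-tested to 1e-6).

Left limbs are handled by flipping the lateral axis during frame
construction (the recorded coordinates are never rewritten), so all ten
metrics are side-agnostic through a single code path. A mirrored limb
measures identically to its right-sided twin (tested).

### The six procedures

- **Segment lengths.** FL = in-plane distance (sagittal) between greater
  trochanter and intercondylar notch; TL = in-plane distance (coronal)
  between the tibial-plateau reference point and the lateral malleolus.
- **Flexion angle.** Project femoral midshaft, knee centre and tibial
  midshaft onto the sagittal plane and apply the law of cosines to the
  triangle side lengths; the knee-vertex angle is reported, with full
  extension at 180°. Reported values near 70–90° therefore describe a
  strongly crouched limb posture.
- **Moment arm.** Transepicondylar axis: the line through the medial
  sulcus toward the lateral sulcus. Line of action: a least-squares
  plane is fitted to the extensor path points (the normal signed toward
  anterior); the line of action runs through their centroid along the
  in-plane direction of largest variance, oriented proximal-positive.
  The moment arm is the common-perpendicular distance between the two
  lines, implementing the protocol's "perpendicular distance" literally
  in 3D (whether the original was read in a projection view is
  unstated). The torque-effective arm |((p−a)×f̂)·â| — the moment per
  unit force about the axis — is computed alongside as a diagnostic; the
  two coincide when the lines are orthogonal.
- **TP:TT planes.** The three parallel planes share the anterior normal.
  P1 passes through the most anterior vertex of a tuberosity submesh, P3
  through the posteriormost vertex of a plateau submesh, and P2 through
  the anterior-cortex landmark: the protocol does not define the cortex
  plane algorithmically, so a user-supplied landmark keeps it
  deterministic and auditable. Submeshes are landmark-seeded geodesic
  regions (Dijkstra over the mesh edge graph, default radius 15 mm) so
  that whole-mesh extremes — the malleolus, the condyles — can never be
  caught. Extreme-vertex ties within 1e-9 resolve to the lowest vertex
  index (mesh-order reproducible).
- **Muscle areas.** The mid-femur slab is the set of `n_slices`
  (default 10, "approximately 10" in the protocol) coronal slices
  centred on the slice containing the midpoint of greater trochanter and
  knee centre; for even n the extra slice goes to the higher-index side
  (an arbitrary but fixed convention — the protocol gives no rule). A
  voxel contributes its full in-plane area iff labelled: no
  partial-volume weighting, matching manual segmentation counting; the
  resulting error scales with the boundary-voxel band and is the only
  non-exact step in the pipeline (see recovery below). The protocol's
  muscle list for the quadriceps sum is read as RF + VL + VI + VM (its
  "WM" is taken as a typo for VM, consistent with the dissection
  tables); SA is segmentable but excluded from QCA.
- **Pennation.** Unit segments along the aponeurosis and fascicle
  directions from their closest-approach midpoint close a triangle whose
  law-of-cosines angle is reported, folded to the acute range (the
  triangle construction is direction-sign ambiguous and pennation is
  conventionally ≤ 90°). Parallel lines give 0, not an error.

### Aggregation and rounding

The summary statistic is the median (mean of the two central order
statistics for even n) with the range (max − min). Reporting rounding is
one decimal, half away from zero, applied **only** at serialization; the
JSON twin of every CSV keeps full precision. Because half-away rounding
is sensitive to binary-float fuzz (the median of 196.1 and 205.2 is
200.64999999999998 in doubles but is meant to be 200.65), serialization
pre-quantizes at 1e-9 before rounding. Two published range cells (FL
20.1, moment arm 3.8) are inconsistent with the published per-limb
values (19.3, 3.7) — presumably computed from unrounded measurements
that were never published — and are documented as non-reproducible
rather than targeted; the same applies to one published QCA·FL cell
(15.4 vs recomputed 15.5).

## Synthetic limb generator

The generator replaces the unavailable CT/MRI specimens with
primitive-based geometry whose metric values are exact by construction:

- Femur: a shaft cylinder from the intercondylar notch to the greater
  trochanter, condylar spheres carrying the sulcus landmarks at the
  requested separation.
- Tibia: a shaft cylinder, a plateau slab whose posterior face lies
  exactly `plateau_depth` behind the cortex plane, and a tuberosity
  pyramid whose apex vertex lies exactly `tt_projection` in front of it
  (both survive subdivision as exact vertices, so the plane metrics are
  resolution-independent).
- Extensor: a planar strap (11 x 3 point grid plus ribbon mesh) from the
  trochanter region to the tuberosity apex, translated along the common
  perpendicular until its central axis sits exactly `extensor_offset`
  from the transepicondylar axis.
- Muscles: five pairwise-disjoint ellipsoidal bellies (RF, VL, VI, VM,
  SA) voxelized by centre-inclusion into an anatomically-anchored label
  grid (default spacing 0.8 x 2.5 x 0.8 mm, echoing a coronal
  acquisition with thick slices). The bellies are laid out side by side
  along the lateral axis — deliberately stylized: analytic disjointness
  of the ellipsoids matters more here than anatomical packing.
- Pennation: aponeurosis/fascicle landmark pairs at the requested angles
  in an axial plane.

Two geometric constraints deserve note. TL is a coronal in-plane
distance while flexion is a sagittal-plane angle, so a tibial axis lying
wholly in either plane cannot satisfy both; the generator splays the
axis out of the sagittal plane (`tibia_sagittal_fraction`, default 0.5)
and solves the shaft length so the measured TL equals `tl_true` exactly.
And the ground-truth QCA is the exact mean of the analytic ellipse
sections at the slice positions the slab convention selects — the slab
arithmetic is shared with the measurement, the areas are not, so
parameter recovery isolates precisely the voxel-counting error.

Defaults follow the published median profile (FL 200.7 mm, TL 400.4 mm,
flexion 74.1°, moment arm 28.9 mm, pennation 27.4°/28.6°). The
tuberosity defaults are `tt_projection` 30 mm and `plateau_depth` 54 mm,
giving the published median TP:TT ratio of 1.8 at a plausible scale; the
published TT projection index (~17.9) is **not** jointly consistent with
index = 100·D1/TL for any plausible D1 at TL ≈ 400 mm (it would imply a
72 mm tuberosity), and the original normalization cannot be recovered
from the protocol text. The ×100 index convention is implemented as
specified and the raw D1/D2 are always reported so any rescaling is
recomputable. The mesh edge target defaults to 4 mm: because every
measurement-critical feature is an exact vertex, resolution affects only
region-growing granularity, and recovery is verified at 4 and 8 mm.

All randomness (landmark noise, randomized cohort specs) flows from a
single integer seed; identical specs give byte-identical meshes, masks
and landmarks.

### What the generator does and does not emulate

It reproduces the geometric relationships the measurements depend on —
landmark configurations, tuberosity/plateau plane structure, strap
offset, belly cross-sections — with analytic truth. It does not emulate
real bone shape variation, cortical/trabecular structure, segmentation
noise, imaging intensities, cartilage or fat-pad anatomy, or anatomical
muscle packing. Passing recovery tests therefore demonstrates that the
measurement code is correct and noise-stable, not that the protocol is
accurate on real specimens.

## Validation results (computed by the tests and scripts)

- Noiseless recovery on 50 seeded random limbs: every metric within 2%
  of truth per limb; in practice all landmark/mesh metrics are exact to
  floating point and only QCA deviates (~0.1%, voxel counting).
- Under 1 mm isotropic landmark noise the moment arm is recovered with
  bias well under 1 mm and mean absolute relative error well under 5%
  (≈ −0.03 mm and ≈ 2.2% on the default cohort). Individual noisy limbs
  can exceed 5% — with the axis anchored on two sulcus landmarks ~40 mm
  apart, a single 1 mm draw carries ~0.7–0.8 mm SD into the arm, which
  is ~4% of a 20 mm offset — so the noise tolerance is stated on the
  cohort mean; the per-limb distribution is tabulated by
  `analysis/03_recovery_sensitivity.py`.
- Operator-level oracles: common-perpendicular distance vs dense grid
  minimization (1e-6 mm), law-of-cosines angles vs coordinate
  construction (1e-9 deg), median/range vs a sort-based reference.
- Problem sizes: cohorts of 50 limbs at the default mask resolution
  (~0.6M voxels per limb) keep the full validation suite in the
  single-digit seconds on one CPU.

## Numerical choices

- Degenerate triangles (closed triangle inequality) are allowed; |cos|
  may exceed 1 by at most 1e-9 (clamped), beyond which the sides are
  rejected — floating-point safety without masking bad input.
- Directions within 1e-6 rad are parallel (plane separation errors,
  skew distance falls back to point-to-line, pennation returns 0).
- Plane fits reject collinear sets at a 1e-9 relative singular-value
  threshold.
- Mesh vertices are deduplicated at 1e-6 mm on read. STL stores float32,
  so round-trips agree to ~1e-4 mm at limb-scale coordinates.
- All tolerances are named constants in `stiflemetrics.config`.

## Known limitations

- The anatomical frame is one realization of the protocol's viewing
  planes; absolute in-plane lengths depend on it (invariance and
  recovery do not).
- The TT projection index scale is a convention choice (see above).
- Voxel areas use full-voxel membership; partial-volume weighting would
  reduce the (already sub-percent) QCA error.
- Dynamic (through-range) moment arms, cartilage/fat-pad modelling and
  ligament modelling are out of scope, as are mesh repair/smoothing and
  automatic landmark detection or muscle segmentation.
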