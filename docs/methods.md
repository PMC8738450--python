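# Methods

This note documents the models, procedures and design choices behind
`osteoreduce`: how the synthetic anatomy is built, how landmarks are
detected, how the contralateral comparison and the reduction-accuracy
coefficient ρ are defined, and what the session score means. It also states
what the synthetic data does and does not emulate, so it is clear what
passing tests demonstrate about real bones.

## Anatomical frame and conventions

All coordinates are millimetres in a right-handed frame. For a right
humerus the generator uses +z proximal along the shaft axis, +x lateral,
+y anterior; a left humerus is the mirror image across the sagittal plane
x = 0. Detection never relies on this pose — it reconstructs its own frame
from the mesh — but ground truth and mirroring are defined in it.
Anatomical labels follow the anatomy under mirroring: the trochlea of a
right bone maps to the trochlea of the mirrored left bone, whose medial
side then lies at the opposite sign of x.

Axis comparisons are sign-insensitive (angles folded into [0°, 90°]): a
line direction has no canonical sign.

## Synthetic humerus generator

The generator stands in for CT-derived bones, which cannot ship with the
package. A humerus is modelled as the union of analytic primitives:

- a **shaft**: capsule of radius 10 mm along z, its distal end buried
  inside the condylar mass so the distal articular surface is purely
  condylar;
- a **head**: sphere of radius 24 mm centred at the proximal shaft end,
  offset 6 mm posteromedially (the offset also serves as a side cue);
- **trochlea** (medial, r = 12 mm) and **capitulum** (lateral, r = 10 mm)
  spheres centred at the distal end, separated by the mean of their radii
  on each side of the axis;
- **epicondylar bumps** (r = 5 mm) protruding a configurable 8 mm beyond
  the condylar bulge, so the extreme transverse surface points are
  unambiguous epicondyle landmarks;
- a **bicipital groove** carved from the anterior proximal shaft as a
  V-shaped capsule subtraction (channel radius 4 mm, default depth 3 mm),
  2.5 mm shallower at its ends than at its apex so the deepest point — the
  groove landmark — is unique and localizable under surface noise.

The solid is a signed-distance field sampled on a regular grid (default
pitch 1.0 mm, in the 0.5–1.0 mm range typical of segmented surface meshes)
and contoured with marching cubes; exact vertex welding makes the result
watertight. All dimensions default to adult-scale values (~30 cm bone).
Identical parameters and seed give bit-identical meshes.

Two noise processes are available, both smooth random fields built from
seeded sums of plane cosine waves (hence deterministic and
mesh-topology-preserving):

- `surface_noise_sd` (mm): per-vertex displacement along vertex normals
  with 15–40 mm wavelengths — emulates segmentation roughness;
- `asymmetry_sd` (mm): a low-frequency (60–140 mm wavelength) vector field
  applied to the mirrored contralateral bone *and* to its ground-truth
  landmark points — emulates natural left/right asymmetry while keeping the
  left truth consistent with its surface. With `asymmetry_sd = 0` the pair
  is an exact mirror pair, the configuration used for closed-loop tests.

What the generator does **not** emulate: cortical/trabecular structure,
anatomical torsion of the distal humerus, realistic articular curvature
blending, segmentation topology artefacts, or population shape variation.
Tests passing on synthetic bones therefore demonstrate the correctness and
internal consistency of the pipeline — detection equivariance, metric
arithmetic, score behaviour — not clinical-grade landmark accuracy on real
CT meshes, which would need validation against expert annotations.

## Virtual fracture

A supracondylar fracture is a transverse cut just proximal to the condyles.
The default plane sits half an FE-length above the epicondyles with its
normal tilted 10° anteriorly off the shaft axis. Cutting uses a plane
slice of the triangle mesh; each open half is closed with a triangulated
fan over its section loop, so both fragments stay watertight and volume is
conserved to floating-point precision (property-tested at ≤ 0.5%, observed
~1e-14 relative). A cut that misses the bone, grazes a landmark, or
produces more than one section loop raises an error rather than returning
an open mesh.

The injury displacement is a seeded rigid perturbation of the distal
fragment: rotation of uniform magnitude in [5°, 25°] about a random axis
through the distal epiphysis plus a 2–10 mm translation. These magnitudes
are a design choice (chosen to produce deviations on the scale the metric
tolerances expect); the inverse of the accumulated perturbation is kept as
the ground-truth perfect reduction. User moves compose rigid transforms
onto fragments and are exactly volume-preserving.

## Landmark detection

Detection is deterministic, purely geometric, and pose-free:

1. **Orientation.** The principal axis of the vertex cloud defines the
   long axis; a long-bone aspect ratio ≥ 2 is required. The proximal end
   is the end slab with the larger RMS radial spread (the near-spherical
   head beats the flat condylar fan). Regions below are percentiles of the
   axial extent, so they scale with bone size and mesh resolution.
2. **HSA** is refitted as the total-least-squares line through
   cross-section centroids over the middle 60% of the extent.
3. **Head**: trimmed least-squares sphere fit to the proximal 15% cap.
4. **Epicondyles**: extreme surface points along the dominant transverse
   direction of the distal 15% slab.
5. **Trochlea/capitulum**: trimmed sphere fits to the two transverse halves
   of the distally-facing articular surface (distal 5%, outward normals
   pointing away from the shaft, epicondylar extremes excluded). The
   larger fitted radius is labelled trochlea (medial); if the radii are
   within 0.3 mm the posteromedial head offset breaks the tie.
6. **Bicipital groove**: in the anterior channel window (68–83% of the
   extent, below the head cap) each vertex's radial distance to the HSA is
   compared with its cross-section median; the groove is the centroid of
   the near-deepest depressions. Averaging candidates within 0.4 mm of the
   deepest value stops surface noise from sliding the landmark along the
   nearly flat channel floor.
7. **Derived elements**: ECA through the epicondyles, FEA through the
   condylar centers, FE length = condylar span, humeral length = head-to-
   trochlea distance, and the Müller cubes (below).

Sphere and axis fits are linear least squares with explicit degeneracy
checks (coplanar points, identical points). Trimmed refits (keep the best
70–75% by radial residual, twice) reject contamination from adjacent
structures. On 50 seeded bones with 0.2 mm surface noise the median
landmark error is ~0.3 mm and the median axis error ~0.04°, comfortably
under the 2 mm / 2° targets; the acceptance script recomputes these.

The detector treats a reassembled fracture (both fragments under their
current transforms) as a single point cloud — no fragment labels are used,
exactly as a simulator would grade an arbitrary arrangement.

### Müller cubes

The "Müller square" reference volumes are realized as oriented cubes. The
distal cube is centred at the FEA midpoint with axes (FEA, HSA
orthogonalized against it, their cross product) and edge equal to the FE
length; the proximal cube is centred at the head center with the same
construction using the ECA, and edge twice the fitted head radius. Their
sizing and anchoring are this package's design; any construction that is a
deterministic function of the landmark set would slot in equally.

## Contralateral comparison and ρ

The mirrored healthy bone is registered onto the reduced bone by
least-squares rigid superposition (Kabsch; never a reflection, never a
scale) of a shaft-side anchor triplet: head center, bicipital groove, and
the point on the HSA 50 mm distal to the head. Anchoring proximally means
the registration absorbs global pose while distal deviations — where the
fracture is — remain visible as reduction error.

The 15 metrics: six point distances (capitulum, trochlea, head, both
epicondyles, groove), four angles (HSA, ECA, FEA, and FEA-MED — the angle
between the FEA and the trochlea-to-medial-epicondyle direction, compared
between sides), two absolute length differences (FE length, humeral
length), the Jaccard overlaps of the distal and proximal Müller cubes, and
the rotation-triangle area discrepancy. The rotation triangle spans the
two condylar centers and the point where the HSA pierces the distal
transverse plane; a distal malrotation skews it, so the between-side area
difference captures rotational mismatch. It is one plausible construction
of this metric and is deliberately swappable; likewise FEA-MED is one
plausible reading of an underdocumented quantity.

Cube overlap is computed by voxel sampling (pitch = edge/50) in the first
cube's local frame, so the value depends only on the cubes' relative pose
and the whole metric vector is invariant (to 1e-6) under a common rigid
motion of both bones. At that pitch the half-shifted unit-cube test case
reproduces the analytic Jaccard value 1/3 to better than 0.02.

ρ aggregates the metrics with clamped linear sub-scores,
s = clamp(1 − deviation/τ, 0, 1), overlaps entering as themselves, and a
weighted mean with unit weights by default. Default tolerances: τ = 10 mm
for distances and length differences, 10° for angles, 1 mm² for the
triangle area. This aggregation was chosen for monotonicity (ρ never
improves when any deviation grows), boundedness in [0, 1] with ρ = 1
exactly when every sub-score is perfect, and interpretability (each τ is
the deviation at which a metric's credit reaches zero). The tolerances and
weights are configuration, not constants: calibration against expert
ratings of real reductions would replace them.

## Session score

score = (k₁ ρ − k₂ t − k₃ n_c) · h, with defaults k₁ = 1000, k₂ = 0.1 per
second, k₃ = 10 per check, and h = 0.7 applied iff the healthy-template
overlay was used at any moment of the session (the penalty models use, not
duration). Time runs from the first logged event to the finish event;
checks are explicit events only (the final grading itself is not a check).
The score is not clamped — a slow, check-heavy session can go negative —
and template use multiplies a positive score by exactly h. Evaluating the
formula at the two published per-case mean input sets reproduces the
published mean scores (900.76 exactly; 597.99 within the ±0.1 propagated
rounding of two-decimal means), which the acceptance script recomputes.

## Numerical choices and degenerate inputs

- Quaternions are scalar-last unit quaternions; composition `A @ B` applies
  B first. Rigid moves are exactly volume-preserving by construction.
- JSON output uses 9 significant digits and sorted keys, so identical
  configurations yield byte-identical reports.
- Degenerate inputs raise typed errors rather than returning garbage:
  coplanar sphere fits, collinear registration anchors, meshes without a
  long-bone aspect ratio, cut planes that miss the bone, session logs
  without a finish event. A degenerate (collinear) rotation triangle is
  reported as area 0 with a warning, since it legitimately occurs when the
  HSA passes through the FEA midpoint.
- Problem sizes used by the shipped tests and acceptance script — 1.0 mm
  sampling pitch (1.6 mm in the 100-seed watertightness sweep), 50 bones
  for landmark recovery, 1000 random sessions for score monotonicity —
  keep a full run at desk scale while exercising every code path.

## Known limitations

- The detector's regionization percentiles assume humerus-like
  proportions; very short or highly deformed bones fail the aspect test or
  may mis-regionize. Trochlea/capitulum labelling assumes the trochlea is
  the larger condyle (with the head-offset tie-break).
- Comminuted (multi-fragment) fractures, soft-tissue constraints and
  fragment collision are out of scope; the fracture model is a single
  plane cut.
- Deviations are reported as magnitudes only; no signed direction of
  malrotation is given.
- ρ tolerances are defaults, not clinical calibration.
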