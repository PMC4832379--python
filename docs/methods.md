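# Methods

This note records the models, estimators and numerical choices behind
`physis`, in enough detail to judge what the package's validation does and
does not demonstrate.

## Coordinate and unit conventions

All volumes are (z, y, x) arrays with axis 0 the bone's longitudinal axis,
proximal at index 0. Spacing is isotropic and in μm; derived quantities are
μm², μm³, μm⁻¹. Inputs must be pre-oriented; the package deliberately has no
per-operation orientation flags, because a single convention removes a whole
class of silent axis bugs. Anisotropic metadata is rejected rather than
resampled — every morphometric estimator below assumes cubic voxels.

## Plate extraction and body splitting

Cartilage and background can share attenuation after binarization, so the
plate is found geometrically. Closing the bone mask with a Euclidean ball of
radius *r* fills the inter-body gap whenever *r* exceeds half the plate
thickness (the ball can no longer pass through); the new cavity voxels are
plate candidates. The closing is computed with two distance transforms
(threshold-dilate, threshold-erode), which is exact for the continuous ball
and much faster than a structuring-element closing at the radii involved
(our guidance: *r* ≈ 2× the expected plate thickness). Two caveats follow
from the geometry: the ball rolls a shallow groove of depth ≈ *t*²/8*r* into
the open rim of the gap, so a sub-voxel rim ring of cartilage is missed, and
candidate cavities are validated by requiring face contact with both of the
two largest bone bodies.

"Deleting the plate from the bone connectivity graph" needs care: bridges
pass through tunnels in the cartilage, so removing cartilage voxels alone
never disconnects the bodies. The package instead builds a **separator
band**: per transverse column, the longitudinal interval spanned by the
extracted plate, filled across plate-free columns (bridge tunnels) from the
nearest plate-bearing column. Bone outside the band splits into the two
bodies (the one with the smaller mean axis-0 coordinate is the epiphysis);
leftover fragments are claimed by geodesic growth of the bodies through the
bone mask, with a Euclidean nearest-body fallback; bone inside the band is
labelled as plate region and flagged as bridge candidates. The
nearest-column fill breaks ties by scan order, so a handful of voxels at
exactly equidistant rim columns may label differently after a 90° rotation
of the input; the epiphysis/metaphysis decision itself is invariant. If the
split yields fewer than two bodies the specimen is reported as
`fully_bridged` rather than erroring — a fused plate is a finding.

## Bridge definition

A bridge is a 26-connected component of in-band bone that is adjacent to
both the epiphyseal and the metaphyseal body. Adjacency is strict face
adjacency at the default contact tolerance of one voxel; the tolerance (the
`dilation` parameter, in μm) exists because discretization can open a
one-voxel gap where a real bridge meets a body. Components adjacent to only
one body are spurs — partial, not yet bridging — and are excluded from the
count. 26-connectivity keeps thin oblique bridges single objects; face
adjacency keeps contact claims conservative.

Whether two mineralized contacts a few μm apart are "one bridge" or "two" is
genuinely ambiguous at the biology level, so the package does not decide:
`merge_touching_bridges` exposes single-linkage merging at a caller-chosen
separation, with 0 (no merging) as the default.

Per-bridge measures: volume = voxel count × spacing³; centroid in physical
μm; minimum transverse cross-section = the smallest per-slice voxel count ×
spacing² along the component. Note the cross-section of a bridge clipped by
the band edge can be a single voxel; the measure describes the detected
component, not an idealized column.

## Projection, density, quadrants

Bridges project as centroids (one point per bridge), which makes every map
count-conserving by construction. Density windows tile the plane from a
fixed anchor with half-open [left, right) intervals — a point exactly on a
boundary goes to the higher-index tile — and the grid auto-expands rather
than dropping outliers. Mean areal density divides the total count by the
number of windows overlapping the projected plate footprint, not by a
bounding box, so anatomy-free windows do not dilute the rate; this choice is
exposed in the API (pass a different footprint to change it). Quadrant
splitting takes the medial direction from configuration (anatomical
registration is input, not inferred), derives anterior as medial rotated
+90° in the transverse plane, and sends boundary points to the
medial/anterior side.

## Morphometry estimators

**Local thickness (Tb.Th)** follows the largest-inscribed-sphere definition:
the thickness at a voxel is the diameter of the largest sphere containing it
that fits in the structure. Candidate radii are Euclidean distance-transform
values; spheres are painted in descending radius order (numba kernel), a
sphere of radius *r* claiming voxels within *r* − ½. Mean and SD are taken
over structure voxels. On a slab of thickness *t* the interior reads exactly
*t*; the whole-structure mean is biased low by the lateral edge band, which
is why validation measures the interior.

**Surface area** triangulates the zero level of the signed Euclidean
distance field (half-voxel-corrected so the interface sits midway between
boundary voxel centres), after Gaussian smoothing with σ = 0.7 voxels.
Unsmoothed, the EDT is quantized near the boundary and marching cubes
inherits the binary faceting bias (≈ +8% on a sphere); σ = 0.7 suppresses it
(sphere within ~1% of 4πr²) while keeping the edge rounding it causes on
rectilinear solids under ~5% for edges ≥ 20 voxels. A 3-direction Crofton
intercept estimate is available as `method="crofton"`; it is unbiased for
isotropically oriented surfaces but reads only ⅔ of a strictly axis-aligned
face, and is provided for cross-checking, not as the default.

**SMI** uses the dilation-derivative definition SMI = 6·V·S′/S², the one
under which an ideal plate, cylinder and sphere score 0, 3 and 4. S′ is
realized by displacing every vertex of the triangulated surface along its
outward normal by ε (default one voxel) and recomputing the area of the
*same* mesh. Re-meshing the dilated solid instead is numerically wrong here:
the faceting bias of marching cubes on distance fields varies with the iso
level, and the finite difference amplifies that variation catastrophically
(a sphere reads ≈ 1.5 instead of 4). Keeping the connectivity fixed cancels
the bias; the residual error is the O(ε/r) bias of the one-sided difference
plus sub-0.2% vertex-normal jitter (the quoted invariance tolerance). SMI is
dimensionless and exactly independent of spacing. Structures thinner than
two dilation steps trigger a warning — the derivative is unreliable there.

**Convergence of the ideal-shape suite.** The anchors 0/3/4 hold for
*unbounded* plate and cylinder; any finite digitization carries a
finite-extent term (≈ 24·t/L for a t×L×L slab, ≈ 6·r/L for a cylinder) that
is scale-invariant and therefore unaffected by uniform voxel refinement. The
fixture suite accordingly refines the plate and cylinder by doubling their
lateral extent/length at fixed thickness/radius — aspect-ratio growth toward
the ideal — and the sphere (whose error is purely discretization) by
doubling its radius. At the finest level the suite reads 0.09 / 3.01 / 4.00.

## Binarization

Otsu thresholding is computed on the exact value histogram when the volume
has ≤ 4096 distinct values, with the realized threshold placed at the
midpoint between the two classes; the generic fixed-width-bin estimator can
cut through a populated bin on few-valued (noise-free synthetic) data and
silently move a whole phase across the threshold. Continuous data falls back
to the standard 256-bin estimator. The realized threshold is always recorded
in provenance, and masking is `attenuation ≥ threshold` in both modes.

## The phantom generator

`make_plate_phantom` renders the structures the pipeline is designed to
measure: two mineralized cylinders (intensity 100) separated by a cartilage
layer (intensity 10, background 0) of configurable thickness, optionally
domed (paraboloid mid-surface, apex proximal, dome height = curvature ×
footprint radius), pierced by bone-intensity pegs crossing the layer with
two voxels of overshoot into each body, plus additive Gaussian noise before
binarization. Pegs are cylinders parallel to the longitudinal axis rather
than normal to the local mid-surface: at the curvature range supported
(0–0.3, local tilt ≤ 31°) an axis-aligned peg still crosses the layer,
and the choice keeps the analytic π·r²·h volume oracle and the ground-truth
centre definition exact. Placement is rejection-sampled under a minimum
mutual separation from a seeded generator; identical spec + seed is
bit-reproducible.

Reference study conditions (the generator defaults): 64×96×96 voxels at
5 μm — a ≈ 0.3 × 0.5 × 0.5 mm field around the plate, laboratory-CT scale —
plate thickness 30 μm, curvature 0.1, 12.5 μm peg radius, ≥ 30 μm mutual
separation, noise SD 5% of bone intensity. These are chosen to emulate a
murine proximal tibia scanned at moderate resolution; scaled down in grid
size so that the 50-phantom validation sweep and the full test suite run in
minutes on one CPU.

What the phantom does *not* emulate: trabecular texture, beam hardening,
ring artifacts, partial-volume gradients at interfaces, marrow/soft-tissue
intensities, or non-cylindrical bridge shapes. Passing the planted-recovery
suite therefore demonstrates the topology and bookkeeping of the pipeline —
counts, positions, conservation, determinism — not robustness to scanner
physics; on real scans the binarization and closing-radius parameters
remain the user's responsibility (all realized parameters are logged to
provenance YAML).

## Pipeline and reporting

Specimens are processed independently; an error in one produces an error
row and exit code 2, never a cohort abort. Group summaries report
mean ± SEM (SEM = sd/√n, sample sd). All CSV floats are written with a
fixed `%.6g` format, making repeated runs byte-identical; timings live only
in provenance files. The only randomness in the whole system is phantom
synthesis, driven by a single config seed.

## Known limitations

- Bridge granularity is parameter-dependent (see merging above).
- The projection is orthogonal, not geodesic along the curved articular
  surface; for strongly domed plates, peripheral densities are compressed.
- The minimum cross-section is band-clipped (see bridge measures).
- Crofton areas are directionally biased on axis-aligned structures.
- The headline quantities of interest on real scans (bridge counts per
  tibia, Tb.Th of real cartilage) depend on acquisition and segmentation
  parameters not reproducible from synthetic data; the package validates
  estimator correctness, not scanner-specific values.
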