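# Methods

## Problem and scope

Surgical closure of ventricular septal defects (VSD) and intracardiac
rerouting use hand-cut patch material whose size and shape are decided
intraoperatively. A digital patch template is designed on a segmented
3D heart model before surgery: the clinician marks the intended patch
circumference on the mesh, the marked points are interpolated into a
closed ring conforming to the anatomy, the ring is swept into a curved
surface whose doming the clinician controls, and the result is
thickened into a printable shell. holopatch implements that geometry
engine together with the analytics used to compare patch-design
methods against a digitised reference of the actually implanted patch
(the DRP): surface area, discrete Gaussian curvature with dome/saddle
classification, principal-component diameters, self-intersection
("double fold") detection, and Bland–Altman / ratio / paired-t method
comparison. All coordinates are millimetres.

Image segmentation, rendering, head-mounted-display integration and
tissue biomechanics are out of scope; meshes arrive pre-segmented.

## Boundary marking

Two marking modes are modelled. In sphere marking, an ordered sequence
of fingertip sphere centres is tested against the heart mesh; for each
centre the closest contact point among the triangles the sphere
overlaps is kept, and consecutive near-duplicates (default 0.25 mm)
collapse. In anchor-point marking, explicitly placed points snap to
their closest surface points and may be adjusted and re-snapped; fewer
than 10 anchors triggers a warning (typical practice, not a hard
precondition). Proximity queries run through a k-d tree over triangle
centroids with per-triangle circumscribing radii; candidate sets are
pruned by the triangle inequality and tested exactly, so every query
is guaranteed identical to a brute-force scan (ties break toward the
lowest triangle index). Queries are exact because the tree only prunes.

## Ring interpolation

The marked loop is interpolated by a closed uniform Catmull–Rom spline
(a periodic interpolating cubic): it passes through every knot exactly,
has local support (moving one marked point perturbs only four spline
segments, matching the interactive editing workflow), and needs no
global solve. Samples are evenly spaced in spline parameter. With
`conform=True` every sample is projected to its closest surface point
so the ring lies on the anatomy; only ring samples are projected, never
interior surface points — the patch spans the defect and must not snap
into the hole. The largest residual projection distance is reported
against a default tolerance of 0.5 mm. A knot sequence that doubles
back is deliberately not rejected at this stage; the resulting pleat is
caught downstream (see fold detection).

## Patch surface

The ring midpoint is the arithmetic mean of the samples; the ring
normal is the smallest-variance principal axis of the samples, signed
toward the marking side when a reference is given. The apex sits at
`A = M + h n̂`, where the signed height `h` (mm) is the single
curvature dial exposed to the user. Each of `n_spokes` boundary
samples `P` is joined to the apex by a cubic Bézier with control
points

    B0 = P
    B1 = P + (1/3) T(A − P)
    B2 = A − (1/3) T(A − P)
    B3 = A,      T(v) = v − (v·n̂) n̂

so the surface leaves the boundary within the wall's tangent plane and
arrives at the apex tangentially — a rounded dome, flat at the apex.
(Placing `B2` at `A − (1/3) h n̂` instead, i.e. below the apex on the
axis, makes every spoke arrive along the normal and produces a cusp;
the tangential form is used because it yields the intended smooth
dome while keeping `h` as the only parameter.) With `h = 0` and a
planar ring all control points are coplanar and the patch degenerates
exactly to the flat disc. Spokes are tessellated into
`n_spokes × n_rings` quads split into triangles with the apex closing
the centre; the surface boundary reproduces the ring samples
bit-exactly. Defaults are 128 spokes × 32 rings, at which the flat-disc
area is within 0.06% of π r² and refinement to double resolution
changes the area of smooth patches by well under 0.5%.

## Solidification

The printable shell is the template surface offset by the requested
thickness along area-weighted vertex normals, plus the original surface
with reversed winding, plus a side wall stitching the two boundary
loops; global orientation is fixed by requiring positive enclosed
volume. The result is watertight (every edge shared by exactly two
triangles, Euler characteristic 2) and, for gently curved patches, has
volume ≈ area × thickness (within 2% for a flat disc). A template
carrying a self-intersection is refused rather than repaired: silent
repair would change the areas being compared, so the user is forced
back through fold detection and re-marking. Reported patch areas are
always template mid-surface areas, not shell areas.

## Fold ("double fold") detection

Imprecise marking — e.g. a stroke arc placed in an adjacent parallel
plane and doubling back — pleats the interpolated surface into
non-adjacent triangle pairs that cross. Detection is exact: candidate
pairs come from axis-aligned bounding-box overlap (chunked vectorised
culling), pairs sharing a vertex are excluded, and survivors undergo a
plane-interval triangle/triangle test, with a 2D polygon-overlap test
for the coplanar case. Grazing contact within the floating-point
threshold (1e-10 of the mesh scale) is not reported; a fold is a
genuine crossing. On the standard synthetic wall fixture, a single
displaced-arc fold produces dozens of intersecting pairs while
changing the patch area by only a few percent (under 10%) — the fold
corrupts curvature statistics far more than area.

## Synthetic anatomy

Patient meshes are not redistributable, so the study conditions are
emulated: a wall segment (flat, or lifted onto a sphere of given
radius) carrying an elliptical defect, meshed by Delaunay over a
jittered lattice with an explicit rim polygon; a marking stroke of
sphere centres circling the rim at a fixed offset with isotropic
Gaussian hand jitter; and a long-format evaluator cohort in which true
patch areas are lognormal across patients (log-mean 5.6, log-SD 1.0,
i.e. a median near 270 mm² spanning a >20× range, fitted to published
per-patient reference areas) and each evaluator's measurement
multiplies the truth by a per-method bias and mean-one lognormal noise
of given coefficient of variation (default 0.2). Default biases are
0.84 for the mixed-reality method and 0.84/1.42 for the desktop method,
matching the published ratio structure; diameters derive from area via
a fixed-aspect (1.3) ellipse. Every generator is a pure function of
its parameters and seed.

What the generators do not emulate: real septal anatomy (trabeculae,
valve apparatus), non-elliptical defect shapes, correlated evaluator
error, and scanner artefacts beyond isotropic noise and gross
outliers. Passing tests therefore certify the geometry and statistics
pipeline, not clinical accuracy on patient data.

## Reference patch (DRP) reconstruction

A scanned point cloud of the surgical leftover material is digitised
automatically: statistical outlier removal on mean 8-NN distances
(default cut 3 SD above the mean — gentle enough to keep the scanned
outline, whose edge points sit in the natural tail of the k-NN
statistic); PCA plane fit with a sheet-likeness gate (out-of-plane
spread must be < 0.3 of in-plane spread); projection to 2D; an alpha
complex of the projected Delaunay triangulation (alpha defaults to 3×
the median nearest-neighbour spacing, tightening the hull to the
scanned outline) with the largest connected component kept; and a
moving-least-squares quadratic lift of the vertices off the plane,
which smooths scanner noise (0.1 mm class) while preserving genuine
curvature — a radius-50 mm cap reconstructs to within 0.2 mm.
Reconstruction handles a single contiguous scanned object; registering
multiple fragments is out of scope.

## Patch metrics

Area is the sum of triangle areas. Gaussian curvature uses the
angle-deficit estimator `K(v) = (2π − Σ angles at v) / A_mixed(v)`
with the obtuse-safe mixed Voronoi area; boundary vertices are
excluded (their fan is incomplete) and non-manifold vertices are
excluded with a warning. The estimator satisfies Gauss–Bonnet exactly
on closed surfaces (Σ K·A_mixed = 4π for genus 0) and converges on a
sphere with refinement. Summaries are mean, median and IQR (linear
interpolation between order statistics); classification is dome
(K_mean > ε), saddle (K_mean < −ε) or flat, with ε = 1e-4 mm⁻² (the
curvature of a 100 mm sphere). Both pooled per-vertex summaries and
per-patch means are obtainable, since published curvature medians are
ambiguous between the two. PCA diameters are the extents of the vertex
cloud along its first two principal axes; they are bit-stable under
rigid motion for non-degenerate shapes, but for rotationally symmetric
patches the in-plane axes are arbitrary (extents then agree only to
the polygonal asphericity, a format-of-the-question limit, not a bug).

## Comparison statistics

Pairing defaults to per-record (every patient × evaluator pair), with
single-record reference methods (DRP, CT) broadcasting across that
patient's evaluators; per-patient-median pairing is also exposed.
Bland–Altman reports mean difference, SD (n−1) and limits of agreement
mean ± 1.96 SD. Ratio summaries report the median and IQR of per-pair
ratios. The paired test is a one-sample two-sided Student t on the
signed differences with a t-quantile 95% CI; a zero-variance sample is
flagged degenerate. No multiple-testing correction is applied (two
comparisons are reported descriptively, mirroring field practice).
Percentiles are type-7 (linear interpolation) throughout.

## Numerical choices and limitations

- Vertex merge on import: 1e-6 mm (STL duplicates vertices per facet).
- Binary STL stores float32; round trips are bit-faithful at that
  precision (~1e-7 relative on area for generic float64 meshes, exact
  for representable coordinates).
- Tie-breaks: closest-triangle ties take the lowest triangle index;
  ring ordering starts at the first point and normalises to CCW about
  the best-fit normal with a deterministic sign.
- Degenerate inputs: zero-area triangles are dropped at construction;
  collinear rings and non-sheet clouds raise geometry errors rather
  than returning garbage.
- Problem sizes in the test and acceptance runs (default tessellation
  128×32, walls at 1–1.5 mm steps, clouds of 1–3 k points, 100-seed
  recovery runs) were chosen so each check completes in seconds while
  keeping discretisation error an order of magnitude below each
  tolerance.
- The Bézier parameterisation of the interactive application this
  emulates is proprietary; the per-spoke construction here is one
  defensible choice, and absolute areas of curved patches depend on it
  (flat-limit areas do not).
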