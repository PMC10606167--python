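# Methods

This note records the geometric definitions, parameter defaults and
numerical choices behind the 22-measurement pipeline, and what the
synthetic phantoms do and do not establish about real data.

## Coordinate conventions

All geometry is in millimetres in the LPS (left–posterior–superior) world
frame.  Units and frame are declared, never inferred: mesh and landmark
files are read as mm/LPS verbatim, and NIfTI/NRRD affines are taken as
voxel→LPS exactly as stored.  No RAS/LPS flip is ever applied — a silent
frame conversion is the classic failure mode in this kind of pipeline, so
a mis-declared file fails loudly downstream (e.g. negative coronary
heights raise QC flags) rather than being "fixed" silently.

## Centerline

The lumen axis through the LV outflow and aortic root is extracted by
Laplacian-based contraction: the surface (subdivided to ≥ 1 sample/mm² if
coarser) is iteratively smoothed by solving, per iteration, the sparse
least-squares system that balances a cotangent-Laplacian contraction term
against per-vertex attraction anchors.  The contraction weight starts at
ratio 64:1 against the anchors (after normalizing the Laplacian to unit
mean diagonal) and doubles each iteration; anchor weights stiffen as each
vertex's one-ring area collapses (∝ √(A₀/Aₜ)).  Iteration stops when the
surface area has collapsed below 0.5% of the original (the signature of a
fully contracted skeleton), when the mean displacement falls below
0.01 mm, or after 20 iterations; failure to collapse below 20% raises a
convergence error with diagnostics.  Degenerate-triangle cotangents are
clamped so the near-flat contracted mesh stays solvable.

The contracted vertex graph (original connectivity, contracted edge
lengths) is reduced to its longest geodesic path by a double farthest-point
sweep; side branches — papillary-muscle artifacts, coronary stubs — are
discarded, because the anatomy of interest is a single lumen axis.  The
raw path is then smoothed (median over an 8 mm arc-length window, then a
cubic smoothing spline with a 0.3 mm per-point residual budget) and
re-centered twice: each node moves to the centroid of the mesh
cross-section perpendicular to the local tangent.  The re-centering
matters: pure curve contraction shortens a bent axis toward its chord —
on a 60 mm-radius bend the raw skeleton sits 0.6–1.4 mm inside the true
axis, and two centroidal passes bring it within ≈ 0.1 mm.  Unit tangents
are evaluated by a symmetric finite difference over ± 2 mm of arc length;
a single-segment difference would pass the skeleton's sub-millimetre
wobble straight into the orientation of every sliding plane.  All of
these knobs live in `LBCParams`.

The centerline is resampled at 0.5 mm and oriented so arc length 0 is the
LV end, defined as the path end farther from the nadir centroid (the LV
cavity below the annulus is longer than the root + ascending segment
above it in these meshes).

A second extractor, `extract_centerline_marching`, tracks cross-section
centroids plane by plane from a seed.  It is exact on a cylinder (the
centroid of every elliptical section of a cylinder lies on the axis) and
serves as an independent cross-check of the contraction path in the test
suite, ending cleanly when the plane exits the mesh or reaches an end cap.

## Planes and sections

* **Annulus plane** — through the three nadirs: origin at their centroid,
  normal the unit triangle normal signed toward increasing arc length
  (toward the aorta).  A nadir triangle under 1 mm² is refused ("nadir
  geometry implausible") — it indicates a failed detection, not anatomy.
* **LVOT plane** — the annulus plane translated 4 mm down the centerline,
  *keeping the annulus normal*.  This pure-translation coupling is
  deliberate: a nadir error tilts the annulus plane and must propagate
  into every LVOT measurement, which is exactly how the measurements
  behave clinically.
* **Profile planes** — 1 mm-spaced stations above the annulus, each
  perpendicular to the local centerline tangent (`orientation_mode =
  "tangent"`; `"annulus_parallel"` is available for sensitivity checks).
  The search stops 40 mm above the annulus (`sov_search_max_mm`) so a
  dilated ascending aorta cannot capture the maximum.
* **SOV plane** — the station of greatest cross-sectional area, refined
  sub-station by a parabola through the argmax and its two neighbours.
  The refinement is a numerical necessity, not a cosmetic one: on the
  bulge flank the radius changes at ≈ 0.9 mm/mm, so a station quantized
  to the 1 mm grid can shift the per-sinus diameters by several percent.
  An argmax on the search boundary raises a QC flag.
* **SNTJ plane** — the smallest station above the SOV where the relative
  area change stays below 2% for 3 consecutive 1 mm steps
  (`sntj_rel_tol`, `sntj_window`).  "Starts to stabilize" is not a sharp
  mathematical definition; this finite-difference plateau detector is the
  minimal reading, and when no station qualifies the station of minimum
  |dA/ds| is used with a QC flag.  Note the detector inherently fires
  slightly before an exact plateau (where the area-change rate first
  drops under the threshold), roughly a third of the bulge half-width
  early on the synthetic roots.

Cutting a plane through the mesh can yield several closed loops (root
plus coronary stub, both limbs of a curved LV).  The loop whose interior
contains the in-plane projection of the anchor (the centerline point the
plane was seeded from) is kept — the smallest such loop if nested — with
nearest-centroid fallback.  Loops under 1 mm² are degenerate.  Contours
are ordered counter-clockwise about the plane normal; area is the planar
shoelace sum, the perimeter the polyline length, the centroid the area
centroid.

## Diameters

Minimum/maximum diameters scan chords through the section centroid every
0.5° (`angular_step_deg`); each chord spans the outermost contour
crossings on the two sides, directions that fail to cross both sides
(non-star-shaped contours) are skipped.  The scan grid is anchored to the
contour itself — θ = 0 points toward the vertex farthest from the
centroid — so the result is independent of the world frame; a
world-anchored grid would shift phase against the polygon under rotation
and break rigid invariance at the 10⁻⁵ level.  The brute-force 0.01° scan
is reserved for test oracles.  `diameter_avg` is (min + max)/2, the
standard TAVI-sizing convention.  Derived diameters are
d_area = 2√(A/π) and d_perim = P/π; the isoperimetric inequality
guarantees d_perim ≥ d_area, which the report validator enforces.

Per-sinus diameters at the SOV plane: each nadir is orthogonally
projected onto the plane; the full line through that projection and the
section centroid is intersected with the contour; the diameter is the
distance between the two crossings (outermost pair, with a "non-convex
sinus contour" QC flag, when there are more than two).  Diameters are
named lcc/rcc/ncc after their nadirs.  Coronary heights are the signed
perpendicular distances (ostium − origin)·normal; the report carries the
unsigned value with a QC flag whenever the signed value is ≤ 0, because a
non-positive height means the landmarks or the plane failed, not that the
anatomy is below the annulus.

## Phantom generator

The phantom sweeps a polar radius field r(s, φ) along a straight or
circular-arc axis.  The base profile runs r_lvot → r_annulus (6 mm
smoothstep below the annulus) → r_stj (5 mm smoothstep above) → r_aorta.
Each sinus adds a separable bump: a raised-cosine angular lobe of 120°
support centered on its nadir azimuth (adjacent lobes meet C¹ at the
commissures), times a compact truncated-Gaussian axial bump that is
exactly zero beyond ± bulge_width_mm of the bulge belly.  The compact
support is what gives the SNTJ its analytic truth: above the bulge the
radius is *exactly* constant, so the plateau onset is a well-defined
station.  Nadirs sit on the annulus ring at the lobe centers, which makes
the nadir-projection sinus rule hit each lobe's peak; ostia sit on the
sinus wall at prescribed heights.

Defaults describe a TAVI-typical adult root: annulus radius 12.5 mm
(area 490.87 mm²), sinus peaks 17 mm at 10 mm above the annulus with a
5 mm axial half-width, STJ/aorta radius 14 mm, ostium heights 14/12 mm,
segment lengths 60 (LV) + 22 (root) + 30 (aorta) mm.  The LV segment is
deliberately longer than root + aorta so the orientation convention (LV
end = farther end) is well-posed, as it is in real LV + root meshes.  The
mesh is a closed 2-manifold (96 vertices per ring, 1 mm ring spacing,
fan caps); optional radial surface noise is uniform in ± noise_mm,
seeded, applied to wall vertices only, and never touches the analytic
truth.

Ground truth is computed by dense numerics, never by the pipeline:
10⁴-point azimuthal quadrature for areas/perimeters/centroids, a 0.01°
chord scan on the analytic contour for the diameters, root-finding of the
plane crossing per meridian for oblique sections of curved phantoms, and
closed forms where they exist (the annulus is exactly a circle).

What the phantoms do **not** emulate: leaflets and calcification,
CT-intensity artifacts, segmentation errors beyond smooth radial noise,
openings (coronary ostia are points, not holes), and realistic population
shape statistics.  Passing the recovery grid therefore demonstrates the
*measurement derivation* is correct given a faithful mesh and landmarks;
it says nothing about segmentation or landmark-detection quality on real
scans, whose failure modes enter here only as QC flags.

## Agreement statistics

Mean absolute relative error uses the second rater (the expert) as
reference, per case e = |a−b|/|b|·100.  Confidence intervals use the
half-width Z·s/√(n−1); the √(n−1) denominator is the printed convention
this package reproduces by default, with `ci_denominator="n"` exposing
the standard-error form.  Pearson r carries a Fisher-z interval with
SE = 1/√(n−3) (the method is recorded in the output since other CI
constructions exist).  Bland–Altman limits are mean(d) ± 1.96·sd(d) with
the sample (n−1) standard deviation; both the signed mean difference and
the absolute relative error are emitted, since published comparison
tables mix the two.

## Landmark mask post-processing

Each of the five channels is binarized at 0.5 (strictly greater),
labelled with 26-connectivity (6/18 available in config; the choice only
matters for pathological masks), the largest component kept (ties go to
the component holding the lexicographically smallest voxel index), and
the unweighted voxel centroid mapped through the affine.  An empty
channel yields "absent", which `masks_to_landmark_set` turns into a
missing-landmark error naming the landmark.  Spherical training masks of
radius 5 are treated as voxels on the 1 mm grid, where the distinction
from mm vanishes.

## Numerical choices and edge cases

* Plane in-plane bases project world +x (or +y when degenerate) — any
  fixed convention works, metrics are basis-invariant.
* Resampling preserves endpoints by using spacing L/round(L/spacing);
  re-resampling is exactly idempotent only when nodes have equal chords
  (straight segments, symmetric arcs) and otherwise reproduces nodes to
  the polyline discretization error.
* Chord scans can lose a crossing to an exact-vertex float hit
  (u ∈ [0,1) on neither adjacent edge); such directions are skipped like
  any non-star-shaped direction and are vanishingly rare (≈ 3 in 18 000
  on a dense ring).
* `allow_partial` lets a case with a failed SOV/SNTJ search or LVOT cut
  still emit the blocks that succeeded, with NaN placeholders and the
  failed stages listed in metadata; by default any stage failure aborts
  the case with a stage-tagged error.
* Problem sizes used in the validation suite — 96-ring phantoms
  (≈ 18 k faces), a ≥ 20-spec recovery grid, 10 rigid transforms, 200
  jitter draws per σ — were chosen to exercise every code path at mesh
  resolutions where discretization error sits well below the recovery
  tolerances.

## Known limitations

* The centerline extractor assumes a single tube-like lumen; true
  branching vasculature is out of scope (side branches are pruned).
* Sections are measured on the polygonal mesh as-is; there is no
  sub-triangle curvature-aware smoothing, so measurements inherit the
  mesh's inscription bias (≈ 0.07% area deficit at 96 vertices/ring).
* The SNTJ stabilization detector is one reasonable formalization of a
  qualitative definition; its station shifts with `sntj_rel_tol` and the
  bulge sharpness, which is why the QC flag and the config knobs exist.
* No valve-size recommendation, calcification scoring, or femoral-access
  measurements are attempted.
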