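# Methods

`stenoscan` re-creates, as desk-scale software, the computational core of a
robot-guided B-mode ultrasound examination of a dialysis arteriovenous
fistula (AVF): plan a scan path over the access, acquire cross-section
frames along it, delineate the vessel boundaries in every frame with an
active contour model, stack the contours into a 3D vessel model, and grade
the stenosis.  Because no scanner is attached, a phantom simulator stands in
for the hardware and supplies exact ground truth for every measurement.

## Degree of stenosis

The clinical quantity is the degree of stenosis

    DOS% = (1 − d²/D²) × 100,

with `D` the vessel diameter and `d` the residual patent diameter at the
plaque.  The squared ratio makes this an area ratio for circular lumens;
it is scale invariant, so pixel- and millimetre-unit diameters agree.
Severity grading: DOS < 30% mild, 30–50% moderate (both endpoints
inclusive, a documented choice where the verbal definition is ambiguous),
> 50% severe — the threshold at which angioplasty is indicated.

Diameters are extracted from closed contours as area-equivalent diameters,
`2·sqrt(A/π)` with the polygon area from the shoelace formula.  Whether a
clinically reported `d` is a linear patent thickness or an area-equivalent
diameter is ambiguous in general; the squared-ratio form of the DOS is
consistent with circular-area equivalence, which is the default here (for
the concentric circular lumens of the phantoms the two coincide).

## Phantom simulator

The generator emulates a grid of nine printed stenosed-vessel phantoms in
a water tank: vessel types A/B/C with lumen diameter D = 10/8/5 mm,
stenosis classes I/II/III with target DOS near 20/40/80%, giving design
pairs (d, D) = (9,10), (7.8,10), (4.5,10), (7,8), (6.2,8), (3.5,8),
(4.5,5), (3.9,5), (2.2,5) mm.  The lumen diameter profile along the
centreline is a symmetric cosine taper from D down to d over the plaque
extent — smooth, differentiable and monotone on each flank.

Geometry defaults (chosen once; the sources state none of them):
centreline length 60 mm, stenosis centred at 30 mm, plaque extent 10 mm,
wall thickness 1.5 mm, straight or arc centreline, concentric lumen
(an eccentric mode offsets the lumen for robustness experiments).

Appearance: the physical phantom is a single printed resin, so plaque and
wall are one material.  A noise-free frame is piecewise constant at three
levels — patent bore (water) 0.05, phantom material 0.90, tank background
0.40 — and the only echogenic boundaries are the bore surface and the
outer material surface; the D-circle (plaque/wall interface) is not
visible, exactly as in a one-material phantom.  Speckle is modelled to
first order as multiplicative unit-mean gamma noise with relative standard
deviation 0.5 (the contrast scale of fully developed speckle), followed by
a Gaussian point-spread blur of σ = 0.15 mm (consistent with the axial
resolution of a 7.5 MHz linear probe).  Frames are 256×256 at 0.1 mm/px
(a 7.5 MHz probe with 38 mm footprint makes sub-millimetre pixels
realistic).  Rendering is a pure function of (spec, position, grid, noise
parameters incl. seed); frame k of a series uses seed `base + k`.

What the simulator does *not* model: depth-dependent attenuation and
focusing, anisotropic point spread, refraction and reverberation
artifacts, probe pressure deformation, tissue layers around the vessel,
and operator motion.  Passing the recovery tests therefore shows the
pipeline is correct and unbiased under first-order speckle imaging of
known geometry; it does not certify performance on clinical images.

## Active-contour segmentation

A snake is a closed contour v(s) minimizing internal plus external
energy; the internal energy `α|dv/ds|² + β|d²v/ds²|²` penalizes length
(elasticity) and bending (stiffness), the external energy is the image
functional `ω_line·E_line + ω_edge·E_edge + ω_term·E_term` (the
constraint term is fixed to zero).  `E_line` is the smoothed intensity,
`E_edge = −|∇I|²`, and `E_term` is the curvature of the level lines of an
extra-smoothed copy (2 px), the standard termination functional.
Discretization: uniform parameterization over vertex index, cyclic finite
differences (so a regular N-gon has per-vertex elasticity `α·(P/N)²`),
totals as means over vertices, image terms sampled by bilinear
interpolation with out-of-domain positions clamped and counted.

Two numerical choices matter and are deliberate:

* **Field normalization.** `E_edge` and `E_term` are scaled per frame to
  unit maximum magnitude.  Raw `|∇I|²` of a [0,1] image is ≤ ~0.25 while
  the elasticity term is O(10) px² at default vertex spacing; without
  normalization the internal energy drags any contour off any edge.
  Within `segment_frame`, each snake's edge weight is additionally
  rescaled by the edge strength sampled along its own initialization ring
  ("well equalization"), so a boundary weaker than the strongest edge in
  the frame still sits in a unit-depth well.  Fields are fixed before
  evolution, so none of this affects monotonicity.
* **Minimizer.** Deterministic greedy neighborhood search: vertices are
  visited in index order; a vertex moves only when a position in its
  (2r+1)² neighborhood strictly lowers its local energy (all energy terms
  containing that vertex), ties among improving candidates resolved by
  lowest energy then row-major offset order.  After each pass the contour
  is resampled to uniform arc length *only if* that does not raise the
  total energy.  Total energy is therefore non-increasing across
  iterations by construction, and at full convergence
  (`move_tolerance = 0`) no single-vertex move in the search neighborhood
  improves the energy — a property checked against brute-force
  re-evaluation through the independent `snake_energy` path.

A consequence worth stating plainly: at the default stiffness β = 0.4 a
lone 1 px vertex move always incurs a curvature penalty (≈ 3β·2) larger
than any normalized image well, so the greedy snake cannot make isolated
sub-pixel corrections; it corrects *correlated* displacements (moving one
vertex toward its displaced neighbors lowers curvature) and guards energy
consistency.  Large-scale contraction through flat regions similarly
requires the stiffness term to be disabled (elasticity alone shrinks a
ring toward the nearest edge well).  Localization accuracy therefore
rests on the initializer.

**Initialization and measurement.**  From a seed inside the dark bore,
rays are cast at the contour's vertex angles.  A threshold crossing
brackets each edge — 50% of the dark-to-bright range for the bore (the
half-height crossing of a blurred step sits at the edge centre), 70% for
the outer surface, taking the *last* crossing along the ray — and the
edge is then localized at the radial gradient extremum with parabolic
sub-sample refinement.  A threshold crossing alone is one-sidedly biased
under speckle (fluctuations can only retreat it); the gradient-peak
jitter is symmetric, and it is the same feature the snake's edge energy
attracts to.  A circular median filter (window 5) over the per-ray radii
rejects rays that shot through a speckle void.  The greedy snake then
refines both rings.  A user-supplied polygon can replace either
initialization, standing in for the clinician's interactive adjustment.

Because the phantom is one material, the vessel boundary (diameter D) is
not echogenic.  The vessel contour is derived from the converged outer
contour by a fixed inward normal offset of the wall thickness (1.5 mm, a
design constant of the phantom, analogous to measuring the adventitia and
subtracting the wall).  At plaque-free slices the bore and the derived
vessel contour coincide on the same physical edge; the nesting guard
allows 2.5 px of coincidence jitter and `d` is clipped to `D`.

**Sequential propagation** re-seeds each frame at the previous frame's
lumen centroid.  The warm start carries position, not shape: a greedy
snake has no inflation force, so a contour carried verbatim into a frame
where the lumen has widened (plaque edge → healthy vessel between
adjacent slices) would strand inside the lumen and collapse.

Default parameters: α = 0.1, β = 0.4, ω_line = 0, ω_edge = 1,
ω_term = 0.3, search radius 2 px, 64 vertices, ≤ 200 iterations, stop
when < 5% of vertices move; pre-smoothing σ = 0.15 mm, matched to the
point-spread width (smoothing well beyond the PSF widens the edge wells
until the elasticity bias exceeds a pixel).  All parameters are recorded
in every report.

## Scan paths

Sites A (arterial anastomosis), L (loop) and V (venous anastomosis) are
marked in workspace coordinates; at least three are required.  For looped
accesses the circle through first/middle/last site is constructed from
the perpendicular bisectors of two chords (through the chord midpoints);
poses are sampled along the arc from the first to the last site, directed
so the middle site lies on the traversed arc, with `theta` the polar
angle about the circle centre.  Straight accesses get a polyline plan
with `theta = 0`.  Near-collinear sites (triangle area below tolerance)
raise a degenerate-geometry error advising the linear method.  The native
capture spacing is speed/frame-rate (0.5 cm/s at 1 Hz → 5 mm); a plan
coarser than that is flagged as requiring interpolated slices.  Arm
workspace limits are validated with a flag, not an error — the package
drives no hardware.

## 3D reconstruction

Each frame's contour (converted to mm about the image centre, plus the
plan radius for arc scans) is rotated by its pose angle θ_n using the
printed clockwise convention x′ = x·cosθ + y·sinθ, y′ = y·cosθ − x·sinθ,
z′ = z, and placed at its arc-length position.  Vertex correspondence
between rings is fixed by minimizing summed squared vertex distance over
cyclic shifts and orientation; gaps wider than the interpolation spacing
(default 20 mm, configurable down to the 5 mm native spacing) are filled
by linear interpolation of corresponding vertices, θ and z, tagged
`interpolated`.  Adjacent rings are triangulated into quads split into
triangles, ends capped by centroid fans; meshes are watertight for closed
stacks and exported as binary STL and ascii PLY with a JSON manifest and
a point-cloud CSV.  Rotation rigidity (area, perimeter, round-trip to
1e-9) is asserted in tests.

## Reference tables and agreement statistics

Two bundled CSVs reproduce the validation tables of the reference
experiment: the nine-phantom design/CBCT/robot comparison and ten paired
robot-vs-clinician patient measurements.  `validate_table_fixtures`
recomputes every cell derivable through the DOS formula (tolerance: one
printed unit, 0.1, absorbing the tables' mixed rounding/truncation).
Eleven of 75 cells do not follow from their own printed inputs; they are
pre-registered as documented exceptions rather than silently tolerated:
three design-DOS cells (A-II, A-III, B-I), three CBCT-DOS cells (A-I,
A-II, C-II), two CBCT-vs-robot error cells (A-III, C-II), and two patient
error rows (2 and 7, which follow a ratio convention `100·(1 − a/b)`
although the other eight rows are absolute differences; the absolute
difference is implemented).  Agreement between two raters reports
per-pair absolute errors in percentage points and the R² of an ordinary
least-squares fit (R² = 0.986 on the ten patient pairs).

## Problem sizes and determinism

The phantom-recovery experiment runs all nine presets end to end
(9-frame linear plan at 5 mm spacing spanning the plaque, 256×256 frames,
default noise, fixed seeds) in a few seconds; recovered maximum DOS
agrees with the design value to within ~1–2 percentage points, against
the 3-point acceptance band.  Every stage is deterministic given its
seed; re-running a pipeline configuration reproduces the report
byte-for-byte.  `scripts/acceptance.py --seed N` derives per-preset noise
seeds as `100·N + k`.

## Known limitations

* The speckle model is first-order; no acoustic propagation is simulated,
  and results on clinical frames depend on the initializer's threshold
  heuristics, which assume a dark lumen inside bright material.
* The wall-thickness offset that recovers the vessel boundary is a
  phantom design constant; on real vessels it would have to be measured
  (e.g. from a healthy segment) rather than assumed.
* The greedy snake refines but cannot perform large-scale motion at the
  default stiffness (see above); it depends on a good initialization.
* Per-slice diameters carry ~0.1–0.2 mm localization error; the DOS
  ratio is tighter because lumen and vessel errors are correlated.
* Arc-scan reconstruction follows the printed rotation convention, which
  places the image plane in the rotation plane; no probe-calibration
  transform is modelled.
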