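# Methods

This note records the models, numerical choices and open design
decisions behind `carotidfem`, at the level of detail a user needs to
judge what the computed numbers do and do not mean.

## Synthetic anatomy

Each branch (CCA, ICA, ECA) is a straight axis with a constant nominal
lumen radius. Defaults: CCA 2.7 mm / 14 mm, ICA 2.7 mm / 13 mm (a
bulb-like, untapered ICA), ECA 2.0 mm / 11 mm, branch angles ≈ 22° and
29° off the CCA axis; single-vessel ("tube") mode uses a 3.0 mm /
24 mm vessel. Radii are untapered on purpose: the reconstruction's
outer-wall rule sets a *constant* outer radius per branch from the
distal inner radius, so a strongly tapered synthetic vessel would make
the rule misclassify healthy sections as narrowed — an artifact of
desk-scale geometry, not of the method. A small seeded perturbation
(default amplitude 1.2%) is applied through θ-dependent Fourier modes
only (ovality and bending of the section shape); pure axial-taper
modes are excluded for the same reason, and because they change the
section area that several conservation checks rely on.

A stenosis multiplies the lumen radius by
`sqrt(1 − A·h(s)·g(θ))` with a cosine-squared axial profile `h` over
the lesion extent and an eccentric angular profile
`g(θ) = 1 + e·cos(θ − θ₀)` (default eccentricity 0.8). Since the mean
of `g` over θ is 1, the maximal area reduction equals `A` exactly.
Calcific and lipid components are polar bands inside the stenotic gap
(lipid against the lumen, calcium towards the outer edge), confined to
the angular window of the plaque bulk and scaled towards the requested
volume fractions of the gap; the fractions are met approximately
(band widths are capped so the components stay disjoint), and all
downstream composition numbers are *measured*, never assumed. The
ground-truth fibrous solid is the gap volume minus the components,
computed from the analytic radii — independent of the reconstruction
path it is later compared against.

The generator emulates segmentation *output*: smooth watertight
surfaces. It does not model CT noise, partial-volume effects,
level-set segmentation behaviour, vessel curvature or taper, so
passing tests demonstrate correctness of the method's geometry and
mechanics pipeline, not robustness to real CTA artifacts.

The optional imaging round trip rasterizes the surfaces into an HU
volume by voxel-center inside tests (contrast blood uniform in
[200, 700], calcific in [800, 1200], lipid in [0, 60], soft tissue
constant 100 HU — strictly between the lipid and blood classes, since
the true HU of fibrous tissue is only "intermediate") and segments it
back by thresholding plus connected components and marching cubes.

## Geometry kernel

There is no robust 3D mesh Boolean available, and the workflow does
not need one: all Boolean logic is evaluated either per
cross-sectional plane as 2D polygon operations (shapely) and
re-lofted, or as a smooth level set sampled on a regular grid and
contoured with marching cubes. Level sets of branch tubes are analytic
(bilinear interpolation of polar radii about the branch axis); unions
use a polynomial smooth maximum with 0.15 mm blend width, which
prevents marching-cubes pinching where two branch surfaces graze and
lifts coincident surfaces by at most 0.04 mm. Default grid pitch is
0.2 mm for branch unions and 0.12–0.15 mm for plaque-scale solids, so
Boolean volume errors stay well inside the 1–2% conservation
tolerances used by the tests.

Contour correspondence (for lofting, enlargement, shrinkage and
interpolation) uses angular sampling about the section area centroid
and therefore assumes star-shaped sections. Lumen slices, convex
merged curves and outer-wall curves satisfy this; a strongly re-entrant
lumen section would be convexified in its hidden parts.

Point-mesh queries (ray-parity inside tests, exact closest points with
a KD-tree and escalating candidate counts) are implemented in
vectorized numpy; both are oracle-tested against brute force.

## Reconstruction rules made precise

The published procedure leaves several constants unstated; the package
fixes them as follows (all configurable):

- plane spacing 0.5 mm (finer than the 0.8 mm global mesh size);
- section smoothing: least-squares *periodic cubic B-spline* with 16
  control points — a stand-in for NURBS rebuilding, whose rational
  weights are not needed for smoothing; if the fit self-intersects it
  is retried with more control points, and the pipeline falls back to
  the raw arc-length-resampled section if it still fails (this occurs
  only for clipped junction slivers);
- "narrowing" criterion: a station is removed when its outer
  equivalent radius falls below 0.98× the line through its retained
  neighbours (leave-one-out), or when the enlargement target is
  smaller than the merged section's own radius; removed stations are
  refilled by per-vertex polar blending of the retained neighbours;
- enlargement scales about the merged-section area centroid and never
  below scale 1, so the plaque hull stays enclosed;
- the CCA outer-radius target uses the larger of the ICA/ECA distal
  radii (the rule names only the ICA/ECA);
- the healthy lumen shrinks the outer sections by the inverse factor
  (÷1.3) about the *lumen* section centroid rather than the merged
  centroid: an eccentric plaque shifts the merged centroid sideways,
  and shrinking about it would cut the healthy lumen into the true
  lumen on the opposite side. The shrink magnitude itself is the
  inverse of the enlargement rule — the construction is not fully
  specified in the source procedure and this is this package's
  decision;
- the fibrous difference applies a 2D morphological opening
  (radius 0.08 mm) per section before subtraction, removing
  tolerance-scale shells where healthy and stenotic lumina nearly
  coincide while leaving the true stenotic gap untouched; calcific and
  lipid sections are then subtracted exactly;
- the bifurcation fillet is local Laplacian smoothing within a 1.5 mm
  sphere at the crotch point (found by marching along the ICA/ECA
  bisector until outside every branch tube), with linearly fading
  weights so the blend joins the untouched surface continuously;
- only the stenotic lumen sections loft the inner wall; plaque
  contours enter through the merged outer curve.

At a bifurcation the healthy lumen is a smooth three-tube union while
the true lumen has a crotch notch, so the fibrous difference includes
tissue at the apex saddle. This is a genuine feature of the
healthy-lumen construction (it is where high stresses at the
bifurcation come from in fibrous-dominant plaques), and it is the main
systematic difference against the generator's ground truth, which
contains only the stenotic gap. Comparison metrics sample distances at
the reference model's vertices, mirroring per-point surface coloring;
an area-weighted variant is not provided.

## Discretization

Two meshers. The *structured* mesher fills the space between the inner
and outer contour tubes with a (station, angle, radial-layer) hex grid
split into 6 tetrahedra per cell (Kuhn subdivision, face-conforming,
exact boundary, no slivers); refinement is axial — stations at the
local size (0.3 mm) inside the plaque span, the global size (0.8 mm)
outside, with angular and radial resolution at the local size
throughout. It is used for tube-like walls and all verification
fixtures. The *background-grid Delaunay* mesher (jittered interior
lattice + even surface samples, keep tetrahedra with interior
centroids, discard volumes < 10⁻⁶ mm³) handles arbitrary watertight
solids, including the bifurcated wall; its elements are lower quality
near the boundary, which is acceptable for labelling and smoke-level
mechanics but not for the convergence benchmarks.

Subset assignment evaluates the minimum-distance-vector rule at
element centroids (the natural test point, also used later for VM₉₉
localization). Elements whose centroid straddles a component surface
within numerical tolerance are decided by the sign of the
distance-vector/normal product; the oracle-equivalence tests therefore
exclude centroids closer than 10⁻³ mm to the surface.

## Mechanics

Small-strain isotropic linear elasticity, displacement-only 4-node
tetrahedra, unit system mm/N/MPa. The lumen pressure is a dead load on
the reference configuration (consistent with a geometrically linear
static analysis); each tagged facet contributes `p·A/3` per node along
the inward surface normal. End planes are constrained through per-node
cylindrical frames (axial and circumferential fixed, radial free),
implemented by a reduction matrix whose columns are the free
directions; the reduced operator is SPD and factorized directly
(`splu`), with a Jacobi-preconditioned CG fallback. Residuals above
10⁻⁹ are rejected.

Two deliberate fidelity choices carry documented caveats:

- **ν = 0.49 with linear tetrahedra locks.** The default material set
  is nearly incompressible, and displacement-only P1 elements are the
  published setup; no hybrid or reduced-integration formulation is
  added. On the pressurized-cylinder benchmark the coarse-mesh error
  at ν = 0.49 is several times the ν = 0.3 error (a dedicated test
  asserts this), and solver *verification* against the Lamé closed
  form is therefore run at ν = 0.3, where the element converges
  cleanly (< 1% at the 0.3 mm mesh, error decreasing under
  refinement). Absolute stresses computed at ν = 0.49 on coarse meshes
  are mesh-sensitive; VM₉₉ comparisons between models on the *same*
  mesh are not affected by this bias.
- **No pre-stress, no hyperelasticity, no fluid–structure
  interaction.** The load is the differential pressure P_S − P_D on
  the unloaded reconstructed geometry; stresses are comparative
  indices, not absolute in-vivo stresses.

## Post-processing

VM₉₉ uses first-crossing semantics on the increasing-stress ordering
("until the cumulative volume reaches 99%"), no interpolation; ties
break by element index, and scaling all stresses by c > 0 scales VM₉₉
by exactly c. The volume–stress curve and the direct element iteration
are two code paths and are tested to agree. The anatomical location
tag is rule-based: centroid within 1 mm of the lipid surface → fibrous
cap; within 1 mm of calcium → calcific plaque shoulder; within 3 mm of
the bifurcation apex → bifurcation. Fibrous-cap thickness is the
minimum lumen-to-lipid contour distance on the VM₉₉ plane within a
±30° angular window about the VM₉₉ centroid direction (the measurement
path is not fully specified in the source; minimum-within-window is
this package's rule). The fibrous-modulus sensitivity sweep re-solves
with E_fibrous scaled by {0.5, 0.8, 0.9, 1.0, 1.1, 1.2, 1.5}.

## Problem sizes and tolerances used by the checks

The default pipeline case is a single-vessel stenotic anatomy
(≈ 70 000 elements at the 0.8/0.3 mm sizes) solved in well under a
minute; the bifurcated anatomy is exercised geometrically. The
verification tube is a = 3.0, b = 3.9 mm (the 30% rule), 6 mm long.
Containment checks allow violations up to 0.25 mm — one level-set
extraction cell — and Boolean bookkeeping closes within 1–2% as per
the per-operation contracts. Parameter recovery (reconstructed vs
ground-truth fibrous solid) is asserted below one contour spacing
(0.5 mm) as mean absolute distance at reference vertices; measured
values are ≈ 0.2 mm on the seeded tube anatomies.

## Known limitations

Straight branch axes only (no curved centerlines); star-shaped section
assumption; the bifurcated wall is meshed by the Delaunay route
without the structured mesher's quality guarantees; component volume
fractions are approximate by construction; no absolute-stress claims
at ν = 0.49 on coarse meshes; no statistical patient-risk
stratification is attempted.
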