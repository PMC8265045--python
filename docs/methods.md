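# Methods

## Mesh and field model

A scaffold is a mesh of 1/2/3-dimensional elements with tensor-product
cubic Hermite basis functions in every local direction. Each node stores,
per field and component, eight parameter slots in the fixed order

```
(value, d/dξ1, d/dξ2, d²/dξ1dξ2, d/dξ3, d²/dξ1dξ3, d²/dξ2dξ3, d³/dξ1dξ2dξ3)
```

— slot index *s* carries a first derivative in direction *i* iff bit *i−1*
of *s* is set; a d-dimensional element uses the first 2^d slots. Local
coordinates ξ lie in the closed cube [0,1]^d, ξ1 varying fastest in the
local node ordering; coordinates are right-handed and in mm. Element
Jacobians of the reference field must be positive at all interior Gauss
points.

Derivative scale factors are not stored separately: nodes may hold several
*derivative versions* (alternative derivative sets), and elements select a
version per local node. This is the single mechanism used both for
deliberate C¹ breaks (e.g. vessel junctions) and for collapsed geometry
(zero-length derivative versions); how production scaffold tools split this
between scale factors and versions is not documented anywhere we could
follow, so versions were chosen as the simpler mechanism with the same
expressive power at this scale.

Inter-element continuity is checked by sampling shared faces from both
sides: C0 as the value gap, C1 as the gap of the face-transverse first
derivative with the sign induced by the face orientations. By default the
C1 check also covers faces whose shared nodes select different derivative
versions (so constructed violations are reported); passing
`c1_where_versions_differ=False` exempts them, which is the right reading
when version switches encode intentional creases.

## Scaffold generation

**Tubes.** A cross-section profile (base radius, wall thickness, taenia
bumps, haustral modulation) is swept along an arc-length-parameterised
centerline using rotation-minimising (double-reflection parallel-transport)
frames rather than Frenet frames, which would flip at inflection points.
Node values are analytic; nodal derivative slots are high-order central
differences of the analytic sweep map, computed once per node and shared by
all adjacent elements, so inter-element continuity is exact by
construction. Taeniae are cos² thickness bumps on the outer surface
(C¹ at their edges); haustra are a sin² axial modulation windowed to vanish
under the taeniae. The published anatomy fixes only the *counts* (taeniae
3/2/0 for human/pig/mouse; pulmonary veins 4/2/3 for human/pig/rat); all
geometric magnitudes are plausible defaults in mm (human colon lumen radius
25 mm, rat heart scale ≈ 10 mm, etc.) and are documented in the preset
definitions. The sweep refuses centerlines whose bend radius is smaller
than the tube radius (self-intersection), naming the offending arc length.

**Atria.** Each anatomical region — left/right atrium, left/right auricle,
each pulmonary vein, the caval veins — is its own swept-tube manifold with
a region annotation group carrying the term, an UBERON CURIE, an
abbreviation (LA, LPV, …) and the faces that bound its tissue volume: the
endocardial (inner) and epicardial (outer) surfaces *and* the open end
rims. Regions deliberately do not share nodes (they are separate
manifolds); the rims matter because without them the axial extent of a
region is invisible to surface data and a fit cannot recover axial
compression. The published 282-element conformal heart topology is out of
scope.

**Body.** Two concentric cylindrical shells: a visceral core and an outer
layer carrying the spinal-cord node path (dorsal, +y) and the skin surface.
One axial node station is placed exactly at `diaphragm_position · length`,
so the diaphragm landmark faces sit at that height to machine precision and
the thorax/abdomen element groups partition the core.

**Refinement.** Each element splits by integer factors per ξ direction; new
nodal parameters are the parent's exact derivatives at the subdivision
points with chain-rule scaling 1/fᵢ per derivative order. Because the
restriction of a tricubic to a sub-box is again a tricubic, the geometry is
reproduced exactly (tested at 1e-9). Shared lattice points are identified
topologically — corner/edge/face keys canonicalised over the symmetry group
of the entity, never by coordinate hashing — so refinement preserves
conformity and never merges spatially coincident but topologically distinct
nodes. Annotation groups propagate to child elements and faces; original
corner nodes keep their ids.

## Fitting

The fit is an iterated-closest-point loop with a linear least-squares core
(the problem stays linear in the nodal parameters θ at frozen material
coordinates):

1. **Projection.** Each datum seeds a 3-per-direction ξ grid in every
   candidate element; candidates whose best seed is within an
   element-diameter margin of the global best (all candidates for the
   single-point API) are polished with a clamped Gauss-Newton iteration
   (max 20 steps, step tolerance 1e-10, active-set handling at the ξ
   bounds, gradient fallback on singular systems, backtracking — it cannot
   fail). Polishing starts from the best three seeds per candidate because
   a single seed's basin can miss the optimum on curved elements. Ties
   within 1e-12 break to the lowest element id, then lexicographically
   smallest ξ. Data annotated with a term that names an annotation group
   are restricted to that group's elements; unmatched terms fall back to
   the whole mesh with a logged warning.

2. **Linear solve.** `solve_linear_fit` minimises the point-to-point
   objective stated in the module docstring: weighted squared data
   distances, a strain penalty λ (first-derivative misfit against the
   reference, 3-point Gauss quadrature per direction), and a smoothness
   penalty β (second-derivative seminorm of the displacement x − X). Both
   penalties vanish on translations of the reference, which is what makes
   translated data recover the translated reference exactly. One sparse
   normal-equations system per coordinate component, factorised once
   (SuperLU) and solved for three right-hand sides with two steps of
   iterative refinement (the normal matrix mixes value and derivative
   scales and is ill-conditioned). Hard landmark constraints are imposed
   through Lagrange multipliers (KKT augmentation) — exact satisfaction
   with arbitrary constraint rows. A singular system (insufficient data
   with zero penalties) raises with the advice to set λ, β > 0.

**Default refinements in `fit()`.** Two failure modes of the plain
formulation, found and characterised on synthetic ground truth, motivate
the defaults:

* *Point-to-plane data metric* (`data_term="surface"`, tangential weight
  0.05): frozen point-to-point correspondences stall tangentially — the
  surface is recovered but material coordinates are not, because once
  residuals are small the data term pins the (wrong) tangential
  parameterisation. Down-weighting the tangential component hands the
  tangential gauge to the strain penalty, which relaxes it to the
  minimum-strain parameterisation. The three coordinate components couple;
  this solve runs on the stacked system.
* *Corotational strain* (`strain_mode="corotational"`): the literal
  first-derivative misfit is not rotation-invariant and biases the
  parameterisation under bends of a few tens of degrees. Re-linearising
  each outer iteration against the polar rotation of the current
  deformation gradient (Kabsch at each quadrature point) approximates true
  rotation-invariant tissue strain while keeping every solve linear.

With `FitConfig(data_term="point", strain_mode="reference")` the loop is
exactly the plain formulation, and its recorded objective is guaranteed
non-increasing across outer iterations (each solve is a global minimiser at
frozen ξ; re-projection cannot increase any distance). With the default
modes the recorded objective is the solved quadratic and is monotone in
practice but not by construction.

Defaults: λ = 0.01, β = 0.001 (small against a unit-RMS data term at the
preset scales), 12 outer iterations with an RMS-change early exit at 1e-6
mm. Twelve, not three or four, because surface shape converges in ~3
iterations but the material parameterisation keeps relaxing for several
more; the end-to-end recovery quality (below) is what set the default.
How many iterations the original organ-mapping studies used, and whether
projections were recomputed between solves, is not documented; both are
exposed in `FitConfig`.

## Embedding, transfer, placement

Surface embedding is closest-point projection. Volume embedding
Newton-inverts x(ξ) = p in the best few candidate elements (same seeding);
when no interior solution exists the point falls back to surface projection
and is flagged `off_mesh` when its residual exceeds 1e-6 of the bounding
box diagonal — off-mesh points are kept at the nearest boundary material
point rather than dropped so per-specimen counts stay comparable. Transfer
simply evaluates stored material points in the target field; an embedded
point's transferred position depends only on the target configuration.

Organ placement uses Umeyama's closed-form least-squares similarity
transform (rotation + isotropic scale + translation, 7 dof, matching the
three-landmark use case; reflections are rejected unless requested) on ≥3
non-collinear fiducial pairs evaluated in both meshes. Values transform
affinely; every derivative slot transforms by sR, so element Jacobians
transform exactly by sR.

## Synthetic ground truth

Deformations are analytic maps with exact derivatives to third order —
affine, a circular bend ((r+x)cos kz − r, y, (r+x)sin kz) about the mesh
centre (identity at the centre plane, Jacobian determinant 1 + kx), a
Gaussian radial bulge, and compositions — so nodal derivative updates use
the exact chain rule (value → φ(v), dᵢ → J dᵢ, dᵢⱼ → J dᵢⱼ + H[dᵢ,dⱼ],
d₁₂₃ with the full third-order term). No numerical differentiation enters
the ground truth. The bend's `amplitude` is calibrated so the peak
displacement is roughly `amplitude ×` the bounding-box diagonal
(curvature = 8·amplitude/diagonal). Deformed meshes are verified to keep
positive Jacobians, with an error naming the parameter to reduce.

Contour sampling emulates segmentation: rings of points at fixed ξ levels
on the faces of surface annotation groups, with isotropic Gaussian noise;
terms inherit from the group, so the fitter's group restriction works as it
would on curated data. Cells are planted uniformly over (element, ξ) in the
filtered groups and observed at the truth-field evaluation (+ optional
noise). Everything stochastic derives from a single integer seed.

What the generator does *not* emulate: segmentation outliers and
topological errors, anisotropic slice-direction noise, partial coverage
(every surface region is sampled uniformly), inter-subject anatomical
variation beyond the smooth deformation family. Passing recovery tests
therefore show the machinery is correct and well-conditioned under
realistic geometry and noise magnitudes, not that real imaging pipelines
will reach the same accuracies.

Recovery is quantified by `registration_error`: paired physical RMS/worst
case in a common configuration, ξ-RMS over same-element pairs, off-mesh
count; labels present on only one side are reported, never dropped. At the
default study conditions (rat atria, 10 % bend, noise-free contours,
default fit) planted cells are recovered on the generic scaffold to ≈0.13
mm RMS, under 1 % of the scaffold diagonal.

## File formats

Segmentation XML: root `units` attribute ("um" default, as in microscopy,
or "mm"; µm inputs are scaled ×0.001 on load), `contour` elements
(`name`, optional `ontologyId`, `closed`, ≥2 `point` children with
`x`/`y`/`z` and optional `d` attributes) and single-point `marker`
elements. Unknown child elements are counted and logged, never silently
dropped; a file with no contours and no markers is an error. The dialect is
a declared subset of public neuromorphology reconstruction formats, not a
compatibility claim.

Native mesh files are versioned JSON with canonical key ordering and
`repr`-exact floats, so identical meshes serialise byte-identically and
round trips are lossless bit-for-bit; a SHA-256 checksum warns about
corruption and an unknown version is a hard error naming both versions.

VTK export writes legacy ASCII unstructured grids by hand (the format is
line-oriented text): each Hermite element subdivides into refine^d linear
hexahedra/quads whose vertices are Hermite field evaluations; annotation
groups become 0/1 cell-data arrays. A minimal reader of the same subset
supports round-trip checks.

## Numerical choices and limitations

* Quadrature: 3-point Gauss per direction everywhere (exact for the
  polynomial degrees the penalties produce, except the corotated target,
  which is only piecewise smooth in θ).
* Projection margin pruning (element-diameter criterion) is a performance
  heuristic; the single-point API polishes every candidate and is the
  reference behaviour.
* The similarity transform class is deliberate: 3 fiducials determine it
  robustly; full affine placement exists behind `allow_reflection`-style
  extension but is not the default because shear placement of organs is
  rarely meaningful.
* Fitting accuracy on near-rotation-symmetric regions (circular vein
  stubs) is gauge-limited: surface data cannot pin the circumferential
  parameterisation, only the strain penalty does, so per-cell recovery is
  a few times worse there than on chambers.
* With dense data and the default small penalties the fitted surface
  follows noise below the noise amplitude (data RMS < σ); increase λ, β
  for smoother fits when data are sparse or noisy.
* 2D elements embed in 3D with the first four parameter slots; 1D elements
  are supported by the kernel but no generator emits them.
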