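# Methods

This note documents the models, discretizations and design choices behind
surfmorph, and what the synthetic validation does and does not establish.

## Surface model and topology optimization

The unit of analysis is a closed, oriented, genus-zero triangle mesh of a
subcortical structure, coordinates in mm. Before parameterization the surface
is opened into a topological cylinder ("topology optimization"): the two
vertices extremal along the first principal axis of the vertex cloud are
found, their k-ring patches removed (k = 2 by default), and the two resulting
boundary loops labeled anterior (larger axis projection) / posterior. The
loops act as landmarks shared by all subjects. Principal axes are made
deterministic by a sign rule (largest-magnitude component positive) with a
lexicographic fallback when the covariance spectrum is degenerate. The cut
size is a convention, not derived from data: any small patch at a stable
extremal position serves, and k = 2 keeps the removed area ≪ 1% of the
surface at the default mesh resolutions.

## Conformal parameterization

On the cylinder we solve the cotangent-Laplacian Dirichlet problem
(f = 0 on loop A, 1 on loop B). The harmonic 1-form is the exact differential
ω = df on edges. Its conjugate ω\* is the discrete Hodge star: the per-face
gradient of f is rotated 90° about the face normal and re-integrated to edges
by averaging the two incident faces. The period of ω\* around either
boundary loop is the conformal modulus h (analytically 2πr/l for a right
tube; the discretization reproduces this to ≈0.3% at 30×24 resolution).

Integration to the rectangle: u is the exact potential of ω normalized to
[0,1]; for v the cylinder is cut along a canonical seam and ω\* integrated on
the cut disk by weighted least squares (a graph Poisson solve), which is
robust to the small closure error of the discrete star — spanning-tree
integration would accumulate it path-dependently. The measured seam jump is
the realized h; v is taken modulo h with v = 0 anchored at the seam.
Per-face-corner coordinates are stored explicitly (the cut-mesh values), so
faces straddling the periodic seam need no unwrapping heuristics; each
face's corners are normalized into the base period so a ±h replication of
faces covers every query.

**Seam canonicalization.** The circular coordinate is only defined up to
rotation, and the subjects' v-origins must land in the same anatomical
region for cross-subject correspondence to mean anything. A plain shortest
cut-to-cut path is ambiguous on an elongated shape (small perturbations move
it around the circumference), so the seam is the shortest path under edge
weights inflated by angular distance from the "inferior" meridian of a
deterministic PCA frame. The short-axis sign is fixed by the skewness of the
vertex distribution along it, which is stable for bent structures; on
surfaces of revolution (zero skewness) the gauge remains arbitrary, which is
inherent, not a defect of the rule.

Registration features are the conformal factor λ (face area in 3-D over face
area in the parameter domain, area-weighted to vertices) and the discrete
mean curvature H (cotangent mean-curvature normal with mixed Voronoi areas,
signed against the outward normal; boundary vertices copy the nearest
interior value). Both are sampled onto a regular n_u × n_v grid (default
64×64; 32×32 in the shipped experiments, see below) by linear interpolation
with periodic replication in v and nearest-neighbour fill outside the
triangulation hull, then z-scored per channel so λ and H contribute
comparably to the registration force. Channels with negligible variance
(e.g. a perfect tube) are treated as constant rather than amplified.

## Registration

**Fluid.** The two feature images are aligned by a viscous-fluid flow on the
rectangle: per iteration, the multi-channel SSD body force drives a velocity
field solving μ∇²v + (μ+λ_visc)∇(∇·v) = −F (sparse direct solve; periodic in
v, zero-velocity Dirichlet rows on the two boundary-loop edges; defaults
μ = 1, λ_visc = 0 make the equation a decoupled vector Poisson problem).
Displacements are advanced compositionally, W ← W ∘ W_step, with the step
capped at `max_step` nodes (0.4 default, the CFL-like bound) and the step's
Jacobian bounded below by `regrid_threshold` (0.5) — continuous regridding
rather than discrete regrid events, with the same diffeomorphism guarantee.
Forward and backward maps are estimated symmetrically and blended toward
each other's fixed-point numerical inverse every other iteration
(ic_weight 0.1); a blend is kept only if it preserves the Jacobian floor and
does not raise the SSD beyond the convergence tolerance. Steps that would
raise the SSD or breach the Jacobian floor trigger step-halving; convergence
is declared after `patience` iterations of relative SSD improvement below
`tolerance` (1e-5). Because the per-subject seam anchor is only consistent
to within a few degrees (and can be worse for unusual noise draws), the flow
is preceded by an exhaustive search over integer circular shifts of the
moving image; the winning shift is folded back into the returned fields.
The exact viscosity constants, iteration counts and inverse-consistency
weights of fluid registration are implementation choices; the defaults here
recover a known smooth warp of up to 1.5 nodes with ≈0.05 node RMS error and
inverse-consistency residual ≈0.1 node on a 32×32 grid.

On the conformal parameter domain the manifold Laplacian and divergence
reduce to flat operators weighted by the conformal factor; the flat-domain
solver operates on z-scored features where this weighting is largely
absorbed, and the recovered warps are validated directly against ground
truth.

**Constrained harmonic baseline.** Both map components solve the Laplace
equation on the grid with the boundary correspondence fixed (loop edges and
seam anchor aligned) and v periodic. In node units the boundary data is the
identity, so the harmonic correspondence carries all inter-subject matching
through the shared conformal coordinates — the method's dependence on
boundary conditions is exactly its documented weakness relative to the
fluid approach, and the package reproduces that pattern: on the default
effect cohort the harmonic baseline still localizes the implanted patch
(the canonical seam does the work) but its corrected p-values are an order
of magnitude weaker than the fluid ones.

**Induced 3-D correspondence.** Each template vertex's (u,v) is pushed
through the field and located on the subject surface by barycentric lookup
(KD-tree over replicated face centroids with an exhaustive fallback for the
rare query whose candidate set misses the containing triangle).

## Morphometry

Per template face, the 2×2 surface Jacobian solves J·(T·X) = (S·Y), where
X/Y are the template/corresponded edge vectors and T/S orthonormal tangent
frames. The frames are aligned with the conformal u-direction and its
pushforward respectively: tangent frames are a gauge, and aligning them to a
smooth direction field is what makes the area-weighted average of face
Jacobians at a vertex meaningful (frames tied to the first edge of each face
would mix incompatible gauges and bias even an exact affine map). The
deformation tensor is S = (JᵀJ)^{1/2} by eigendecomposition; log S is
vectorized as (ℓ₁₁, √2 ℓ₁₂, ℓ₂₂) so the Euclidean norm equals the tensor
Frobenius norm. Vertices with det J ≤ 0 (excluded, counted in the run
report) cannot occur while the registration respects its Jacobian guard.

The medial axis is the centroid of each iso-u parameter curve, sampled on a
32-level grid; the radial distance R of a vertex is the Euclidean distance
from its corresponded point to the axis point at the same u (axis linearly
interpolated). By default the axis is recomputed from the subject's own
corresponded points, so R measures the subject's local thickness at
corresponding locations; `axis_source="template"` switches to distances from
the template's axis.

## Statistical inference

Measures are adjusted for age at scan with the GLM
y = β₀ + β₁·age + β₂·diagnosis per vertex and channel; the adjusted value is
y − β₁(age − mean age). Keeping diagnosis in the design prevents the group
effect from being absorbed into the age slope when age and group correlate
(here the groups differ by ~4 weeks).

Group differences use the squared pooled-variance t (det J, R) and
Hotelling's T² with pooled covariance (log S, combined; a trace-scaled ridge
of 1e-12 guards exactly singular cases). Significance comes from
permutation: group sizes are preserved and a single seeded stream serves
both the vertex-wise p-values and the map-level correction (the
suprathreshold vertex count per permutation, threshold 0.05 by default).
Every labeling is compared against the pooled set of all N = n_perm + 1
labelings including itself, which makes p ≥ 1/N (add-one smoothing) and
gives the observed labeling no asymmetric advantage.

**Why covariate pairs are permuted, not labels.** With age differing between
groups, two tempting schemes are anticonservative, and measurably so in this
package's null calibration: (a) adjusting once with the observed labels and
then permuting labels (measured map-level rejection 0.13–0.28 at α = 0.05),
and (b) re-fitting the adjustment under each permuted label vector with ages
pinned to the data — the observed labeling is then the most age-aligned one
and its statistic is stochastically larger under the null. surfmorph instead
permutes the (diagnosis, age) covariate *pair* across subjects (design-row
permutation) and refits the age slope under each assignment. Under the null
hypothesis that the data are independent of both covariates this test is
exact; measured rejection is 0.04–0.07 across the four statistics
(200 cohorts × 500 permutations). When a true age effect is present the
scheme is approximate, as all nuisance-covariate permutation schemes are.
Because the covariate pair moves as a unit, the design Gram matrix is
permutation-invariant and the whole sweep reduces to a few weighted group
moments per permutation — 10,000 permutations over a few thousand vertices
run in seconds.

The CDF/FDR critical value is the largest p(i) ≤ q·i/m over the sorted
p-values (the step-up threshold; equivalently the highest non-origin
crossing of the empirical CDF with y = x/q), with the CDF curve exported
for plotting; it may be absent, meaning no threshold controls false
discoveries at rate q.

## Synthetic cohorts and what the validation shows

The generator emulates the study conditions: group 0 with 19 subjects (ages
N(45.1, 5.1) weeks), group 1 with 17 (N(41.1, 5.0)). The base shape is a
bent superellipsoid (semi-axes 12 × 6 × 4 mm, exponent 0.85, bend 0.6 of the
short axis — an elongated, banana-like blob at neonatal putamen scale)
triangulated from a subdivided icosahedron (642 vertices at the default
3 subdivisions). Group 1 receives an inward displacement of
δ·(local radius)·cosine-taper within a 6 mm geodesic radius of the surface
point nearest the anterior/inferior direction (δ = 0.1 default; δ = 0 gives
a null cohort), with a per-vertex ground-truth indicator. Every subject gets
smooth band-limited shape noise: a random real spherical-harmonic field
(degrees 1–4) scaled to amplitude 0.02 of the local radius along the normal.
An optional linear age scaling (1 + slope·(age − 43 wk)) exists and defaults
to 0, isolating the group effect; the age adjustment is still exercised
because the groups differ in age.

What the synthetic validation shows: the geometry converges to analytic
values; known warps and rigid motions are recovered; the inference is
calibrated under the null and recovers an implanted effect with the
multivariate-advantage ordering (combined ≥ logS ≥ detJ in detected-vertex
counts) and a large fluid-over-harmonic power gap. What it does not show:
robustness to segmentation error, topology defects, strongly non-convex
anatomy, partial-volume smoothing of real MRI, or non-linear age effects —
real data carry all of these and the synthetic noise model none of them.

## Problem sizes in the shipped experiments

The library defaults are a 64×64 feature grid, 200 fluid iterations and
10,000 permutations. The test suite and the acceptance script run the
pipeline at 32×32 / 80 iterations / 500–1,000 permutations on 642-vertex
meshes — sizes chosen so a complete cohort analysis takes tens of seconds
while leaving all measured tolerances far from their asserted bounds; the
null calibration runs at the inference level (300 spatially smoothed
vertices per cohort, 200 cohorts × 500 permutations) with one end-to-end
null cohort as a smoke check, since hundreds of full mesh pipelines would
add hours without changing what the calibration measures.

## Known limitations

- The conformal gauge (seam) is undefined on surfaces of revolution; the
  circular pre-alignment in the fluid registration compensates, the harmonic
  baseline cannot.
- The medial axis is an iso-parameter-slice centroid curve, sensible for
  elongated quasi-tubular structures only; it is not an m-rep or a true
  medial surface.
- Hotelling's T² assumes a common within-group covariance; the permutation
  protects the error rate but not the optimality of the statistic.
- `adjust_for_age` residualizes linearly; non-linear age effects leak into
  the residuals.
- The two cut patches remove a small amount of surface from analysis; the
  boundary loops themselves are constrained, not estimated.
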