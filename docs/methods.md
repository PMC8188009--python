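# Methods

This note documents the models and procedures implemented in `trabshape`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic phantoms can and cannot show about
real bone images.

## Containers and conventions

All stages operate on a 3D grid indexed `(z, y, x)` with voxel centres at
integer coordinates and isotropic spacing (anisotropic voxels are rejected
rather than silently mis-scaled).  Everything outside the grid is
background: the distance transform zero-pads before computing, contact
detection treats out-of-grid samples as background hits, and the
iso-surface mesh closes at the image border.  Thresholding is strict
(`intensity > level` is foreground); the 3D median filter uses a spherical
neighbourhood of the given radius, matching the radius phrasing — a cubic
one over-smooths along diagonals.

## Seeding

Ellipsoids start from seed points on the medial locus of the foreground.

*Distance ridge.*  With D the Euclidean distance transform, the residue
R = closing(D) − opening(D) over a 3×3×3 structuring element vanishes on
linear slopes of D and exceeds one voxel on the medial crest where the
gradient flips.  The default ridge threshold is R > 1.0 voxel: the discrete
EDT of a smooth, sloped boundary carries staircase ripples whose residue
reaches exactly 1.0, so any lower threshold floods the seed set with
ripple artefacts far from the medial locus (measured: 18.6k of 95k gyroid
foreground voxels at R > 0.5 versus 4.8k at R > 1.0, with sphere seeds
spread to the surface versus confined to within one voxel of the centre).
A crest that is a plateau — even-thickness slabs have a two-voxel-wide one —
survives the opening and leaves no residue at all, so plateau-tolerant
local maxima of D (voxels with no strictly larger neighbour) are unioned
into the ridge.  Both the element size and the threshold are exposed.

*Topology-preserving skeleton.*  3D thinning via scikit-image.  The
installed implementation can erode a convex component down to nothing,
which no topology-preserving thinning may do; components left without a
skeleton voxel are repaired with their distance-transform maximum, keeping
the component-count contract.

Seed density is controlled by keeping every n-th point in lexicographic
scan order (`skeleton points per ellipsoid`); the documented default of 10
gives a quick overview, and the production preset of 1 (with 6 repetitions)
is recommended for final results.

## Ellipsoid fitting

Each seed grows a sphere by one `sampling increment` (default 1/2.3 voxel)
at a time.  A contact check draws `number of sampling vectors` (default
100) points uniformly *with respect to surface area* — directions uniform
on the unit sphere, mapped to the ellipsoid and rejection-corrected by the
surface-area Jacobian, since the plain mapping is measurably non-uniform on
elongated ellipsoids — and registers a collision when at least
`contact sensitivity` (default 1) of them land in background voxels.

The fit proceeds in declared phases:

1. **First contact.** Uniform growth until collision.  The constrained
   direction is estimated as the principal eigenvector of the
   contact-direction scatter matrix; the naive mean of contact vectors
   cancels over a rod's waist ring (or a plate's two opposite faces) and
   leaves only noise, which made fits bimodal in testing.
2. **In-plane growth.** The two axes orthogonal to the constrained
   direction grow together until the second collision.
3. **Free-direction probe.** One in-plane direction may remain free (the
   long axis of a rod, the second extent of a plate), but one or two
   contact points cannot identify it reliably.  Six random in-plane
   directions are probed by growing each to contact; the largest wins,
   then the remaining (middle) axis also grows to contact.  This
   operationalizes growth directions "recalculated at each iteration to be
   random, but in the plane of the mean contact vector".
4. **Stochastic refinement.** Up to `maximum iterations` (default 50)
   consecutive non-improvements, or ten times that many total attempts, of:
   a single-increment dilation of a random axis; a small rotation (uniform
   in [0, 0.1] rad about a random axis) or small translation (uniform in a
   ball of one increment, clipped so the centre never drifts more than
   `maximum drift` — one pixel diagonal, √3 voxels — from the seed),
   followed by regrowth of a random axis to contact.  A proposal is kept
   only if it is collision-free and strictly larger, so recorded volume is
   non-decreasing; rejected proposals are simply abandoned.
5. **Final polish.** Contract clear of the boundary, then dilate each axis
   in turn while two consecutive checks stay clean, making the result
   maximal in the contact-sensitivity sense without leaving it grazing.

After any collision the ellipsoid contracts by a factor 0.95 until checks
come back clean; a single clean check can leave the surface grazing the
boundary (the next random sample registers a contact and stalls all
further growth), so clearance demands consecutive clean checks.  A seed
whose initial sphere already collides is contracted once to half the
increment and then discarded as sub-voxel structure; a fitted ellipsoid
with more than half of its surface samples outside the image is invalid.

Fits are bit-deterministic: every random draw, including the 64-bit seeds
handed to the compiled contact kernel, derives from one
`numpy.random.Generator`, and each seed point receives an independent
substream spawned from the run seed, so results do not depend on seed
ordering.

### Accuracy limits of the contact rule

A surface sample "hits the boundary" when the voxel containing it (nearest
integer coordinates) is background.  Near a curved voxelized boundary a
sample half a voxel inside can still round into a background voxel, so
fits stop roughly half a voxel short of the continuum surface.  Two
consequences worth knowing: recovered semi-axes underestimate true radii
by ~0.3–0.6 voxels, and the filling percentage of a voxelized ball — the
worst case, where the uncovered shell scales as (1 − 0.5/R)³ — plateaus
near 86% for one run (≈ 90% after six).  Pushing fits closer to the
boundary would violate the containment property instead (≥ 98% of a dense
fresh surface sample on foreground), which we treat as the harder
contract.

## EF assignment and averaging

Each foreground voxel receives the EF of the *largest-volume* valid
ellipsoid containing it (ties break to the lower ID in the volume-sorted
list), or NaN when none does.  The assignment walks ellipsoids in
descending volume with per-ellipsoid bounding boxes; it is tested for
exact equality against a full-grid all-pairs scan.  An
`average over largest n` option (default 1, the standard rule) averages
the n largest containing ellipsoids per voxel instead.

Runs are averaged NaN-aware per voxel: a voxel covered in a subset of runs
averages over that subset.  Convergence records follow the running mean:
for each n ≥ 2, the median and maximum of |mean₁..ₙ − mean₁..ₙ₋₁| over
voxels covered by both running means.  The median change falls fast
(≈ 0.01 by run 6 on the 64³ gyroid).  The maximum is dominated by voxels
covered in very few runs: a voxel first covered in run k and again in run
n moves by up to |x − y|/2, whereas a voxel covered in every run can move
by at most 2/n (1/3 at n = 6).  On phantoms whose per-run filling is well
below 100% the maximum change therefore stays in the 0.5–0.7 range even
when the map is visually converged — reported as computed, not clipped.

Reporting includes the results row (min/max/median EF, filling
percentage, ellipsoid count, per-run change records), descriptive
statistics with a binned mode (bin width 0.05 over [−1, 1], ties to the
lowest bin), Flinn data (peak plot: one point per voxel-claiming ellipsoid
at (b/c, a/b) weighted by voxels claimed; plain plot: all fitted
ellipsoids) and seven aligned secondary images (a, b, c, a/b, b/c, volume,
ID).

## Structure model index

The binary volume is optionally block-averaged by the `resampling` factor
(partial-volume grayscale smooths the surface), zero-padded, triangulated
by marching cubes at level 0.5, and relaxed by one Laplacian pass with
relaxation factor `smoothing` (default 0.5) — the declared reading of a
single smoothing parameter.  Enclosed volume comes from the signed
tetrahedron sum over the closed mesh.  Each vertex is displaced by
dr = 1/100 voxel along its outward vertex normal; S′ sums the per-triangle
area changes divided by dr.  SMI = 6·V·S′/S²; the positive and negative
per-triangle parts give SMI⁺ and SMI⁻, an exact decomposition.  dr is
small enough for a good derivative and large enough to avoid cancellation
(the sphere value is stable to < 0.05 across dr ∈ [1/200, 1/20]).

Grid-spanning phantoms stand in for the infinite reference shapes.  Faces
touching the image bounding box — any vertex on (or, with partial-volume
resampling, within the border band of) the box — are excluded from S and
S′: the strip adjacent to an end cap carries the cap's normal distortion,
and keeping it biases the cylinder up by ≈ +0.25.  With this exclusion the
voxelized sphere, cylinder and slab score 3.97, 3.29 and 0.09 at the
default settings.  The slab value reflects the mathematics of the index:
a plane has zero mean curvature, its area does not respond to dilation,
and the ideal-plate value of the dilation-based index is 0 (sphere 4,
cylinder 3).

## Phantoms: what they do and do not show

The generators produce binary grids by voxel-centre inclusion (no partial
volume, no noise): sphere, axis-aligned ellipsoid, grid-spanning rod and
plate, a gyroid lattice (foreground where
sin x′cos y′ + sin y′cos z′ + sin z′cos x′ > level, coordinates scaled by
2π/period) whose hyperbolic surface and labyrinthine connectivity mimic
trabecular texture, and a random lattice of *finite* rods and plates with
per-voxel ground-truth labels (finite because grid-spanning rods and
plates always intersect, making a disjoint lattice impossible).  All
generators are deterministic given their parameters and seed.

Default study conditions used by the acceptance checks: 64³ grids; sphere
r = 12, rod r = 8, plate t = 8; gyroid period 24, level 0.4 (volume
fraction ≈ 0.36, wall thickness ≈ 6–8 voxels, comparable to the 5–8 pixel
trabeculae of low-resolution vertebral scans); lattice of 3 rods
(r = 4, length 44) and 2 plates (t = 4, extent 36) with ≥ 2 voxels of
separation.

Passing on these phantoms shows the geometry engine is correct on shapes
with known answers and that the pipeline's plate/rod discrimination works
at realistic feature sizes.  It does not exercise grayscale noise, partial
volume effects, threshold sensitivity, anisotropic resolution, or the
connectivity and curvature statistics of real trabecular networks — on
real scans the preprocessing choices (median radius, threshold) remain the
user's responsibility, and published EF parameters should accompany any
results.

## Known limitations

- Semi-axes carry a systematic −0.3 to −0.6 voxel bias from the
  voxel-rounding contact rule; EF, being a ratio difference, is less
  affected but noisier for structures thinner than ~4 voxels.
- The outermost voxel shell of a thin strut cannot be claimed by an
  inscribed ellipsoid at all, so coverage of an r = 4 rod plateaus near
  88% even after six runs; classification quality should therefore be
  judged over covered voxels, with the filling percentage reported
  alongside (as is done for real bone).
- Individual fits have heavy tails (a stalled fit can be half the size of
  the best); the per-voxel assignment is a maximum filter over ellipsoids,
  which suppresses most of this, but voxel medians of phantoms whose
  claims come from a handful of large ellipsoids (rod, plate) fluctuate by
  ±0.05–0.1 between runs.
- The maximum run-to-run change statistic is structurally inflated by
  sparsely covered voxels (see above).
- Grayscale (fuzzy-boundary) input, anisotropic voxels and GPU execution
  are out of scope.
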