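# Methods

This note documents the model behind `vesselmesh`, the parameters that
matter, the numerical choices, what the synthetic phantoms do and do not
exercise, and the known limitations.

## Problem and model

The input is a binary segmentation volume: an occupancy grid with
anisotropic voxel spacing where 1 marks vessel and 0 background.  The goal
is an explicit triangle mesh of the vessel wall that is (a) geometrically
faithful to the segmentation, (b) smooth (no staircase artifacts),
(c) a closed two-manifold with the correct topology, and (d) built from
well-shaped triangles whose size adapts to local curvature.  All geometry
is computed in world coordinates (`world = origin + index * spacing`,
voxel centers at integer indices), so anisotropic spacing is handled
uniformly.

The surface is represented implicitly before it is meshed.  The indicator
function ψ (≈1 inside the vessel, ≈0 outside) satisfies the Poisson
equation Δψ = ∇·V⃗, where V⃗ is the field of inward surface normals
carried by the extracted boundary samples.  Meshing then amounts to
polygonizing the level set ψ = isovalue.

## Stage by stage

### Point extraction

Each (object voxel, background 6-neighbor) pair contributes one sample at
the shared face center.  Structures thinner than the 3×3×3 structuring
element — found as the white top-hat, i.e. the voxels a morphological
opening erases — would be undersampled, so boundary faces whose background
voxel is 6-adjacent to a thin voxel are split into their four subface
quadrant centers (4× local density).  Every sample lies exactly on the
object/background interface by construction, and each remembers its source
voxel and face.

### Normal estimation

The unoriented normal at a sample is the smallest-eigenvalue eigenvector
of the covariance matrix of its k = 10 nearest neighbors about their
centroid.  (The covariance requires the centroid; the neighbor mean is
used.)  Orientation needs no propagation: the sign is chosen so the
normal points from the sample toward its source object voxel's center —
a local, deterministic rule that is always available because extraction
records the source voxel.  A normal exactly orthogonal to that direction
falls back to the face's inward axis.

### Poisson indicator function

Each depth-d octree node *o* (center c, width w) carries the basis
function F_o(q) = F((q−c)/w)/w³ with F the tensor-product quadratic
B-spline — the standard compactly supported approximation of a
unit-variance Gaussian; compact support is what makes the linear system
sparse.  Each sample's inward unit normal is distributed over the 8
nearest depth-d nodes with trilinear weights (sub-node precision; the
weights sum to 1, so total splat mass equals the sum of normals).

The Galerkin system A c = b with A_ij = ∫∇F_i·∇F_j and b_i = ∫∇F_i·V⃗ is
solved by conjugate gradients (relative tolerance 1e-8, iteration cap
10·√N + 1000).  The implementation realizes the depth-d node set as the
complete 2^d grid over the bounding cube (side = 1.25× the cloud extent,
guarding against boundary effects): on a single-depth grid both A and the
splat-to-rhs map factor into separable 5-tap 1D stencils (the B-spline
product integrals), so the operator is applied matrix-free with three 1D
correlations per axis and no matrix is ever formed.  The mathematics is
identical to solving on the sample-refined octree; the complete grid is
simply bookkeeping that makes the operator separable.  Depths up to 8
(2^24 nodes) are practical this way.  An `Octree` class still provides the
sparse structural queries (leaf containment, root-to-leaf chains).

The isovalue is the mean of ψ over the sample positions.  ψ and ∇ψ are
evaluated analytically from the basis (the gradient matches central
differences to ~1e-10 in the tests).

**Choosing the depth.**  The basis should resolve the sampling density,
not exceed it: when the node width drops well below the sample spacing
(≈1 voxel face centers), the field starts reproducing the staircase of the
voxelization instead of smoothing it, and the surface normals become
noisy.  For the desk-scale phantoms here (40–65 voxels across) depth 6
puts the node width at 0.6–1.3 voxels, which is the sweet spot; clinical
512³ volumes would use depth 8–9 by the same rule.  The library default
is 7.

### Mesh expansion

A seed hexagon is built in the tangent plane of a projected start point
(the sample nearest the cloud centroid), sized by the probed radius of
curvature, re-projected, and its outer edges queued.  Expansion pops
boundary edges FIFO (breadth-first keeps the fronts round):

* **ear rule** — two adjacent boundary edges meeting at < 70° are closed
  with the existing vertices (no new vertex), provided the ear's minimal
  angle is at least 20° (a quality floor that sends degenerate wedges to
  the stitcher instead);
* **growth** — otherwise a candidate apex is placed opposite the edge's
  triangle, in its plane, at leg length ρ·r where r is the probed radius
  of curvature; growth is clamped to [1/1.25, 1.35]× the base length per
  step, which keeps the in-plane base angles inside the 50°–70° window by
  construction and makes triangle size change gradually; the apex is then
  Newton-projected onto the isosurface (rejecting projections that jump
  farther than 0.75 of the leg length — a fold or step);
* **front merging** — if the projected apex lands within 0.6 leg lengths
  of an existing boundary vertex of an opposing front stretch (opposing
  direction, similar normals, proximity-checked), the apex snaps to that
  vertex, zipping the two fronts together instead of stalling;
* **collision rule** — a candidate closer than one third of the longest
  involved edge to any triangle not sharing a vertex with the popped edge
  is rejected; after a rejection a relaxed ear (≤110°, minimal angle
  ≥25°) is attempted before the edge is left for the stitcher.

Newton projection iterates x ← x − (ψ−iso)·∇ψ/|∇ψ|² with steps capped at
two node widths, converging to 1e-6 of the field's value span; a gradient
four orders of magnitude below the typical surface gradient raises a
vanishing-gradient error (e.g. at the symmetric center of a closed
shape).

**Curvature probing.**  The radius of curvature uses the chord formula
r = min_i d_i/(2 sin(θ_i/2)) (exact on spheres), but the θ_i must be read
at the right scale: the reconstructed field carries voxel-scale ripple,
and probes closer than a few node widths measure ripple, not bending.
Probes are therefore placed at max(2× edge length, 5 node widths) along
two orthogonal tangent directions; each probe normal is the field
gradient averaged over a tangent ring of 0.75× the probe distance (the
curvature signal is symmetric about the point and survives the average;
the ripple does not); and the two probes of each direction are averaged
before the minimum over directions is taken, halving the noise of the
minimum without losing directional sensitivity (a tube's tight
cross-section direction still dominates).  r is clamped to
[0.5·min spacing, 100·max spacing], and the edge length additionally
floors at one node width — below that the field cannot resolve curvature
and probe noise would shrink triangles indefinitely.

Multiple segmentation components are handled by re-seeding at the
farthest sample more than 4 mean-edge-lengths from the mesh, with the new
hexagon rejected if it lands on already-meshed surface (samples in the
crease of a junction sit off the smoothed isosurface and must not spawn
overlapping seeds).

### Gap stitching

The boundary edges left by expansion partition into closed loops, chained
by triangle-fan adjacency so that a vertex the boundary passes through
twice (created by front merging) still resolves into well-defined cycles.
Each loop is triangulated by the O(n³) dynamic program over its vertex
cycle: w(i,i+1) = 0, w(i,i+2) = Φ(i,i+1,i+2), then increasing spans with
w(i,k) = min over m of w(i,m) + w(m,k) + Φ(i,m,k), recovering the patch
by recursive trace.  Φ(i,m,k) = (α, β, A): α the candidate's minimal
interior angle in 3D, β its worst dihedral deviation against the fixed
neighbors (the mesh triangle across each touched loop edge, and the
tabulated subpatch triangle across each chord), A its area.  The order
prefers larger α, then smaller β, then smaller A; accumulation keeps the
worst α, the worst β, and sums areas.  Degenerate candidates score
(0°, 180°, 0), chords already occupied by mesh edges are blocked, loops
longer than 400 vertices are pre-split at their closest non-adjacent
vertex pair, and ties take the smallest split index.

The α component is intrinsic to each triangle, so the DP maximizes the
minimal angle exactly (verified against exhaustive enumeration).  The β
and A tie-breaks couple across chords — the dihedral against a neighbor
depends on which triangle the neighbor's subproblem chose — and the
tabulated-subpatch approximation (shared with the hole-filling DP family
this stage follows) can then differ from the global optimum on strongly
warped loops; planar loops are immune, since all dihedrals vanish and the
total area is triangulation-independent.

Patches are refined to the surrounding density by longest-edge bisection
(splitting the longest edge of the pair, propagating to the neighbor when
its longest edge differs), with new midpoints projected onto the
isosurface; the threshold is 1.5× the loop's mean boundary edge length.
Loops whose patch could not be fully glued are closed by a greedy
best-ear pass and, as a last resort, a center-vertex fan (new-vertex
edges cannot collide, so closure is guaranteed).  Vertices left with two
separate triangle fans by independently zipped seams are split into
coincident duplicates, restoring vertex-manifoldness without moving
geometry.

### Refinement

Stitched meshes carry seam triangles shaped by where the fronts happened
to collide, and all vertices inherit the field's voxel-scale ripple.  A
few alternating passes of (a) Lawson edge flips — flip an interior edge
when that increases the minimal angle over its two triangles and keeps
both facing the same way — and (b) umbrella relaxation with immediate
re-projection onto ψ = isovalue equalize the triangulation.  Because
every vertex ends on the same isosurface the other stages use, surface
accuracy is unchanged by construction (the phantom tests confirm the max
distance moves by <0.01 voxel).  Five rounds are the default; the loop
stops early once a pass makes no flips.

## Metrics

* **Edge ratio** τ = min/max edge length per triangle, histogrammed in
  decile bins; the headline fractions are τ ≥ 0.8 (close to equilateral)
  and τ < 0.3 (needles).
* **Surface distance**: points are sampled on both surfaces (all vertices
  plus a nested barycentric lattice per triangle — nested so refining the
  sampling is monotone in the measured max), each measured to the other
  surface by exact point-to-triangle distance (KD-tree-pruned) or |signed
  distance| for analytic references; mean/max/RMS are taken over the
  pooled directed distances.
* **RMS curvature** √((k²max+k²min)/2) per vertex from a quadric fit
  (z = ax² + bxy + cy² + dx + ey in the normal frame, shape operator of
  the graph at the origin) over the 1-ring (2-ring fallback).  Validated
  against spheres (1/R), planes (0) and cylinders (1/(ρ√2)).
* **Topology**: Euler characteristic over referenced vertices, face
  components, boundary-edge count, edge- and vertex-level manifoldness,
  orientation consistency.

## Phantoms and what the tests show

The phantoms (sphere, capsule tube, torus, Y-bifurcation of two capsules,
dumbbell of two spheres joined by a tube) have exact signed distance
functions; rasterization marks a voxel as object iff its center is
strictly inside, with the lattice aligned so the bounding-box midpoint is
a voxel center.  They emulate the essential difficulties of vascular
data — curved tubes, a branching junction with a concave crease, a
genus-1 surface, curvature contrast — under a perfectly clean
segmentation.  What they do not emulate: segmentation noise (isolated
voxels, rough walls), contacting or near-touching branches, very long
vessel trees, and strongly anisotropic clinical spacings in combination
with all of the above.  Passing tests therefore demonstrate correctness
of the pipeline's geometry and topology handling on clean input, not
robustness to segmentation errors.

Default study conditions used by the tests and the acceptance script:
sphere R = 20 at unit spacing, depth 6; Y-bifurcation with radius-6
branches at 60°, depth 6; torus 12/4 (depth 5 in the topology test, which
only asks for the genus); dumbbell 15/5 with a radius-3 neck, depth 6;
ρ = 0.15 and k = 10 throughout.

## Parameters

| parameter | default | meaning |
|---|---|---|
| ρ | 0.15 | triangle edge length as a fraction of the local curvature radius |
| k | 10 | neighbors for the covariance normal |
| depth d | 7 (6 for desk-scale phantoms) | octree depth of the Poisson basis |
| r_min, r_max | 0.5·min spacing, 100·max spacing | curvature-radius clamp |
| edge floor | 1.0 node width | smallest edge the field can justify |
| CG tolerance | 1e-8 relative | Poisson solver stopping rule |
| refine rounds | 5 | flip+relax passes |

## Known limitations

* The expansion stage's front merging and relaxed ears extend the stated
  expansion rules; without them, colliding fronts stall into very long
  winding gaps whose chord patches are poor.  The merge step is the
  standard device of the marching-triangles family.
* The gap DP's dihedral/area tie-breaks are heuristic under the
  tabulated-subpatch approximation (see above); the max-min-angle
  guarantee is exact.
* Pinch repair duplicates vertices at seam kisses; the surface is
  combinatorially manifold there but geometrically touching.
* Octree depths above 8 are impractical in the complete-grid realization
  (memory), and depths that push the node width well below the voxel size
  degrade normal quality rather than improving accuracy.
* The pipeline assumes a validated segmentation: no denoising, no
  multi-label handling, no DICOM series reading.
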