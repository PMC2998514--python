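# vesselmesh

Scale-adaptive surface reconstruction of vascular structures from binary
segmentation volumes.

Given a segmented vessel volume (1 = vessel, 0 = background), `vesselmesh`
produces a smooth, closed, two-manifold triangle mesh whose triangle size
follows the local curvature of the vessel wall — small triangles on tight
bends and thin branches, large triangles on straight segments.  Meshes like
this are the input that computational fluid dynamics, finite-element
analysis, and interactive surgical-planning tools need: accurate to the
segmentation, free of staircase artifacts, and built from close-to-
equilateral triangles.

## Method

The pipeline is model-free (no centerline or circular-cross-section
assumption) and runs in six stages:

1. **Point extraction** — every face shared by an object voxel and a
   background voxel yields a sample at the face center.  Thin structures,
   found with a white top-hat transform (3×3×3 box), are sampled at 4×
   density through subface refinement.
2. **Normal estimation** — for each sample *P*, the covariance matrix of
   its *k* nearest neighbors (default *k* = 10),

       C = Σ (p_i − p̄)(p_i − p̄)ᵀ,

   gives the surface normal as the eigenvector of the smallest eigenvalue,
   oriented toward the sample's source voxel (inward).
3. **Poisson indicator function** — the indicator ψ (≈1 inside, ≈0
   outside) is recovered from the inward normal field V⃗ by solving
   Δψ = ∇·V⃗ in a Galerkin basis of tensor-product quadratic B-splines on
   the depth-*d* nodes of an octree over the samples, by conjugate
   gradients.  The reconstructed surface is the level set ψ = isovalue
   (the mean of ψ over the samples).
4. **Mesh expansion** — a seed hexagon is placed in the tangent plane of a
   surface point and the mesh grows from a queue of boundary edges.  The
   local radius of curvature is probed from surface normals via the chord
   formula r(p) = min_i d_i / (2 sin(θ_i/2)); new triangle edges are sized
   ρ·r (default ρ = 0.15), with a 50°–70° angle window, an ear rule for
   wedges under 70°, a one-third-longest-edge collision rule, and
   front-merging where fronts meet.
5. **Gap stitching** — the boundary loops left by expansion are closed by
   a dynamic-programming minimum-weight triangulation under the
   lexicographic weight (α, β, A): maximize the minimal triangle angle α
   first, then minimize the worst dihedral β, then the area A.  Patches
   are subdivided to the surrounding density and all new vertices are
   projected back onto ψ = isovalue.
6. **Refinement** — min-angle-improving edge flips plus tangential vertex
   relaxation with re-projection onto the isosurface, which equalizes the
   triangles without moving the surface.

Quality is measured by the edge ratio τ = |t|₀/|t|∞ (min/max edge length;
1 = equilateral), sampled symmetric Hausdorff-style distances, per-vertex
RMS curvature √((k²max + k²min)/2), and topology reports (Euler
characteristic, manifoldness).

Analytic phantoms (sphere, tube, torus, Y-bifurcation, dumbbell) with
exact signed-distance ground truth are built in, so the whole pipeline is
testable end to end without any clinical data.

## Worked example

```python
from vesselmesh import Sphere, PipelineConfig, run_pipeline

result = run_pipeline(Sphere((0, 0, 0), 20.0), PipelineConfig(depth=6))
topo = result.report.topology
print(f"{topo['vertices']} vertices, {topo['faces']} triangles, "
      f"euler={topo['euler']}, manifold={topo['manifold']}")
print(f"tau >= 0.8: {100 * result.report.fraction_tau_atleast_08:.1f}%  "
      f"tau < 0.3: {100 * result.report.fraction_tau_below_03:.2f}%")
print(f"max distance to analytic sphere: "
      f"{result.report.distance_stats['max']:.3f} voxels")
```

prints (about half a minute on one CPU):

```
1060 vertices, 2116 triangles, euler=2, manifold=True
tau >= 0.8: 51.7%  tau < 0.3: 1.04%
max distance to analytic sphere: 0.459 voxels
```

That is: the rasterized R = 20 sphere came back as a closed, manifold,
genus-0 mesh; about half the triangles are close to equilateral; and no
point of the reconstruction is more than half a voxel from the true
sphere.

The same pipeline is exposed on the command line:

```sh
vesselmesh reconstruct --in seg.nii.gz --out mesh.ply --report report.json
vesselmesh reconstruct --phantom bifurcation --depth 6 --out y.ply
vesselmesh evaluate --mesh y.ply --phantom bifurcation
vesselmesh phantom --kind torus --out torus.mha
```

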