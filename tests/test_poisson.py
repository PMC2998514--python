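"""Octree structure, B-spline basis, splatting, and the Poisson solve."""

import numpy as np
import pytest

from vesselmesh.normals import OrientedPointCloud
from vesselmesh.poisson import (
    Octree,
    basis_value,
    build_octree,
    compute_indicator_field,
    select_isovalue,
    solve_poisson,
    splat_vector_field,
)
from vesselmesh.volume import Sphere


def _analytic_sphere_cloud(R=20.0, n=3000):
    P = Sphere((0, 0, 0), R).surface_samples(n)
    normals = -P / np.linalg.norm(P, axis=1, keepdims=True)
    return OrientedPointCloud(P, normals)


def _isosurface_radius(field, directions, lo=0.6, hi=1.25, R=20.0):
    lo = np.full(len(directions), lo * R)
    hi = np.full(len(directions), hi * R)
    for _ in range(40):
        mid = (lo + hi) / 2
        inside = field.psi(directions * mid[:, None]) > field.isovalue
        lo = np.where(inside, mid, lo)
        hi = np.where(inside, hi, mid)
    return (lo + hi) / 2


class TestOctree:
    def test_single_point_forces_one_chain(self):
        cloud = OrientedPointCloud(np.array([[0.2, 0.3, -0.1]]),
                                   np.array([[0.0, 0, 1]]))
        tree = build_octree(cloud, depth=4)
        assert len(tree.leaves()) == 1
        chain = tree.depth_chain([0.2, 0.3, -0.1])
        assert [n[0] for n in chain] == [0, 1, 2, 3, 4]

    def test_antipodal_points_get_disjoint_leaves(self):
        pos = np.array([[-10.0, 0, 0], [10.0, 0, 0]])
        cloud = OrientedPointCloud(pos, np.tile([1.0, 0, 0], (2, 1)))
        tree = build_octree(cloud, depth=5)
        leaves = tree.leaves()
        assert len(leaves) == 2

    def test_every_sample_in_a_max_depth_leaf(self, sphere_cloud):
        tree = build_octree(sphere_cloud, depth=6)
        for p in sphere_cloud.positions[::37]:
            leaf = tree.leaf_containing(p)
            assert leaf is not None and leaf[0] == 6
            center = tree.node_center(6, leaf[1:])
            assert np.all(np.abs(p - center) <= tree.node_width(6) / 2 + 1e-12)

    def test_child_geometry(self):
        tree = Octree((0.0, 0.0, 0.0), 16.0, 4)
        parent = tree.node_center(1, (0, 0, 0))
        child = tree.node_center(2, (0, 0, 0))
        np.testing.assert_allclose(parent - child, np.full(3, 16.0 / 8))

    def test_depth_bounds_validated(self):
        with pytest.raises(ValueError):
            Octree((0, 0, 0), 8.0, 3)


class TestBasis:
    def test_peak_at_center_scaled_by_width(self):
        c = np.array([1.0, 2.0, 3.0])
        for w in (0.5, 1.0, 2.0):
            val = basis_value(c, w, c)
            assert val == pytest.approx(0.75**3 / w**3)

    def test_zero_outside_support(self):
        c = np.zeros(3)
        assert basis_value(c, 1.0, [1.51, 0, 0]) == 0.0
        assert basis_value(c, 2.0, [0, 3.1, 0]) == 0.0

    def test_unit_integral(self):
        # quadrature over the support box
        w = 1.3
        xs = np.linspace(-1.5 * w, 1.5 * w, 61)
        gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        vals = basis_value(np.zeros(3), w, pts).reshape(gx.shape)
        h = xs[1] - xs[0]
        assert np.sum(vals) * h**3 == pytest.approx(1.0, abs=1e-3)


class TestSplat:
    def _tree(self):
        pos = np.array([[0.0, 0.0, 0.0]])
        cloud = OrientedPointCloud(pos, np.array([[0.0, 0, 1]]))
        tree = Octree((0.0, 0.0, 0.0), 16.0, 4)
        return cloud, tree

    def test_sample_at_node_center_gets_full_weight(self):
        _, tree = self._tree()
        c = tree.node_center(4, (8, 8, 8))
        cloud = OrientedPointCloud(c[None, :], np.array([[0.0, 0, 1]]))
        V = splat_vector_field(cloud, tree)
        assert V[8, 8, 8, 2] == pytest.approx(1.0)
        assert np.abs(V).sum() == pytest.approx(1.0)

    def test_axis_midpoint_splits_half_half(self):
        _, tree = self._tree()
        c = tree.node_center(4, (8, 8, 8))
        mid = c + np.array([tree.node_width(4) / 2, 0.0, 0.0])
        cloud = OrientedPointCloud(mid[None, :], np.array([[0.0, 0, 1]]))
        V = splat_vector_field(cloud, tree)
        assert V[8, 8, 8, 2] == pytest.approx(0.5)
        assert V[9, 8, 8, 2] == pytest.approx(0.5)

    def test_total_mass_conserved(self, sphere_cloud):
        tree = build_octree(sphere_cloud, depth=5)
        V = splat_vector_field(sphere_cloud, tree)
        np.testing.assert_allclose(
            V.sum(axis=(0, 1, 2)), sphere_cloud.normals.sum(axis=0), atol=1e-9)


class TestSolve:
    def test_zero_field_gives_zero_coefficients(self):
        V = np.zeros((16, 16, 16, 3))
        coeffs = solve_poisson(V, 0.5)
        assert np.all(coeffs == 0.0)

    def test_indicator_semantics_inside_above_outside(self, sphere_field):
        center = sphere_field.psi(np.zeros(3))
        lo, hi = sphere_field.bounds
        corner = sphere_field.psi(hi - 3 * sphere_field.node_width)
        assert center > sphere_field.isovalue > corner

    def test_flipping_normals_negates_psi(self):
        cloud = _analytic_sphere_cloud(R=10.0, n=800)
        flipped = OrientedPointCloud(cloud.positions.copy(), -cloud.normals)
        f1 = compute_indicator_field(cloud, depth=5)
        f2 = compute_indicator_field(flipped, depth=5)
        pts = cloud.positions[::50] * 0.9
        np.testing.assert_allclose(f1.psi(pts), -f2.psi(pts), atol=1e-6)


class TestEvaluate:
    def test_gradient_matches_finite_differences(self, sphere_field):
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(100, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = dirs * 20.0
        _, grad = sphere_field.evaluate(pts)
        eps = 1e-4
        for ax in range(3):
            dp = pts.copy()
            dp[:, ax] += eps
            dm = pts.copy()
            dm[:, ax] -= eps
            fd = (sphere_field.psi(dp) - sphere_field.psi(dm)) / (2 * eps)
            rel = np.abs(fd - grad[:, ax]) / (np.linalg.norm(grad, axis=1) + 1e-12)
            assert rel.max() < 1e-3

    def test_sign_change_near_true_radius(self, sphere_field):
        rr = np.linspace(15.0, 24.0, 181)
        # along an axis the voxelized surface itself sits at a face plane
        # half a voxel in; single clean crossing is all we can ask there
        ray = np.stack([rr, np.zeros_like(rr), np.zeros_like(rr)], axis=1)
        psi = sphere_field.psi(ray) - sphere_field.isovalue
        assert len(np.flatnonzero(np.diff(np.sign(psi)))) == 1
        # a generic direction probes the reconstruction, not the staircase
        d = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
        psi = sphere_field.psi(rr[:, None] * d) - sphere_field.isovalue
        crossings = rr[np.flatnonzero(np.diff(np.sign(psi)))]
        assert len(crossings) == 1
        assert abs(crossings[0] - 20.0) < 0.5

    def test_continuity(self, sphere_field):
        p = np.array([19.7, 2.0, -3.0])
        base = sphere_field.psi(p)
        deltas = [1e-2, 1e-4, 1e-6]
        errs = [abs(sphere_field.psi(p + np.array([d, 0, 0])) - base)
                for d in deltas]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-5

    def test_outside_bounds_rejected(self, sphere_field):
        lo, hi = sphere_field.bounds
        with pytest.raises(ValueError, match="outside"):
            sphere_field.evaluate(hi + 1.0)


class TestIsovalue:
    def test_is_the_mean_over_samples(self):
        assert select_isovalue(np.array([0.2, 0.8])) == pytest.approx(0.5)

    def test_isosurface_radius_within_half_voxel(self, sphere_field):
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(400, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        r = _isosurface_radius(sphere_field, dirs)
        assert np.abs(r - 20.0).max() < 0.5


class TestFieldProperties:
    def test_translation_equivariance(self):
        cloud = _analytic_sphere_cloud(R=8.0, n=600)
        delta = np.array([0.37, -0.21, 0.11])
        moved = OrientedPointCloud(cloud.positions + delta, cloud.normals.copy())
        f1 = compute_indicator_field(cloud, depth=5)
        f2 = compute_indicator_field(moved, depth=5)
        pts = cloud.positions[::25] * 0.95
        np.testing.assert_allclose(f1.psi(pts), f2.psi(pts + delta), atol=1e-6)
        assert f1.isovalue == pytest.approx(f2.isovalue, abs=1e-9)

    def test_inside_outside_separation(self, sphere_field):
        rng = np.random.default_rng(4)
        dirs = rng.normal(size=(500, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        inside = sphere_field.psi(dirs * 18.0)
        outside = sphere_field.psi(dirs * 22.0)
        assert (inside > sphere_field.isovalue).mean() >= 0.99
        assert (outside < sphere_field.isovalue).mean() >= 0.99

    def test_refinement_does_not_hurt_on_exact_samples(self):
        # on an analytic (noise-free) sphere cloud, a deeper basis cannot
        # worsen the isosurface radius
        cloud = _analytic_sphere_cloud(R=20.0, n=4000)
        rng = np.random.default_rng(2)
        dirs = rng.normal(size=(200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        errs = []
        for depth in (5, 6):
            fld = compute_indicator_field(cloud, depth=depth)
            r = _isosurface_radius(fld, dirs)
            errs.append(np.abs(r - 20.0).mean())
        assert errs[1] <= errs[0]
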