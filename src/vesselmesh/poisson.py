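"""Poisson indicator function from an oriented point cloud.

The indicator function psi (~1 inside the vessel, ~0 outside) is recovered
from the samples' inward normal field V by solving the Poisson equation

    laplacian(psi) = div(V)

in a Galerkin basis of compactly supported kernels attached to the depth-d
nodes of an octree over the cloud's bounding cube.  Each node o with center
c and width w carries

    F_o(q) = F((q - c) / w) / w^3

where F is the tensor-product quadratic B-spline — the standard compactly
supported approximation of a unit-variance Gaussian, and the choice that
makes the stiffness matrix sparse.  V is defined by splatting each sample's
inward normal onto the 8 depth-d nodes around it with trilinear weights.

The solver realizes the depth-d node set as a complete 2^d grid over the
bounding cube and applies the stiffness operator with separable 5-tap
stencils (the 1D B-spline product integrals), so the system is solved
matrix-free by conjugate gradients.  The math is identical to solving on the
refined-to-depth-d octree; the complete grid is simply the bookkeeping that
lets the operator factor into 1D correlations.  Depths up to 8 are practical
this way (2^24 nodes); the accompanying :class:`Octree` provides the sparse
node structure for inspection and containment queries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, cg

from vesselmesh.normals import OrientedPointCloud

DEFAULT_DEPTH = 7
BOUNDING_CUBE_SCALE = 1.25

# ---------------------------------------------------------------------------
# Quadratic B-spline kernel and its 1D product integrals
# ---------------------------------------------------------------------------

def bspline2(t: np.ndarray) -> np.ndarray:
    """Unit-integral quadratic B-spline, support (-1.5, 1.5)."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    near = t <= 0.5
    mid = (t > 0.5) & (t < 1.5)
    out[near] = 0.75 - t[near] ** 2
    out[mid] = 0.5 * (1.5 - t[mid]) ** 2
    return out


def bspline2_deriv(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    a = np.abs(t)
    out = np.zeros_like(t)
    near = a <= 0.5
    mid = (a > 0.5) & (a < 1.5)
    out[near] = -2.0 * t[near]
    out[mid] = -(1.5 - a[mid]) * np.sign(t[mid])
    return out


def _product_integrals() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1D integrals of shifted B-spline products for integer offsets -2..2:

    m0[k]  = int b(t) b(t+k) dt      (mass)
    m1[k]  = int b'(t) b'(t+k) dt    (stiffness)
    m10[k] = int b'(t) b(t+k) dt     (mixed, odd in k)
    """
    x = np.linspace(-1.5, 1.5, 6001)
    b = bspline2(x)
    db = bspline2_deriv(x)
    m0 = np.empty(5)
    m1 = np.empty(5)
    m10 = np.empty(5)
    for i, k in enumerate(range(-2, 3)):
        bs = bspline2(x + k)
        dbs = bspline2_deriv(x + k)
        m0[i] = np.trapezoid(b * bs, x)
        m1[i] = np.trapezoid(db * dbs, x)
        m10[i] = np.trapezoid(db * bs, x)
    return m0, m1, m10


_M0, _M1, _M10 = _product_integrals()


def basis_value(center: np.ndarray, width: float, q: np.ndarray) -> np.ndarray:
    """F_o(q) for a node with the given center and width; zero outside the
    1.5-width support box."""
    u = (np.atleast_2d(np.asarray(q, dtype=float)) - np.asarray(center)) / width
    return bspline2(u[..., 0]) * bspline2(u[..., 1]) * bspline2(u[..., 2]) / width**3


# ---------------------------------------------------------------------------
# Octree structure
# ---------------------------------------------------------------------------

class Octree:
    """Adaptive octree over a bounding cube, refined to ``max_depth`` along
    the inserted sample positions.

    Nodes are addressed by (depth, ix, iy, iz); the node at depth l and grid
    index g has width ``root_width / 2**l`` and center
    ``cube_origin + (g + 0.5) * width``, so each child's center sits at its
    parent's center offset by a quarter of the parent width per axis.
    """

    def __init__(self, center: np.ndarray, root_width: float, max_depth: int):
        if not 4 <= max_depth <= 10:
            raise ValueError(f"octree depth must be in [4, 10], got {max_depth}")
        self.center = np.asarray(center, dtype=float)
        self.root_width = float(root_width)
        self.max_depth = int(max_depth)
        self.cube_origin = self.center - self.root_width / 2.0
        self.nodes: set[tuple[int, int, int, int]] = {(0, 0, 0, 0)}

    @classmethod
    def from_cloud(
        cls, cloud: OrientedPointCloud, max_depth: int,
        scale: float = BOUNDING_CUBE_SCALE,
    ) -> "Octree":
        if len(cloud) == 0:
            raise ValueError("cannot build an octree over an empty cloud")
        lo = cloud.positions.min(axis=0)
        hi = cloud.positions.max(axis=0)
        width = float(max((hi - lo).max(), 1e-9)) * scale
        tree = cls((lo + hi) / 2.0, width, max_depth)
        tree.insert(cloud.positions)
        return tree

    def node_width(self, depth: int) -> float:
        return self.root_width / (1 << depth)

    def node_center(self, depth: int, idx) -> np.ndarray:
        w = self.node_width(depth)
        return self.cube_origin + (np.asarray(idx, dtype=float) + 0.5) * w

    def insert(self, points: np.ndarray) -> None:
        """Refine the tree to max_depth along each point's path."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (pts - self.cube_origin) / self.root_width
        if np.any(rel < 0) or np.any(rel >= 1):
            raise ValueError("point outside octree bounding cube")
        for depth in range(1, self.max_depth + 1):
            idx = np.floor(rel * (1 << depth)).astype(int)
            for g in np.unique(idx, axis=0):
                self.nodes.add((depth, int(g[0]), int(g[1]), int(g[2])))

    def leaves(self) -> list[tuple[int, int, int, int]]:
        """Nodes at max depth (the leaves carrying samples)."""
        return sorted(n for n in self.nodes if n[0] == self.max_depth)

    def leaf_containing(self, point: np.ndarray) -> tuple[int, int, int, int] | None:
        rel = (np.asarray(point, dtype=float) - self.cube_origin) / self.root_width
        if np.any(rel < 0) or np.any(rel >= 1):
            return None
        g = tuple(np.floor(rel * (1 << self.max_depth)).astype(int))
        node = (self.max_depth, *g)
        return node if node in self.nodes else None

    def depth_chain(self, point: np.ndarray) -> list[tuple[int, int, int, int]]:
        """Root-to-leaf chain of existing nodes containing the point."""
        rel = (np.asarray(point, dtype=float) - self.cube_origin) / self.root_width
        chain = []
        for depth in range(self.max_depth + 1):
            g = tuple(np.floor(rel * (1 << depth)).astype(int))
            node = (depth, *g)
            if node in self.nodes:
                chain.append(node)
        return chain


def build_octree(
    cloud: OrientedPointCloud, depth: int, scale: float = BOUNDING_CUBE_SCALE
) -> Octree:
    """Octree over the cloud's bounding cube (expanded by ``scale``),
    refined to ``depth`` along sample positions."""
    return Octree.from_cloud(cloud, depth, scale)


# ---------------------------------------------------------------------------
# Vector-field splatting
# ---------------------------------------------------------------------------

def splat_vector_field(cloud: OrientedPointCloud, tree: Octree) -> np.ndarray:
    """Distribute each sample's inward normal over the 8 nearest depth-d
    node centers with trilinear weights (which sum to 1 per sample).

    Returns the dense (n, n, n, 3) per-node vector coefficients,
    n = 2**max_depth.
    """
    d = tree.max_depth
    n = 1 << d
    w = tree.node_width(d)
    V = np.zeros((n, n, n, 3))
    u = (cloud.positions - tree.cube_origin) / w - 0.5
    if np.any(u < -0.5) or np.any(u > n - 0.5):
        raise ValueError("sample outside octree bounds")
    base = np.floor(u).astype(int)
    frac = u - base
    for dx in (0, 1):
        wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
            for dz in (0, 1):
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                weight = wx * wy * wz
                gx = np.clip(base[:, 0] + dx, 0, n - 1)
                gy = np.clip(base[:, 1] + dy, 0, n - 1)
                gz = np.clip(base[:, 2] + dz, 0, n - 1)
                np.add.at(V, (gx, gy, gz), weight[:, None] * cloud.normals)
    return V


# ---------------------------------------------------------------------------
# Poisson solve
# ---------------------------------------------------------------------------

def _stiffness_apply(c: np.ndarray, w: float) -> np.ndarray:
    """(A c)[g] = sum_h c[h] int grad F_g . grad F_h, as separable 5-tap
    correlations; the even stencils make correlation == convolution."""
    out = np.zeros_like(c)
    for axis in range(3):
        term = c
        for ax2 in range(3):
            taps = _M1 if ax2 == axis else _M0
            term = ndimage.correlate1d(term, taps, axis=ax2, mode="constant")
        out += term
    return out / w**5


def _divergence_rhs(V: np.ndarray, w: float) -> np.ndarray:
    """Right-hand side of the normal equations, b[g] = int grad F_g . V
    (equivalently -int F_g div V after integration by parts), with V
    expanded in the node basis."""
    m10_rev = _M10[::-1]  # correlation over Delta = h - g needs m10[-Delta]
    b = np.zeros(V.shape[:3])
    for axis in range(3):
        term = V[..., axis]
        for ax2 in range(3):
            taps = m10_rev if ax2 == axis else _M0
            term = ndimage.correlate1d(term, taps, axis=ax2, mode="constant")
        b += term
    return b / w**4


def solve_poisson(
    V: np.ndarray, node_width: float, rtol: float = 1e-8,
    maxiter: int | None = None,
) -> np.ndarray:
    """Solve the Galerkin Poisson system for the basis coefficients of psi.

    The system matrix (gradients' Gram matrix) is symmetric positive
    definite, so plain conjugate gradients apply; a zero vector field yields
    the zero coefficient vector.
    """
    shape = V.shape[:3]
    size = int(np.prod(shape))
    b = _divergence_rhs(V, node_width).ravel()
    if not np.all(np.isfinite(b)):
        raise FloatingPointError("non-finite right-hand side in Poisson solve")
    if np.linalg.norm(b) == 0.0:
        return np.zeros(shape)
    if maxiter is None:
        maxiter = int(10 * math.sqrt(size)) + 1000
    op = LinearOperator(
        (size, size),
        matvec=lambda x: _stiffness_apply(x.reshape(shape), node_width).ravel(),
    )
    x, info = cg(op, b, rtol=rtol, atol=0.0, maxiter=maxiter)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("Poisson solver diverged (non-finite iterate)")
    if info > 0:
        warnings.warn(
            f"conjugate gradients hit the iteration cap ({maxiter}); "
            "residual above tolerance", RuntimeWarning, stacklevel=2,
        )
    return x.reshape(shape)


# ---------------------------------------------------------------------------
# Evaluable field
# ---------------------------------------------------------------------------

@dataclass
class ImplicitField:
    """Solved indicator function psi with gradient and isovalue.

    ``coeffs[g]`` is the basis weight of the depth-d node at grid index g.
    """

    coeffs: np.ndarray
    cube_origin: np.ndarray
    node_width: float
    depth: int
    isovalue: float = 0.0
    octree: Octree | None = field(default=None, repr=False)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.coeffs.shape[0]
        lo = self.cube_origin
        return lo, lo + n * self.node_width

    def evaluate(self, points: np.ndarray, with_gradient: bool = True):
        """psi (and grad psi) at world points; points must lie inside the
        bounding cube."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        single = np.asarray(points).ndim == 1
        n = self.coeffs.shape[0]
        w = self.node_width
        u = (pts - self.cube_origin) / w - 0.5
        if np.any(u < -0.5 - 1e-9) or np.any(u > n - 0.5 + 1e-9):
            raise ValueError("evaluation point outside octree bounds")
        base = np.floor(u).astype(int)
        psi = np.zeros(len(pts))
        grad = np.zeros((len(pts), 3)) if with_gradient else None
        # nodes within the 1.5-width support: offsets -1..2 around the base cell
        offs = np.arange(-1, 3)
        t = u[:, None, :] - (base[:, None, :] + offs[None, :, None])  # (m,4,3)
        bw = bspline2(t)           # b weights per axis
        dbw = bspline2_deriv(t)
        g = base[:, None, :] + offs[None, :, None]
        inside = (g >= 0) & (g < n)
        gc = np.clip(g, 0, n - 1)
        bw = np.where(inside, bw, 0.0)
        dbw = np.where(inside, dbw, 0.0)
        for i in range(4):
            for j in range(4):
                wij = bw[:, i, 0] * bw[:, j, 1]
                for k in range(4):
                    cvals = self.coeffs[gc[:, i, 0], gc[:, j, 1], gc[:, k, 2]]
                    psi += cvals * wij * bw[:, k, 2]
                    if with_gradient:
                        grad[:, 0] += cvals * dbw[:, i, 0] * bw[:, j, 1] * bw[:, k, 2]
                        grad[:, 1] += cvals * bw[:, i, 0] * dbw[:, j, 1] * bw[:, k, 2]
                        grad[:, 2] += cvals * wij * dbw[:, k, 2]
        psi /= w**3
        if with_gradient:
            grad /= w**4
            if single:
                return psi[0], grad[0]
            return psi, grad
        return psi[0] if single else psi

    def psi(self, points: np.ndarray) -> np.ndarray:
        return self.evaluate(points, with_gradient=False)


def select_isovalue(fieldvals_at_samples: np.ndarray) -> float:
    """The iso-level is the mean of psi over the sample positions."""
    return float(np.mean(fieldvals_at_samples))


def compute_indicator_field(
    cloud: OrientedPointCloud,
    depth: int = DEFAULT_DEPTH,
    scale: float = BOUNDING_CUBE_SCALE,
    rtol: float = 1e-8,
) -> ImplicitField:
    """Full indicator-function pipeline: octree, normal splatting, Poisson
    solve, and isovalue selection."""
    tree = build_octree(cloud, depth, scale)
    V = splat_vector_field(cloud, tree)
    coeffs = solve_poisson(V, tree.node_width(depth), rtol=rtol)
    fld = ImplicitField(
        coeffs=coeffs,
        cube_origin=tree.cube_origin.copy(),
        node_width=tree.node_width(depth),
        depth=depth,
        octree=tree,
    )
    fld.isovalue = select_isovalue(fld.psi(cloud.positions))
    return fld
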