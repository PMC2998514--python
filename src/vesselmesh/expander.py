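"""Curvature-adaptive polygonization of the implicit surface: expansion stage.

The isosurface psi = isovalue is triangulated by growing a mesh across it.
A seed hexagon is placed in the tangent plane of a starting surface point,
sized by the local radius of curvature r, and the mesh then expands from a
FIFO queue of boundary edges: each popped edge either closes an "ear" with
an adjacent boundary edge meeting it at less than 70 degrees, or sprouts a
new vertex placed so the new triangle is close to equilateral with edge
length rho * r.  Edge length therefore scales with the local radius of
curvature — small triangles on tight bends, large ones on straight segments.

A candidate triangle is accepted only if its base angles fall in [50, 70]
degrees and it does not approach any unrelated boundary triangle closer than
one third of the longest edge involved.  Regions where no candidate is
acceptable are left as open gaps for the stitching stage.

The radius of curvature at a surface point p with normal n_p is probed from
nearby surface points q_i (normals n_qi), using chord length d_i = |p - q_i|
and normal deviation theta_i:

    r(p) = min_i  d_i / (2 sin(theta_i / 2))

which is exact on a sphere (the chord of a central angle theta has length
2 R sin(theta/2)).
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from vesselmesh.normals import OrientedPointCloud
from vesselmesh.poisson import ImplicitField

DEFAULT_RHO = 0.15
ANGLE_MIN_DEG = 50.0
ANGLE_MAX_DEG = 70.0
EAR_ANGLE_DEG = 70.0
_ANGLE_FLOOR_RAD = 1e-4

# diagnostic counters for candidate dispositions (reset freely in tests)
REJECTS: Counter = Counter()


class ProjectionError(RuntimeError):
    """Newton projection onto the isosurface failed to converge."""


class VanishingGradientError(ProjectionError):
    """The field gradient vanished (e.g. at a symmetry center)."""


class ExpansionCapError(RuntimeError):
    """Triangle cap exceeded during expansion (runaway growth)."""


# ---------------------------------------------------------------------------
# Surface projection and curvature probing
# ---------------------------------------------------------------------------

def _psi_tolerance(field: ImplicitField) -> float:
    span = float(np.ptp(field.coeffs)) / field.node_width**3
    return 1e-6 * max(span, 1e-12)


def project_to_surface(
    x: np.ndarray, field: ImplicitField, max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton-project a point onto the isosurface.

    Iterates ``x <- x - (psi - iso) * grad / |grad|^2`` until |psi - iso|
    drops below 1e-6 of the field's value span.  Returns the surface point
    and the *outward* unit normal there (psi increases inward, so outward is
    ``-grad/|grad|``).
    """
    x = np.asarray(x, dtype=float).copy()
    tol = _psi_tolerance(field)
    step_cap = 2.0 * field.node_width
    # typical surface gradient is ~span/width; 4 orders below that is a
    # critical point (e.g. the symmetric center of a closed shape)
    grad_floor = 1e-4 * max(float(np.ptp(field.coeffs)) / field.node_width**4, 1e-12)
    for _ in range(max_iter):
        try:
            psi, grad = field.evaluate(x)
        except ValueError as exc:  # wandered outside the octree cube
            raise ProjectionError(str(exc)) from exc
        gn2 = float(grad @ grad)
        if math.sqrt(gn2) < grad_floor:
            raise VanishingGradientError(
                f"vanishing gradient at {x} (|grad|={math.sqrt(gn2):.3g})"
            )
        err = psi - field.isovalue
        if abs(err) < tol:
            return x, -grad / math.sqrt(gn2)
        step = -err / gn2 * grad
        slen = np.linalg.norm(step)
        if slen > step_cap:
            step *= step_cap / slen
        x += step
    raise ProjectionError(f"Newton projection did not converge near {x}")


def smoothed_normal(
    field: ImplicitField, p: np.ndarray, radius: float,
) -> np.ndarray:
    """Outward unit normal from the field gradient averaged over a tangent
    ring of the given radius.

    The reconstructed field carries voxel-scale ripple from the staircase
    samples; averaging normalized gradients over a ring proportional to the
    probing distance keeps the curvature signal (which is symmetric about
    p) while cancelling the ripple, so curvature probes read geometry
    rather than noise."""
    _, g = field.evaluate(p)
    gn = np.linalg.norm(g)
    if gn == 0:
        raise VanishingGradientError(f"vanishing gradient at {p}")
    n0 = g / gn
    t1, t2 = _tangent_basis(n0)
    radius = max(radius, 0.5 * field.node_width)
    ang = np.arange(6) * (math.pi / 3.0)
    ring = p + radius * (np.cos(ang)[:, None] * t1 + np.sin(ang)[:, None] * t2)
    lo, hi = field.bounds
    ring = np.clip(ring, lo + 1e-9, hi - 1e-9)
    _, gr = field.evaluate(ring)
    grn = np.linalg.norm(gr, axis=1, keepdims=True)
    acc = n0 + (gr / np.maximum(grn, 1e-300)).sum(axis=0)
    return -acc / np.linalg.norm(acc)


@dataclass
class CurvatureEstimate:
    r: float
    clamped: bool = False


def probe_radius(
    field: ImplicitField,
    p: np.ndarray,
    n_p: np.ndarray,
    probe_dist: float,
    r_min: float,
    r_max: float,
) -> CurvatureEstimate:
    """Estimate the radius of curvature at a surface point by projecting
    four tangent probes at ``probe_dist`` and applying the chord formula.

    The probe distance must be several node widths: closer probes measure
    the field's voxel-scale ripple instead of the surface's bending (the
    normal-deviation signal grows with distance while the ripple does not).
    The two probes of each tangent direction sample the same geodesic, so
    their radii are averaged before the minimum over directions is taken —
    halving the noise without losing directional sensitivity.
    """
    from vesselmesh.refine import project_points  # local import: cycle guard

    t1, t2 = _tangent_basis(n_p)
    starts = np.array([p + probe_dist * t1, p - probe_dist * t1,
                       p + probe_dist * t2, p - probe_dist * t2])
    probes, ok = project_points(field, starts)
    nq = _smoothed_normals_batch(field, probes, 0.75 * probe_dist)
    r_dirs = []
    for pair in ((0, 1), (2, 3)):
        r_pair = []
        for i in pair:
            if not ok[i]:
                continue
            est = radius_of_curvature(
                p, n_p, probes[i][None, :], nq[i][None, :], r_min, r_max)
            r_pair.append(est.r)
        if r_pair:
            r_dirs.append(float(np.mean(r_pair)))
    if not r_dirs:
        return CurvatureEstimate(r=r_max, clamped=True)
    r = min(r_dirs)
    return CurvatureEstimate(r=r, clamped=r in (r_min, r_max))


def _smoothed_normals_batch(
    field: ImplicitField, P: np.ndarray, radius: float,
) -> np.ndarray:
    """Outward smoothed normals for several points in one field call."""
    P = np.atleast_2d(P)
    lo, hi = field.bounds
    _, g0 = field.evaluate(np.clip(P, lo + 1e-9, hi - 1e-9))
    n0 = g0 / np.maximum(np.linalg.norm(g0, axis=1, keepdims=True), 1e-300)
    radius = max(radius, 0.5 * field.node_width)
    ang = np.arange(6) * (math.pi / 3.0)
    rings = []
    for i, n in enumerate(n0):
        t1, t2 = _tangent_basis(n)
        rings.append(P[i] + radius * (np.cos(ang)[:, None] * t1
                                      + np.sin(ang)[:, None] * t2))
    ring_pts = np.clip(np.concatenate(rings), lo + 1e-9, hi - 1e-9)
    _, gr = field.evaluate(ring_pts)
    gr = gr / np.maximum(np.linalg.norm(gr, axis=1, keepdims=True), 1e-300)
    acc = n0 + gr.reshape(len(P), 6, 3).sum(axis=1)
    return -acc / np.maximum(np.linalg.norm(acc, axis=1, keepdims=True), 1e-300)


def radius_of_curvature(
    p: np.ndarray,
    n_p: np.ndarray,
    probe_points: np.ndarray,
    probe_normals: np.ndarray,
    r_min: float,
    r_max: float,
) -> CurvatureEstimate:
    """Minimum osculating radius over the probes (see module docstring);
    near-parallel normals (theta below 1e-4 rad) read as locally flat and
    contribute r_max.  The result is clamped to [r_min, r_max]."""
    probe_points = np.atleast_2d(probe_points)
    probe_normals = np.atleast_2d(probe_normals)
    if len(probe_points) == 0:
        raise ValueError("need at least one curvature probe")
    d = np.linalg.norm(probe_points - p, axis=1)
    cosang = np.clip(probe_normals @ np.asarray(n_p, dtype=float), -1.0, 1.0)
    theta = np.arccos(cosang)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(theta > _ANGLE_FLOOR_RAD,
                     d / np.maximum(2.0 * np.sin(theta / 2.0), 1e-300), r_max)
    r_raw = float(np.min(r))
    r_clamped = min(max(r_raw, r_min), r_max)
    return CurvatureEstimate(r=r_clamped, clamped=not r_min < r_raw < r_max)


# ---------------------------------------------------------------------------
# Growing mesh structure
# ---------------------------------------------------------------------------

class GrowingMesh:
    """Triangle mesh under construction: two-manifold with boundary.

    Triangles are vertex-index triples with consistent winding (outward
    normals).  A directed edge (u, v) is *boundary* when its reverse (v, u)
    belongs to no triangle; boundary edges of the final expansion form the
    gap loops closed by the stitcher.
    """

    def __init__(self) -> None:
        self.vertices: list[np.ndarray] = []
        self.vertex_normals: list[np.ndarray] = []
        self.triangles: list[tuple[int, int, int] | None] = []
        self.directed: dict[tuple[int, int], int] = {}
        self.boundary: set[tuple[int, int]] = set()
        self.bnd_out: dict[int, set[int]] = {}
        self.bnd_in: dict[int, set[int]] = {}
        self.incident: dict[int, set[int]] = {}
        self.queue: deque[tuple[int, int]] = deque()

    # -- basic accessors ---------------------------------------------------

    def add_vertex(self, pos: np.ndarray, normal: np.ndarray) -> int:
        self.vertices.append(np.asarray(pos, dtype=float))
        self.vertex_normals.append(np.asarray(normal, dtype=float))
        return len(self.vertices) - 1

    def vertex_array(self) -> np.ndarray:
        return np.array(self.vertices) if self.vertices else np.empty((0, 3))

    def face_array(self) -> np.ndarray:
        faces = [t for t in self.triangles if t is not None]
        return np.array(faces, dtype=int) if faces else np.empty((0, 3), dtype=int)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertex_array(), self.face_array()

    @property
    def n_triangles(self) -> int:
        return sum(1 for t in self.triangles if t is not None)

    def triangle_points(self, tri: tuple[int, int, int]) -> np.ndarray:
        return np.array([self.vertices[i] for i in tri])

    # -- topology maintenance ---------------------------------------------

    def can_add(self, a: int, b: int, c: int) -> bool:
        """Would adding triangle (a, b, c) keep an orientable 2-manifold?"""
        if len({a, b, c}) < 3:
            return False
        for e in ((a, b), (b, c), (c, a)):
            if e in self.directed:      # same-direction duplicate: fold-over
                return False
        return True

    def _set_boundary(self, e: tuple[int, int], on: bool) -> None:
        u, v = e
        if on:
            self.boundary.add(e)
            self.bnd_out.setdefault(u, set()).add(v)
            self.bnd_in.setdefault(v, set()).add(u)
        else:
            self.boundary.discard(e)
            self.bnd_out.get(u, set()).discard(v)
            self.bnd_in.get(v, set()).discard(u)

    def add_triangle(self, a: int, b: int, c: int) -> int:
        if not self.can_add(a, b, c):
            raise ValueError(f"adding triangle ({a},{b},{c}) violates manifoldness")
        idx = len(self.triangles)
        self.triangles.append((a, b, c))
        for e in ((a, b), (b, c), (c, a)):
            self.directed[e] = idx
            rev = (e[1], e[0])
            if rev in self.directed:
                self._set_boundary(rev, False)
            else:
                self._set_boundary(e, True)
        for vtx in (a, b, c):
            self.incident.setdefault(vtx, set()).add(idx)
        return idx

    def remove_triangle(self, idx: int) -> None:
        tri = self.triangles[idx]
        if tri is None:
            return
        a, b, c = tri
        self.triangles[idx] = None
        for e in ((a, b), (b, c), (c, a)):
            del self.directed[e]
            self._set_boundary(e, False)
            rev = (e[1], e[0])
            if rev in self.directed:
                self._set_boundary(rev, True)
        for vtx in (a, b, c):
            self.incident[vtx].discard(idx)

    def is_boundary(self, e: tuple[int, int]) -> bool:
        return e in self.boundary

    def boundary_next(self, v: int) -> int | None:
        out = self.bnd_out.get(v)
        if out and len(out) == 1:
            return next(iter(out))
        return None

    def boundary_prev(self, u: int) -> int | None:
        inc = self.bnd_in.get(u)
        if inc and len(inc) == 1:
            return next(iter(inc))
        return None

    def fan_next(self, u: int, v: int) -> int | None:
        """Outgoing boundary edge (v, x) in the same triangle fan as the
        boundary edge (u, v): rotate around v through edge-adjacent
        triangles starting at (u, v) until an open edge is hit.

        Unlike :meth:`boundary_next` this is well defined even when the
        boundary passes through v more than once (a front-merge vertex).
        """
        e = (u, v)
        for _ in range(len(self.incident.get(v, ())) + 2):
            ti = self.directed.get(e)
            if ti is None:
                return None
            tri = self.triangles[ti]
            x = tri[(tri.index(v) + 1) % 3]
            if (x, v) not in self.directed:
                return x  # (v, x) is the fan-matched boundary edge
            e = (x, v)
        return None

    def fan_prev(self, u: int, v: int) -> int | None:
        """Incoming boundary edge (t, u) in the same triangle fan as the
        boundary edge (u, v); the mirror of :meth:`fan_next`."""
        e = (u, v)
        for _ in range(len(self.incident.get(u, ())) + 2):
            ti = self.directed.get(e)
            if ti is None:
                return None
            tri = self.triangles[ti]
            t = tri[(tri.index(u) + 2) % 3]
            if (u, t) not in self.directed:
                return t  # (t, u) is the fan-matched boundary edge
            e = (u, t)
        return None

    def edge_triangle(self, e: tuple[int, int]) -> int | None:
        """Index of the unique triangle containing directed edge e."""
        return self.directed.get(e)

    def boundary_triangles(self) -> set[int]:
        """Triangles owning at least one boundary edge."""
        return {self.directed[e] for e in self.boundary}


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _tri_normal(pts: np.ndarray) -> np.ndarray:
    n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    ln = np.linalg.norm(n)
    return n / ln if ln > 0 else n


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> float:
    """Exact distance from a point to a 3D triangle."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(ap))
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(bp))
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3)
        return float(np.linalg.norm(ap - t * ab))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(cp))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6)
        return float(np.linalg.norm(ap - t * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(np.linalg.norm(p - (b + t * (c - b))))
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    return float(np.linalg.norm(p - (a + v * ab + w * ac)))


def _triangle_distance(tri_a: np.ndarray, tri_b: np.ndarray) -> float:
    """Approximate triangle-to-triangle distance: vertex- and edge-midpoint-
    to-triangle distances in both directions (adequate for the one-third
    proximity rule between similar-size, non-intersecting triangles)."""
    best = math.inf
    for src, dst in ((tri_a, tri_b), (tri_b, tri_a)):
        probes = [src[0], src[1], src[2],
                  (src[0] + src[1]) / 2, (src[1] + src[2]) / 2,
                  (src[2] + src[0]) / 2, src.mean(axis=0)]
        for q in probes:
            best = min(best, _point_triangle_distance(q, dst))
    return best


def _longest_edge(tri: np.ndarray) -> float:
    return max(
        float(np.linalg.norm(tri[0] - tri[1])),
        float(np.linalg.norm(tri[1] - tri[2])),
        float(np.linalg.norm(tri[2] - tri[0])),
    )


# ---------------------------------------------------------------------------
# Expansion driver
# ---------------------------------------------------------------------------

@dataclass
class ExpanderConfig:
    rho: float = DEFAULT_RHO
    r_min: float = 0.5          # set from 0.5 * min spacing by the pipeline
    r_max: float = 100.0        # set from 100 * max spacing by the pipeline
    max_triangles: int = 200_000
    initial_edge: float | None = None  # probe hexagon size; default 2 node widths
    edge_floor_factor: float = 1.0     # min edge length, in field node widths


def _edge_floor(field: ImplicitField, cfg: "ExpanderConfig") -> float:
    """Smallest useful edge length: below ~a node width the field cannot
    resolve curvature and probe noise would shrink triangles indefinitely."""
    return cfg.edge_floor_factor * field.node_width


class _ProximityIndex:
    """KD-tree over mesh vertices, rebuilt lazily, for proximity queries."""

    def __init__(self, mesh: GrowingMesh, rebuild_every: int = 48):
        self.mesh = mesh
        self.rebuild_every = rebuild_every
        self.tree: cKDTree | None = None
        self.tree_size = 0

    def nearby_vertices(self, center: np.ndarray, radius: float) -> list[int]:
        n = len(self.mesh.vertices)
        if self.tree is None or n - self.tree_size >= self.rebuild_every:
            self.tree = cKDTree(self.mesh.vertex_array())
            self.tree_size = n
        hits = self.tree.query_ball_point(center, radius)
        # vertices added since the last rebuild are checked linearly
        for i in range(self.tree_size, n):
            if np.linalg.norm(self.mesh.vertices[i] - center) <= radius:
                hits.append(i)
        return hits


def _proximity_ok(
    mesh: GrowingMesh,
    index: _ProximityIndex,
    cand_pts: np.ndarray,
    exclude: set[int],
) -> bool:
    """The one-third-of-longest-edge rule: candidate triangle must keep its
    distance from every boundary triangle not sharing a vertex with it."""
    cand_longest = _longest_edge(cand_pts)
    center = cand_pts.mean(axis=0)
    radius = 2.0 * cand_longest
    seen: set[int] = set()
    for vi in index.nearby_vertices(center, radius):
        for ti in mesh.incident.get(vi, ()):
            if ti in seen:
                continue
            seen.add(ti)
            tri = mesh.triangles[ti]
            if tri is None or any(v in exclude for v in tri):
                continue
            # interior triangles are tested too: a legitimate front keeps
            # its own wake at >= sin(60) * edge ~ 0.87 L, comfortably past
            # the L/3 threshold, while an overlapping sheet gets caught
            tpts = mesh.triangle_points(tri)
            threshold = max(cand_longest, _longest_edge(tpts)) / 3.0
            if _triangle_distance(cand_pts, tpts) < threshold:
                return False
    return True


def _tangent_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed tangent frame (t1, t2) with t1 x t2 = n."""
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(a, n)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


def seed_mesh(
    field: ImplicitField,
    start: np.ndarray,
    rho: float = DEFAULT_RHO,
    config: ExpanderConfig | None = None,
) -> GrowingMesh:
    """Seed hexagon: project the start point to the surface, probe the local
    radius of curvature with a provisional tangent hexagon, rebuild the
    hexagon with circumradius rho * r, re-project, and emit the 6-triangle
    fan with its outer edges queued."""
    cfg = config or ExpanderConfig()
    p, _ = project_to_surface(start, field)
    n = smoothed_normal(field, p, 1.5 * field.node_width)
    t1, t2 = _tangent_basis(n)
    h0 = cfg.initial_edge or 2.0 * field.node_width
    floor = _edge_floor(field, cfg)
    ang = np.arange(6) * (math.pi / 3.0)
    # iterate the curvature probe at the hexagon's own scale: a probe far
    # smaller than rho*r underestimates the normal deviation on staircase
    # data, so re-estimate until the size settles (growth clamped per round)
    L = max(h0, floor)
    for _ in range(4):
        probe_dist = max(2.0 * L, 5.0 * field.node_width)
        n = smoothed_normal(field, p, 0.75 * probe_dist)
        est = probe_radius(field, p, n, probe_dist, cfg.r_min, cfg.r_max)
        L_new = min(max(rho * est.r, L / 2.0, floor), 2.0 * L)
        settled = abs(L_new - L) < 0.05 * L
        L = L_new
        if settled:
            break
    hexa = p + L * (np.cos(ang)[:, None] * t1 + np.sin(ang)[:, None] * t2)
    mesh = GrowingMesh()
    ip = mesh.add_vertex(p, n)
    ring = []
    for q in hexa:
        qp, _ = project_to_surface(q, field)
        ring.append(mesh.add_vertex(qp, smoothed_normal(field, qp, 0.75 * L)))
    for i in range(6):
        mesh.add_triangle(ip, ring[i], ring[(i + 1) % 6])
    for i in range(6):
        mesh.queue.append((ring[i], ring[(i + 1) % 6]))
    return mesh


def _vec_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    d = max(np.linalg.norm(a) * np.linalg.norm(b), 1e-300)
    return math.degrees(math.acos(np.clip(float(a @ b) / d, -1.0, 1.0)))


def _try_ear(
    mesh: GrowingMesh, field: ImplicitField, u: int, v: int,
    max_angle: float = EAR_ANGLE_DEG, min_quality: float = 20.0,
) -> bool:
    """Close an ear where two adjacent boundary edges meet at < max_angle.

    Neighbors come from the triangle-fan traversal, so ears also work at
    vertices the boundary passes through twice.  ``min_quality`` optionally
    requires a minimal interior angle (degrees) of the ear triangle, used by
    the relaxed post-rejection ear."""
    pu, pv = mesh.vertices[u], mesh.vertices[v]
    w = mesh.fan_next(u, v)
    t = mesh.fan_prev(u, v)
    candidates = []
    if w is not None and w != u:
        a = _vec_angle_deg(pu - pv, mesh.vertices[w] - pv)
        candidates.append((a, (w, v, u)))
    if t is not None and t != v:
        a = _vec_angle_deg(pv - pu, mesh.vertices[t] - pu)
        candidates.append((a, (v, u, t)))
    candidates.sort(key=lambda c: c[0])
    for a, tri in candidates:
        if a >= max_angle:
            break
        if not mesh.can_add(*tri):
            continue
        pts = mesh.triangle_points(tri)
        if min_quality > 0.0:
            sides = [pts[0] - pts[1], pts[1] - pts[2], pts[2] - pts[0]]
            min_ang = min(
                _vec_angle_deg(-sides[i], sides[(i + 1) % 3]) for i in range(3)
            )
            if min_ang < min_quality:
                continue
        tn = _tri_normal(pts)
        # guard against fold-over: the ear must face outward like the surface
        avg_n = np.mean([mesh.vertex_normals[i] for i in tri], axis=0)
        if tn @ avg_n <= 0:
            continue
        mesh.add_triangle(*tri)
        # the closing edge of the ear is the new boundary (if it stayed open)
        new_e = (tri[2], tri[0])
        if mesh.is_boundary(new_e):
            mesh.queue.append(new_e)
        return True
    return False


def _try_merge(
    mesh: GrowingMesh,
    index: _ProximityIndex,
    u: int, v: int,
    p: np.ndarray,
    L: float,
    merge_radius_factor: float = 0.6,
    min_quality: float = 25.0,
) -> bool:
    """Snap the candidate apex to a nearby boundary vertex, zipping two
    approaching mesh fronts together instead of leaving a gap.

    The snapped triangle (v, u, z) must keep the mesh manifold, face
    outward, and have a minimal interior angle of ``min_quality`` degrees.
    """
    pu, pv = mesh.vertices[u], mesh.vertices[v]
    neighborhood = {u, v}
    for a, b in ((u, v),):
        t = mesh.fan_prev(a, b)
        w = mesh.fan_next(a, b)
        if t is not None:
            neighborhood.add(t)
        if w is not None:
            neighborhood.add(w)
    best = None
    for zi in index.nearby_vertices(p, merge_radius_factor * L):
        if zi in neighborhood or not mesh.bnd_out.get(zi):
            continue
        d = float(np.linalg.norm(mesh.vertices[zi] - p))
        if best is None or d < best[0]:
            best = (d, zi)
    if best is None:
        return False
    z = best[1]
    if not mesh.can_add(v, u, z):
        return False
    pz = mesh.vertices[z]
    # z must belong to an *opposing* stretch of front: some boundary edge
    # through z runs against the direction of (u, v)
    base_dir = pv - pu
    opposing = False
    for w in mesh.bnd_out.get(z, ()):
        if (mesh.vertices[w] - pz) @ base_dir < 0:
            opposing = True
    for t in mesh.bnd_in.get(z, ()):
        if (pz - mesh.vertices[t]) @ base_dir < 0:
            opposing = True
    if not opposing:
        return False
    pts = np.array([pv, pu, pz])
    sides = [pts[0] - pts[1], pts[1] - pts[2], pts[2] - pts[0]]
    min_ang = min(_vec_angle_deg(-sides[i], sides[(i + 1) % 3]) for i in range(3))
    if min_ang < min_quality:
        return False
    n_z = mesh.vertex_normals[z]
    if (n_z @ mesh.vertex_normals[u] < 0.5
            or n_z @ mesh.vertex_normals[v] < 0.5):
        return False  # z faces a different way: not the same sheet of front
    tn = _tri_normal(pts)
    avg_n = (mesh.vertex_normals[u] + mesh.vertex_normals[v]
             + mesh.vertex_normals[z])
    if tn @ avg_n <= 0:
        return False
    exclude = neighborhood | {z}
    for w in mesh.bnd_out.get(z, ()):
        exclude.add(w)
    for t in mesh.bnd_in.get(z, ()):
        exclude.add(t)
    if not _proximity_ok(mesh, index, pts, exclude=exclude):
        return False
    mesh.add_triangle(v, u, z)
    for e in ((u, z), (z, v)):
        if mesh.is_boundary(e):
            mesh.queue.append(e)
    return True


def _place_candidate(
    mesh: GrowingMesh, field: ImplicitField, u: int, v: int,
    rho: float, cfg: ExpanderConfig, length: float | None,
):
    """Build a candidate apex opposite the existing triangle of (u, v).

    With ``length`` None the edge length adapts to the probed curvature
    (rho * r); otherwise the apex is placed at the given isoceles leg length.
    Returns (p, n_p) or None on projection failure.
    """
    pu, pv = mesh.vertices[u], mesh.vertices[v]
    ti = mesh.edge_triangle((u, v))
    tri = mesh.triangles[ti]
    q = next(x for x in tri if x not in (u, v))
    pq = mesh.vertices[q]
    mid = (pu + pv) / 2.0
    base = pv - pu
    blen = np.linalg.norm(base)
    if blen == 0:
        return None
    plane_n = _tri_normal(mesh.triangle_points(tri))
    out_dir = np.cross(base / blen, plane_n)   # in-plane, perpendicular to base
    if out_dir @ (pq - mid) > 0:
        out_dir = -out_dir
    try:
        if length is None:
            # equilateral first guess, probe curvature at its projection
            cand = mid + out_dir * (math.sqrt(3) / 2.0 * blen)
            phat, _ = project_to_surface(cand, field)
            probe_dist = max(2.0 * blen, 5.0 * field.node_width)
            nhat = smoothed_normal(field, phat, 0.75 * probe_dist)
            est = probe_radius(field, phat, nhat, probe_dist,
                               cfg.r_min, cfg.r_max)
            # triangle size must change gradually: clamp growth per step so
            # the in-plane base angles acos(blen/2L) stay in the [50,70] window
            L = min(max(rho * est.r, blen / 1.25, _edge_floor(field, cfg)),
                    1.35 * blen)
        else:
            L = length
        # isoceles apex with legs L in the original plane (base angles in
        # [50, 70] degrees by construction of the clamp above)
        h2 = L * L - 0.25 * blen * blen
        if h2 <= 0:
            return None
        cand = mid + out_dir * math.sqrt(h2)
        p, _ = project_to_surface(cand, field)
        if np.linalg.norm(p - cand) > 0.75 * L:
            REJECTS["far_projection"] += 1
            return None  # projection jumped too far: folded or stepped region
        return p, smoothed_normal(field, p, 0.75 * L)
    except ProjectionError:
        return None


def expand_step(
    mesh: GrowingMesh,
    field: ImplicitField,
    rho: float = DEFAULT_RHO,
    config: ExpanderConfig | None = None,
    index: _ProximityIndex | None = None,
) -> bool:
    """Process one queued boundary edge; returns True if a triangle was added.

    Stale queue entries (edges no longer boundary) are skipped; an edge whose
    candidates all fail is left open for the gap-stitching stage.
    """
    cfg = config or ExpanderConfig()
    index = index or _ProximityIndex(mesh)
    while mesh.queue:
        u, v = mesh.queue.popleft()
        if not mesh.is_boundary((u, v)):
            continue
        if _try_ear(mesh, field, u, v):
            return True
        pu, pv = mesh.vertices[u], mesh.vertices[v]
        blen = float(np.linalg.norm(pv - pu))
        accepted = None
        # the adaptive placement keeps the in-plane base angles inside the
        # [50, 70] window by construction; the retry falls back to an exact
        # equilateral placement when the projected triangle folds
        for length in (None, blen):
            got = _place_candidate(mesh, field, u, v, rho, cfg, length)
            if got is None:
                continue
            p, n_p = got
            # an approaching opposite front: snap to it instead of growing
            # into it (keeps gaps short and zip-closes colliding fronts)
            if _try_merge(mesh, index, u, v, p, max(blen, float(np.linalg.norm(p - pu)))):
                REJECTS["merged"] += 1
                return True
            cand_pts = np.array([pv, pu, p])
            if _tri_normal(cand_pts) @ n_p <= 0.1:
                REJECTS["folded"] += 1
                continue  # folded or strongly warped after projection
            if not _proximity_ok(mesh, index, cand_pts, exclude={u, v}):
                REJECTS["proximity"] += 1
                break  # collision: try a relaxed ear, else leave the gap
            accepted = (p, n_p)
            break
        if accepted is None:
            # last resort before deferring to the stitcher: close the wedge
            # with the adjacent boundary edge even past the 70-degree rule
            if _try_ear(mesh, field, u, v, max_angle=110.0, min_quality=25.0):
                REJECTS["relaxed_ear"] += 1
                return True
            continue  # edge stays boundary; the stitcher will close it
        p, n_p = accepted
        ipn = mesh.add_vertex(p, n_p)
        mesh.add_triangle(v, u, ipn)
        mesh.queue.append((u, ipn))
        mesh.queue.append((ipn, v))
        return True
    return False


def expand_all(
    mesh: GrowingMesh,
    field: ImplicitField,
    rho: float = DEFAULT_RHO,
    config: ExpanderConfig | None = None,
) -> GrowingMesh:
    """Run expansion until the boundary queue empties.

    Raises :class:`ExpansionCapError` (leaving the partial mesh intact) if
    the triangle cap trips, which signals a runaway rho/field combination.
    """
    cfg = config or ExpanderConfig()
    index = _ProximityIndex(mesh)
    while mesh.queue:
        if mesh.n_triangles >= cfg.max_triangles:
            raise ExpansionCapError(
                f"triangle cap {cfg.max_triangles} exceeded during expansion"
            )
        expand_step(mesh, field, rho, cfg, index)
    return mesh


def expand_surface(
    field: ImplicitField,
    cloud: OrientedPointCloud,
    rho: float = DEFAULT_RHO,
    config: ExpanderConfig | None = None,
) -> GrowingMesh:
    """Seed and expand, re-seeding in genuinely unmeshed regions until every
    sample is near the mesh, so disconnected components all get meshed.

    A re-seed is planted at the *farthest* uncovered sample and only if its
    projected hexagon stays clear of the existing mesh — samples that sit
    off the smoothed isosurface (e.g. in the crease of a vessel junction)
    would otherwise trigger hexagons on top of already-meshed surface.
    """
    cfg = config or ExpanderConfig()
    mesh: GrowingMesh | None = None
    positions = cloud.positions
    covered = np.zeros(len(positions), dtype=bool)
    centroid = positions.mean(axis=0)
    for _ in range(64):  # component cap
        remaining = np.flatnonzero(~covered)
        if len(remaining) == 0:
            break
        if mesh is None:
            order = remaining[np.argsort(
                np.linalg.norm(positions[remaining] - centroid, axis=1))]
        else:
            tree = cKDTree(mesh.vertex_array())
            dist, _ = tree.query(positions[remaining])
            edges = mesh.vertex_array()[mesh.face_array()]
            mean_edge = float(np.mean(np.linalg.norm(
                edges - np.roll(edges, 1, axis=1), axis=2)))
            near = dist <= 4.0 * mean_edge
            covered[remaining[near]] = True
            remaining = remaining[~near]
            if len(remaining) == 0:
                break
            order = remaining[np.argsort(-dist[~near])]  # farthest first
        planted = False
        for si in order[:40]:
            if mesh is not None:
                # samples that project onto already-meshed surface (e.g. in
                # the crease of a junction) must not spawn a hexagon there
                try:
                    proj, _ = project_to_surface(positions[si], field)
                except ProjectionError:
                    covered[si] = True
                    continue
                d_proj, _ = tree.query(proj)
                if d_proj <= 4.0 * mean_edge:
                    covered[si] = True
                    continue
            try:
                sub = seed_mesh(field, positions[si], rho, cfg)
            except ProjectionError:
                covered[si] = True
                continue
            if mesh is None:
                mesh = sub
                planted = True
                break
            # reject hexagons that land on already-meshed surface
            idx = _ProximityIndex(mesh)
            sub_pts = sub.vertex_array()
            clear = all(
                _proximity_ok(mesh, idx, sub_pts[list(tri)], exclude=set())
                for tri in sub.triangles
            )
            if not clear:
                covered[si] = True  # region is effectively meshed already
                continue
            offset = len(mesh.vertices)
            for pos, nrm in zip(sub.vertices, sub.vertex_normals):
                mesh.add_vertex(pos, nrm)
            for tri in sub.triangles:
                mesh.add_triangle(*(i + offset for i in tri))
            for e in sub.queue:
                mesh.queue.append((e[0] + offset, e[1] + offset))
            planted = True
            break
        if not planted:
            if mesh is None:
                raise ProjectionError("no viable seed point found")
            break
        expand_all(mesh, field, rho, cfg)
    return mesh
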