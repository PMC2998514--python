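"""Gap stitching: close the boundary loops left by mesh expansion.

The open boundary after expansion partitions into simple closed loops.  Each
loop is closed with a dynamic-programming minimum-weight triangulation over
the loop's vertex cycle, where the weight of a candidate triangle is the
lexicographic triple

    (alpha, beta, A)

with alpha the triangle's minimal interior angle (to be maximized), beta the
worst (largest) dihedral deviation against the already-fixed neighboring
triangles, and A the area.  Triples are ordered alpha-first (larger alpha is
*better*, i.e. compares smaller), then beta, then area; accumulating two
subpatches keeps the worst minimal angle, the worst dihedral, and sums the
areas.  The DP therefore produces the two-manifold triangulation of the loop
that maximizes the minimal triangle angle, breaking ties by flatness and
then by total area.

After stitching, the patch triangles are midpoint-subdivided (new vertices
projected back onto the isosurface) until their edge lengths match the
surrounding mesh density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import total_ordering

import numpy as np

from vesselmesh.expander import GrowingMesh, ProjectionError, project_to_surface
from vesselmesh.poisson import ImplicitField

log = logging.getLogger("vesselmesh.stitcher")

_TOL = 1e-9
MAX_DP_LOOP = 400
_MERGE_EPS = 1e-6


class NonSimpleBoundaryError(RuntimeError):
    """A boundary vertex has more or fewer than two incident boundary edges."""


# ---------------------------------------------------------------------------
# Weight triples
# ---------------------------------------------------------------------------

@total_ordering
@dataclass(frozen=True)
class WeightTriple:
    """Lexicographic (alpha, beta, A) triangulation weight.

    ``a < b`` means *a is the better patch*: larger minimal angle alpha
    first, then smaller worst dihedral beta, then smaller area.
    """

    alpha: float  # minimal interior angle, degrees (larger is better)
    beta: float   # worst dihedral deviation, degrees (0 = coplanar)
    area: float

    def __lt__(self, other: "WeightTriple") -> bool:
        if self.alpha > other.alpha + _TOL:
            return True
        if self.alpha < other.alpha - _TOL:
            return False
        if self.beta < other.beta - _TOL:
            return True
        if self.beta > other.beta + _TOL:
            return False
        return self.area < other.area - _TOL

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightTriple):
            return NotImplemented
        return (abs(self.alpha - other.alpha) <= _TOL
                and abs(self.beta - other.beta) <= _TOL
                and abs(self.area - other.area) <= _TOL)

    def __add__(self, other: "WeightTriple") -> "WeightTriple":
        return WeightTriple(
            min(self.alpha, other.alpha),
            max(self.beta, other.beta),
            self.area + other.area,
        )

    @classmethod
    def empty(cls) -> "WeightTriple":
        """Neutral element for degenerate (edge-only) subproblems."""
        return cls(math.inf, 0.0, 0.0)

    @classmethod
    def worst(cls) -> "WeightTriple":
        return cls(0.0, 180.0, 0.0)


def compare_weights(a: WeightTriple, b: WeightTriple) -> int:
    """-1 if a is the better weight, +1 if b, 0 on (toleranced) equality."""
    if a == b:
        return 0
    return -1 if a < b else 1


def add_weights(a: WeightTriple, b: WeightTriple) -> WeightTriple:
    return a + b


# ---------------------------------------------------------------------------
# Triangle geometry helpers
# ---------------------------------------------------------------------------

def _min_angle_area(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> tuple[float, float]:
    """(minimal interior angle in degrees, area) of a 3D triangle;
    degenerate triangles report (0, 0)."""
    e0 = p1 - p0
    e1 = p2 - p1
    e2 = p0 - p2
    l0, l1, l2 = np.linalg.norm(e0), np.linalg.norm(e1), np.linalg.norm(e2)
    if min(l0, l1, l2) == 0.0:
        return 0.0, 0.0
    cross = np.cross(e0, -e2)
    area = 0.5 * float(np.linalg.norm(cross))
    if area <= _TOL * max(l0, l1, l2) ** 2:
        return 0.0, 0.0
    angs = []
    for a, b in ((e0, -e2), (e1, -e0), (e2, -e1)):
        c = float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        angs.append(math.degrees(math.acos(max(-1.0, min(1.0, c)))))
    return min(angs), area


def _dihedral_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between consistently wound face normals; 0 means coplanar."""
    c = float(n1 @ n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def weight_of(
    i: int, k: int, j: int,
    positions: np.ndarray,
    neighbor_normals: list[np.ndarray] | None = None,
) -> WeightTriple:
    """Weight triple of candidate triangle (p_i, p_k, p_j), i < k < j.

    ``neighbor_normals`` are the unit normals of the already-fixed triangles
    adjacent to the candidate (mesh triangles on touched loop edges, plus
    the subsolution patch triangles sharing an edge); beta is the worst
    dihedral deviation against them.  Collinear triangles get the worst
    possible triple (0, 180, 0).
    """
    if not i < k < j:
        raise ValueError("weight_of requires loop indices i < k < j")
    alpha, area = _min_angle_area(positions[i], positions[k], positions[j])
    if alpha == 0.0:
        return WeightTriple.worst()
    n = _patch_normal(positions, i, k, j)
    beta = 0.0
    for nn in neighbor_normals or ():
        beta = max(beta, _dihedral_deg(n, nn))
    return WeightTriple(alpha, beta, area)


def _patch_normal(P: np.ndarray, i: int, k: int, j: int) -> np.ndarray:
    """Unit normal of patch triangle (i, k, j) in its mesh winding (j, k, i),
    which reverses the loop's boundary direction."""
    n = np.cross(P[k] - P[j], P[i] - P[j])
    ln = np.linalg.norm(n)
    return n / ln if ln > 0 else np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# Gap loops
# ---------------------------------------------------------------------------

@dataclass
class GapLoop:
    """An ordered closed cycle of boundary vertices with, per loop edge
    (a -> a+1), the unit normal of the unique existing mesh triangle."""

    vertices: list[int]
    positions: np.ndarray
    edge_normals: np.ndarray

    def __len__(self) -> int:
        return len(self.vertices)


def find_gap_loops(mesh: GrowingMesh) -> list[GapLoop]:
    """Partition the boundary edges into closed loops.

    Boundary edges are chained by triangle-fan adjacency, so a vertex the
    boundary passes through twice (created when two expansion fronts merge)
    still resolves into well-defined disjoint edge cycles.  Raises
    :class:`NonSimpleBoundaryError` when a boundary vertex has unbalanced
    incoming/outgoing boundary edges, which cannot be paired into cycles.
    """
    for u in {e[0] for e in mesh.boundary} | {e[1] for e in mesh.boundary}:
        n_out = len(mesh.bnd_out.get(u, ()))
        n_in = len(mesh.bnd_in.get(u, ()))
        if n_out != n_in or n_out == 0:
            raise NonSimpleBoundaryError(
                f"boundary vertex {u} has {n_in} incoming / {n_out} outgoing "
                "boundary edges (unpairable boundary)"
            )
    loops = []
    unvisited = set(mesh.boundary)
    while unvisited:
        start = next(iter(unvisited))
        cycle = [start[0]]
        e = start
        while True:
            unvisited.discard(e)
            v = e[1]
            nxt = mesh.fan_next(e[0], v)
            if nxt is None:
                raise NonSimpleBoundaryError(
                    f"fan traversal broke at boundary vertex {v}"
                )
            if (v, nxt) == start:
                break
            cycle.append(v)
            e = (v, nxt)
        verts = np.array([mesh.vertices[i] for i in cycle])
        normals = []
        for a in range(len(cycle)):
            edge = (cycle[a], cycle[(a + 1) % len(cycle)])
            ti = mesh.edge_triangle(edge)
            tri = mesh.triangles[ti]
            pts = mesh.triangle_points(tri)
            nrm = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            ln = np.linalg.norm(nrm)
            normals.append(nrm / ln if ln > 0 else np.array([0.0, 0.0, 1.0]))
        loops.append(GapLoop(cycle, verts, np.array(normals)))
    return loops


# ---------------------------------------------------------------------------
# DP minimum-weight triangulation
# ---------------------------------------------------------------------------

def triangulate_loop(
    positions: np.ndarray,
    edge_normals: np.ndarray | None = None,
    blocked: np.ndarray | None = None,
) -> tuple[list[tuple[int, int, int]], WeightTriple]:
    """Minimum-weight triangulation of a vertex cycle.

    Returns the n-2 triangles as loop-index triples (i, k, j) with
    i < k < j, plus the optimal total weight.  ``edge_normals[a]`` is the
    existing mesh triangle normal across loop edge (a, a+1) and feeds the
    dihedral term; when None the boundary dihedrals are skipped (free
    boundary).
    """
    P = np.asarray(positions, dtype=float)
    n = len(P)
    if n < 3:
        raise ValueError("need at least 3 loop vertices")
    has_mesh = edge_normals is not None
    N_loop = np.asarray(edge_normals, dtype=float) if has_mesh else None
    B = blocked if blocked is not None else np.zeros((n, n), dtype=bool)

    INF = math.inf
    Wa = np.full((n, n), INF)   # alpha of optimal subpatch (min over triangles)
    Wb = np.zeros((n, n))       # beta
    Ws = np.zeros((n, n))       # area
    O = np.full((n, n), -1, dtype=int)
    TN = np.zeros((n, n, 3))    # normal of the triangle chosen for cell (i, k)
    if has_mesh:
        for i in range(n - 1):
            TN[i, i + 1] = N_loop[i]

    # span-2 cells: single triangle (i, i+1, i+2)
    for i in range(n - 2):
        k = i + 2
        alpha, area = _min_angle_area(P[i], P[i + 1], P[k])
        nrm = _patch_normal(P, i, i + 1, k)
        beta = 0.0
        if has_mesh:
            beta = max(_dihedral_deg(nrm, N_loop[i]), _dihedral_deg(nrm, N_loop[i + 1]))
        if alpha == 0.0 or B[i, k] or B[i, i + 1] or B[i + 1, k]:
            alpha, beta, area = 0.0, 180.0, 0.0
        Wa[i, k], Wb[i, k], Ws[i, k] = alpha, beta, area
        O[i, k] = i + 1
        TN[i, k] = nrm

    for span in range(3, n):
        for i in range(n - span):
            k = i + span
            m = np.arange(i + 1, k)
            # candidate triangle (i, m, k) geometry, vectorized over m
            e0 = P[m] - P[i]
            e1 = P[k] - P[m]
            e2 = P[i] - P[k]
            l0 = np.linalg.norm(e0, axis=1)
            l1 = np.linalg.norm(e1, axis=1)
            cross = np.cross(e0, -np.broadcast_to(e2, e0.shape))
            cln = np.linalg.norm(cross, axis=1)
            area = 0.5 * cln
            l2 = np.linalg.norm(e2)
            with np.errstate(invalid="ignore", divide="ignore"):
                ca = np.clip(np.einsum("ij,ij->i", e0, -np.broadcast_to(e2, e0.shape)) / (l0 * l2), -1, 1)
                cb = np.clip(np.einsum("ij,ij->i", e1, -e0) / (l1 * l0), -1, 1)
                cc = np.clip(np.einsum("ij,ij->i", np.broadcast_to(e2, e1.shape), -e1) / (l2 * l1), -1, 1)
                angs = np.degrees(np.arccos(np.stack([ca, cb, cc], axis=1)))
            alpha = np.min(np.nan_to_num(angs, nan=0.0), axis=1)
            degen = (np.minimum(np.minimum(l0, l1), l2) == 0) | (
                area <= _TOL * np.maximum(np.maximum(l0, l1), l2) ** 2)
            # winding (k, m, i): normal = (P[m]-P[k]) x (P[i]-P[k])
            nrm = np.cross(P[m] - P[k], np.broadcast_to(P[i] - P[k], e0.shape))
            nln = np.linalg.norm(nrm, axis=1)
            nrm = np.where(nln[:, None] > 0, nrm / np.maximum(nln, 1e-300)[:, None], nrm)
            beta = np.zeros(len(m))
            if has_mesh:
                left = TN[i, m]          # triangle fixed across edge (i, m)
                right = TN[m, k]         # triangle fixed across edge (m, k)
                for other in (left, right):
                    d = np.degrees(np.arccos(np.clip(
                        np.einsum("ij,ij->i", nrm, other), -1, 1)))
                    beta = np.maximum(beta, d)
                if i == 0 and k == n - 1:
                    # top cell: the span edge is the loop edge (n-1 -> 0)
                    d = np.degrees(np.arccos(np.clip(nrm @ N_loop[n - 1], -1, 1)))
                    beta = np.maximum(beta, d)
            bad = degen | B[i, m] | B[m, k] | B[i, k]
            alpha = np.where(bad, 0.0, alpha)
            beta = np.where(bad, 180.0, beta)
            area = np.where(bad, 0.0, area)
            # accumulate with the subsolutions (Eq. 8 semantics)
            tot_a = np.minimum(np.minimum(Wa[i, m], Wa[m, k]), alpha)
            tot_b = np.maximum(np.maximum(Wb[i, m], Wb[m, k]), beta)
            tot_s = Ws[i, m] + Ws[m, k] + area
            # lexicographic argmin with 1e-9 tolerance, smallest m on ties
            cand = np.flatnonzero(tot_a >= np.max(tot_a) - _TOL)
            if len(cand) > 1:
                cand = cand[tot_b[cand] <= np.min(tot_b[cand]) + _TOL]
            if len(cand) > 1:
                cand = cand[tot_s[cand] <= np.min(tot_s[cand]) + _TOL]
            best = int(cand[0])
            Wa[i, k], Wb[i, k], Ws[i, k] = tot_a[best], tot_b[best], tot_s[best]
            O[i, k] = int(m[best])
            TN[i, k] = nrm[best]

    tris: list[tuple[int, int, int]] = []

    def trace(i: int, k: int) -> None:
        if i + 2 == k:
            tris.append((i, i + 1, k))
            return
        o = O[i, k]
        if o != i + 1:
            trace(i, o)
        tris.append((i, o, k))
        if o != k - 1:
            trace(o, k)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, n + 100))
    try:
        trace(0, n - 1)
    finally:
        sys.setrecursionlimit(old)
    return tris, WeightTriple(float(Wa[0, n - 1]), float(Wb[0, n - 1]), float(Ws[0, n - 1]))


# ---------------------------------------------------------------------------
# Loop preprocessing: degenerate cleanup and long-loop splitting
# ---------------------------------------------------------------------------

def _clean_loop(loop: GapLoop) -> GapLoop:
    """Merge consecutive coincident vertices (< 1e-6 apart)."""
    keep = []
    n = len(loop)
    for a in range(n):
        nxt = (a + 1) % n
        if np.linalg.norm(loop.positions[a] - loop.positions[nxt]) >= _MERGE_EPS:
            keep.append(a)
    if len(keep) == n:
        return loop
    return GapLoop(
        [loop.vertices[a] for a in keep],
        loop.positions[keep],
        loop.edge_normals[keep],
    )


def _split_indices(P: np.ndarray) -> tuple[int, int]:
    """Closest non-adjacent vertex pair of a cycle (world distance)."""
    n = len(P)
    best = (math.inf, 0, 2)
    for a in range(n - 2):
        lo = a + 2
        hi = n - 1 if a == 0 else n
        if lo >= hi:
            continue
        d = np.linalg.norm(P[lo:hi] - P[a], axis=1)
        b = int(np.argmin(d))
        if d[b] < best[0]:
            best = (float(d[b]), a, lo + b)
    return best[1], best[2]


def _triangulate_general(
    positions: np.ndarray, edge_normals: np.ndarray,
    blocked: np.ndarray | None = None,
) -> list[tuple[int, int, int]]:
    """DP triangulation with recursive pre-splitting of very long loops,
    keeping the cubic DP desk-scale."""
    n = len(positions)
    if n <= MAX_DP_LOOP:
        tris, _ = triangulate_loop(positions, edge_normals, blocked)
        return tris
    a, b = _split_indices(positions)
    idx1 = list(range(a, b + 1))
    idx2 = list(range(b, n)) + list(range(0, a + 1))
    out: list[tuple[int, int, int]] = []
    for idx in (idx1, idx2):
        sub_pos = positions[idx]
        # the split edge has no fixed mesh triangle; reuse the adjacent
        # loop-edge normal as its dihedral reference
        sub_nrm = np.array([
            edge_normals[idx[t]] if (idx[t] + 1) % n == idx[(t + 1) % len(idx)]
            else edge_normals[idx[t] % n]
            for t in range(len(idx))
        ])
        sub_blocked = blocked[np.ix_(idx, idx)] if blocked is not None else None
        sub_tris = _triangulate_general(sub_pos, sub_nrm, sub_blocked)
        out.extend(tuple(idx[t] for t in tri) for tri in sub_tris)
    return out


# ---------------------------------------------------------------------------
# Patch subdivision and stitching driver
# ---------------------------------------------------------------------------

def _longest_edge_of(mesh: GrowingMesh, ti: int) -> tuple[tuple[int, int], float]:
    tri = mesh.triangles[ti]
    best, best_len = None, -1.0
    for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
        length = float(np.linalg.norm(mesh.vertices[e[0]] - mesh.vertices[e[1]]))
        if length > best_len:
            best, best_len = e, length
    return best, best_len


def _bisect_edge(
    mesh: GrowingMesh, u: int, v: int, field: ImplicitField | None,
    patch: set[int],
) -> bool:
    """Split edge (u, v) at its (surface-projected) midpoint, 1-2 splitting
    both adjacent triangles; children inherit patch membership."""
    t1 = mesh.directed.get((u, v))
    t2 = mesh.directed.get((v, u))
    if t1 is None:
        return False
    mid = (mesh.vertices[u] + mesh.vertices[v]) / 2.0
    nrm = (mesh.vertex_normals[u] + mesh.vertex_normals[v]) / 2.0
    if field is not None:
        try:
            mid, nrm = project_to_surface(mid, field)
        except ProjectionError:
            return False  # keep the flat edge rather than a bad midpoint
    a = next(x for x in mesh.triangles[t1] if x not in (u, v))
    in_patch_1 = t1 in patch
    in_patch_2 = t2 in patch if t2 is not None else False
    b = next(x for x in mesh.triangles[t2] if x not in (u, v)) if t2 is not None else None
    mesh.remove_triangle(t1)
    patch.discard(t1)
    if t2 is not None:
        mesh.remove_triangle(t2)
        patch.discard(t2)
    m = mesh.add_vertex(mid, nrm)
    new1 = [mesh.add_triangle(u, m, a), mesh.add_triangle(m, v, a)]
    if in_patch_1:
        patch.update(new1)
    if t2 is not None:
        new2 = [mesh.add_triangle(v, m, b), mesh.add_triangle(m, u, b)]
        if in_patch_2:
            patch.update(new2)
    return True


def subdivide_patch(
    mesh: GrowingMesh,
    patch: set[int],
    field: ImplicitField,
    target_edge: float,
    max_splits: int | None = None,
) -> set[int]:
    """Refine patch triangles to the surrounding mesh density by
    longest-edge bisection, projecting new vertices onto the isosurface.

    Always bisecting the *longest* edge of the pair (propagating to the
    neighbor when its longest edge differs, as in Rivara refinement) keeps
    the children's angles bounded, so refinement cannot degrade a patch
    into needles.  Edges at or below 1.5x the surrounding edge length are
    left alone."""
    threshold = 1.5 * target_edge
    if max_splits is None:
        max_splits = 20 * max(len(patch), 1) + 100
    splits = 0
    while splits < max_splits:
        work = None
        for ti in patch:
            if mesh.triangles[ti] is None:
                continue
            e, length = _longest_edge_of(mesh, ti)
            if length > threshold:
                work = ti
                break
        if work is None:
            break
        # propagate to the longest-edge-compatible neighbor chain
        chain_guard = 0
        ti = work
        while chain_guard < 64:
            chain_guard += 1
            e, length = _longest_edge_of(mesh, ti)
            tn = mesh.directed.get((e[1], e[0]))
            if tn is None:
                break
            en, _ = _longest_edge_of(mesh, tn)
            if frozenset(en) == frozenset(e):
                break
            ti = tn  # neighbor's longest edge must split first
        e, _ = _longest_edge_of(mesh, ti)
        if not _bisect_edge(mesh, e[0], e[1], field, patch):
            break
        splits += 1
    patch = {t for t in patch if mesh.triangles[t] is not None}
    return patch


def _blocked_chords(mesh: GrowingMesh, loop: GapLoop) -> np.ndarray:
    """Chords of the loop already occupied by mesh edges elsewhere; using
    them in a patch would create a non-manifold or duplicated edge."""
    n = len(loop)
    B = np.zeros((n, n), dtype=bool)
    verts = loop.vertices
    for a in range(n):
        for b in range(a + 2, n):
            if a == 0 and b == n - 1:
                continue  # the closing loop edge, not a chord
            if (verts[a] == verts[b]
                    or (verts[a], verts[b]) in mesh.directed
                    or (verts[b], verts[a]) in mesh.directed):
                B[a, b] = B[b, a] = True
    return B


def stitch_loop(
    mesh: GrowingMesh, loop: GapLoop, field: ImplicitField | None = None,
    subdivide: bool = True,
) -> set[int]:
    """Triangulate one gap loop and glue the patch into the mesh."""
    loop = _clean_loop(loop)
    n = len(loop)
    if n < 3:
        return set()
    edge_lengths = np.linalg.norm(
        loop.positions - np.roll(loop.positions, -1, axis=0), axis=1)
    blocked = _blocked_chords(mesh, loop)
    tris = _triangulate_general(loop.positions, loop.edge_normals, blocked)
    patch: set[int] = set()
    for i, k, j in tris:
        a, b, c = loop.vertices[j], loop.vertices[k], loop.vertices[i]
        if mesh.can_add(a, b, c):
            patch.add(mesh.add_triangle(a, b, c))
        else:
            log.debug("patch triangle (%d,%d,%d) skipped: chord already "
                      "occupied; deferring to the cleanup passes", a, b, c)
    if subdivide and field is not None and patch:
        patch = subdivide_patch(mesh, patch, field, float(edge_lengths.mean()))
    return patch


def _greedy_close(mesh: GrowingMesh, loop: GapLoop) -> int:
    """Fallback hole closure by ear clipping with the best addable ear
    (maximal minimal angle), used where the DP patch could not be glued
    (chords already occupied by mesh edges).  Returns triangles added."""
    verts = list(loop.vertices)
    added = 0
    while len(verts) >= 3:
        n = len(verts)
        best = None
        for a in range(n):
            i, k, j = verts[a], verts[(a + 1) % n], verts[(a + 2) % n]
            if len({i, k, j}) < 3 or not mesh.can_add(j, k, i):
                continue
            alpha, _ = _min_angle_area(
                np.asarray(mesh.vertices[i]),
                np.asarray(mesh.vertices[k]),
                np.asarray(mesh.vertices[j]))
            if best is None or alpha > best[0]:
                best = (alpha, a)
        if best is None:
            log.debug("greedy closure stalled with %d open vertices", n)
            break
        a = best[1]
        i, k, j = verts[a], verts[(a + 1) % n], verts[(a + 2) % n]
        mesh.add_triangle(j, k, i)
        added += 1
        verts.pop((a + 1) % n)
    return added


def _fan_close(mesh: GrowingMesh, loop: GapLoop, field: ImplicitField | None) -> int:
    """Close a loop unconditionally by fanning to a fresh center vertex
    (projected to the isosurface when possible).  New-vertex edges cannot
    collide with existing ones, so this always succeeds."""
    center = loop.positions.mean(axis=0)
    normal = loop.edge_normals.mean(axis=0)
    nl = np.linalg.norm(normal)
    normal = normal / nl if nl > 0 else np.array([0.0, 0.0, 1.0])
    if field is not None:
        try:
            center, normal = project_to_surface(center, field)
        except ProjectionError:
            pass
    c = mesh.add_vertex(center, normal)
    n = len(loop)
    added = 0
    for a in range(n):
        i, j = loop.vertices[a], loop.vertices[(a + 1) % n]
        if mesh.can_add(j, i, c):
            mesh.add_triangle(j, i, c)
            added += 1
    return added


def repair_pinched_vertices(mesh: GrowingMesh) -> int:
    """Split vertices whose incident triangles form more than one
    edge-connected fan (created where independently zipped seams meet).

    Each extra fan gets a duplicate vertex at the same position, restoring
    vertex-manifoldness without moving any geometry.  Returns the number of
    splits performed.
    """
    splits = 0
    for v in range(len(mesh.vertices)):
        tris = [t for t in mesh.incident.get(v, ()) if mesh.triangles[t] is not None]
        if len(tris) < 2:
            continue
        # group the triangles into fans connected via shared edges through v
        parent = {t: t for t in tris}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        by_other: dict[int, list[int]] = {}
        for t in tris:
            for o in mesh.triangles[t]:
                if o != v:
                    by_other.setdefault(o, []).append(t)
        for ts in by_other.values():
            for t2 in ts[1:]:
                parent[find(ts[0])] = find(t2)
        fans: dict[int, list[int]] = {}
        for t in tris:
            fans.setdefault(find(t), []).append(t)
        if len(fans) <= 1:
            continue
        for fan in list(fans.values())[1:]:
            dup = mesh.add_vertex(mesh.vertices[v], mesh.vertex_normals[v])
            for t in fan:
                tri = mesh.triangles[t]
                mesh.remove_triangle(t)
                mesh.add_triangle(*(dup if x == v else x for x in tri))
            splits += 1
    return splits


def stitch_all(
    mesh: GrowingMesh, field: ImplicitField | None = None, subdivide: bool = True,
) -> int:
    """Close every gap loop; returns the number of patch triangles added.

    Loops whose DP patch cannot be fully glued (some chords were already
    mesh edges) leave residual holes; a greedy ear pass closes most of
    those, and a center-vertex fan closes whatever remains.  Pinched
    vertices left by seam zipping are split at the end, so a successful
    stitch yields a closed vertex- and edge-manifold surface.
    """
    total = 0
    for loop in find_gap_loops(mesh):
        total += len(stitch_loop(mesh, loop, field, subdivide))
    for _ in range(3):
        if not mesh.boundary:
            break
        for loop in find_gap_loops(mesh):
            total += _greedy_close(mesh, loop)
    if mesh.boundary:
        for loop in find_gap_loops(mesh):
            total += _fan_close(mesh, loop, field)
    repair_pinched_vertices(mesh)
    return total
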