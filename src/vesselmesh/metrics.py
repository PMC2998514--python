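"""Mesh quality, smoothness, accuracy, and topology metrics.

Four families of measures evaluate a reconstructed surface:

* **edge ratio** tau = (min edge length)/(max edge length) per triangle —
  1 for an equilateral triangle, approaching 0 for a needle; reported as a
  decile histogram plus the fractions above/below thresholds of interest;
* **RMS curvature** sqrt((k_max^2 + k_min^2)/2) per vertex from a local
  quadric fit, a smoothness map (a rasterization-faithful surface is smooth
  except where the data itself bends);
* **surface distance** between a mesh and a reference (another mesh or an
  analytic shape): mean/max/RMS over pooled symmetric point samples, the
  sampled Hausdorff-style comparison used for accuracy claims;
* **topology**: Euler characteristic, connected components, boundary
  edges, and manifoldness (edge- and vertex-level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from vesselmesh.volume import AnalyticShape

TAU_GOOD = 0.8
TAU_BAD = 0.3


# ---------------------------------------------------------------------------
# Edge ratio
# ---------------------------------------------------------------------------

def edge_ratio(triangle: np.ndarray) -> float:
    """tau = shortest edge / longest edge of a single 3D triangle."""
    t = np.asarray(triangle, dtype=float)
    lengths = np.linalg.norm(t - np.roll(t, -1, axis=0), axis=1)
    if lengths.max() == 0:
        raise ValueError("degenerate triangle with zero-length edges")
    return float(lengths.min() / lengths.max())


def edge_ratios(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Vectorized tau for every triangle of a mesh."""
    E = V[F]
    lengths = np.linalg.norm(E - np.roll(E, -1, axis=1), axis=2)
    return lengths.min(axis=1) / lengths.max(axis=1)


def edge_ratio_histogram(taus: np.ndarray) -> list[int]:
    """Counts over the decile bins [0,0.1), ..., [0.9, 1.0]."""
    bins = np.minimum((np.asarray(taus) * 10).astype(int), 9)
    return np.bincount(bins, minlength=10).tolist()


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

def _vertex_normals(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    fn = np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]])
    vn = np.zeros_like(V)
    for i in range(3):
        np.add.at(vn, F[:, i], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    return vn / np.maximum(norms, 1e-300)


def _vertex_rings(F: np.ndarray, n: int) -> list[set[int]]:
    rings: list[set[int]] = [set() for _ in range(n)]
    for f in F:
        for i in range(3):
            rings[f[i]].add(int(f[(i + 1) % 3]))
            rings[f[i]].add(int(f[(i + 2) % 3]))
    return rings


def rms_curvature(
    V: np.ndarray, F: np.ndarray, vertex: int,
    rings: list[set[int]] | None = None,
    normals: np.ndarray | None = None,
) -> tuple[float, bool]:
    """RMS of the principal curvatures at one vertex, from a quadric fit
    over its 1-ring (2-ring when the 1-ring is too small).

    Fits z = a x^2 + b xy + c y^2 + d x + e y in the local normal frame and
    takes the shape operator of the graph at the origin.  Returns
    (sqrt((k_max^2 + k_min^2)/2), ok); a rank-deficient neighborhood gives
    (0.0, False).
    """
    if rings is None:
        rings = _vertex_rings(F, len(V))
    if normals is None:
        normals = _vertex_normals(V, F)
    nbrs = set(rings[vertex])
    if len(nbrs) < 5:
        for x in list(nbrs):
            nbrs |= rings[x]
        nbrs.discard(vertex)
    if len(nbrs) < 5:
        return 0.0, False
    n = normals[vertex]
    a_ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(a_ref, n)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    rel = V[sorted(nbrs)] - V[vertex]
    x = rel @ t1
    y = rel @ t2
    z = rel @ n
    A = np.stack([x * x, x * y, y * y, x, y], axis=1)
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < 5:
        return 0.0, False
    a, b, c, d, e = coef
    # first/second fundamental forms of the graph z(x, y) at the origin
    E1 = 1 + d * d
    F1 = d * e
    G1 = 1 + e * e
    w = np.sqrt(1 + d * d + e * e)
    L = 2 * a / w
    M = b / w
    N = 2 * c / w
    shape_op = np.linalg.solve(np.array([[E1, F1], [F1, G1]]),
                               np.array([[L, M], [M, N]]))
    k1, k2 = np.linalg.eigvals(shape_op).real
    return float(np.sqrt((k1 * k1 + k2 * k2) / 2.0)), True


def rms_curvature_map(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Per-vertex RMS curvature for the whole mesh."""
    rings = _vertex_rings(F, len(V))
    normals = _vertex_normals(V, F)
    out = np.zeros(len(V))
    for v in range(len(V)):
        out[v], _ = rms_curvature(V, F, v, rings, normals)
    return out


# ---------------------------------------------------------------------------
# Surface distance
# ---------------------------------------------------------------------------

def sample_mesh_surface(
    V: np.ndarray, F: np.ndarray, samples_per_triangle: int = 10,
) -> np.ndarray:
    """All vertices plus a fixed barycentric lattice per triangle
    (deterministic, so repeated measurements agree exactly)."""
    pts = [V]
    if samples_per_triangle > 0:
        bary = _barycentric_lattice(samples_per_triangle)
        E = V[F]  # (m, 3, 3)
        for w in bary:
            pts.append(np.einsum("i,mij->mj", w, E))
    return np.concatenate(pts)


def _barycentric_lattice(k: int) -> np.ndarray:
    """At least k interior barycentric weights, as the *nested* union of
    regular lattices of increasing level.  Nesting makes the sample set grow
    monotonically with k, so a refined sampling can never lose an extremum
    already seen at a coarser one (the measured max distance is monotone)."""
    out: list[tuple[float, float, float]] = []
    seen: set[tuple[float, float, float]] = set()
    level = 3
    while len(out) < k:
        for i in range(1, level):
            for j in range(1, level - i):
                w = (i / level, j / level, (level - i - j) / level)
                if w not in seen:
                    seen.add(w)
                    out.append(w)
        level += 1
    return np.array(out)


def _point_triangles_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from one point to each triangle in ``tri`` (k, 3, 3),
    via the standard region classification of the closest point."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    eps = 1e-300
    t_ab = np.clip(d1 / np.where(d1 - d3 == 0, eps, d1 - d3), 0, 1)
    t_ac = np.clip(d2 / np.where(d2 - d6 == 0, eps, d2 - d6), 0, 1)
    t_bc = np.clip((d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, eps,
                                        (d4 - d3) + (d5 - d6)), 0, 1)
    denom = np.where(va + vb + vc == 0, eps, va + vb + vc)
    v = vb / denom
    w = vc / denom
    inside = a + v[:, None] * ab + w[:, None] * ac
    closest = inside
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[:, None], b + t_bc[:, None] * (c - b), closest)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[:, None], a + t_ac[:, None] * ac, closest)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[:, None], a + t_ab[:, None] * ab, closest)
    at_c = (d6 >= 0) & (d5 <= d6)
    closest = np.where(at_c[:, None], c, closest)
    at_b = (d3 >= 0) & (d4 <= d3)
    closest = np.where(at_b[:, None], b, closest)
    at_a = (d1 <= 0) & (d2 <= 0)
    closest = np.where(at_a[:, None], a, closest)
    return np.linalg.norm(p - closest, axis=1)


def _distance_to_mesh(points: np.ndarray, V: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Exact point-to-mesh distances: a KD-tree over triangle centroids
    prunes candidates (any triangle whose centroid is farther than the best
    centroid distance plus the largest circumradius cannot be closest), and
    the exact point-triangle distance decides among the survivors."""
    tri = V[F]  # (k, 3, 3)
    centroids = tri.mean(axis=1)
    circum = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    slack = float(circum.max())
    tree = cKDTree(centroids)
    d1, _ = tree.query(points)
    out = np.empty(len(points))
    for i, p in enumerate(np.asarray(points, dtype=float)):
        cand = tree.query_ball_point(p, d1[i] + slack + 1e-12)
        out[i] = _point_triangles_distance(p, tri[cand]).min()
    return out


def surface_distance(
    mesh: tuple[np.ndarray, np.ndarray],
    reference,
    samples_per_triangle: int = 10,
    n_reference_samples: int = 4000,
) -> tuple[float, float, float]:
    """Symmetric sampled surface distance (mean, max, RMS).

    ``reference`` is either another ``(V, F)`` mesh or an
    :class:`AnalyticShape`.  Points are sampled on both surfaces; each
    directed distance set is pooled before taking the statistics, giving the
    sampled Hausdorff-style comparison (max over the pool approaches the
    true Hausdorff distance as sampling is refined).
    """
    V, F = mesh
    if len(V) == 0 or len(F) == 0:
        raise ValueError("empty mesh")
    pts_a = sample_mesh_surface(V, F, samples_per_triangle)
    if isinstance(reference, AnalyticShape):
        d_ab = np.abs(reference.signed_distance(pts_a))
        pts_b = reference.surface_samples(n_reference_samples)
        d_ba = _distance_to_mesh(pts_b, V, F)
    else:
        Vr, Fr = reference
        d_ab = _distance_to_mesh(pts_a, Vr, Fr)
        pts_b = sample_mesh_surface(Vr, Fr, samples_per_triangle)
        d_ba = _distance_to_mesh(pts_b, V, F)
    pooled = np.concatenate([d_ab, d_ba])
    return (
        float(pooled.mean()),
        float(pooled.max()),
        float(np.sqrt(np.mean(pooled**2))),
    )


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def topology_report(V: np.ndarray, F: np.ndarray) -> dict:
    """Euler characteristic, components, boundary edges, and manifoldness.

    Vertices never referenced by a face are ignored.  ``manifold`` requires
    every edge to border at most two faces *and* every vertex's incident
    faces to form a single edge-connected fan; ``oriented`` requires each
    interior edge's two directed occurrences to be opposite.
    """
    F = np.asarray(F, dtype=int)
    if len(F) == 0:
        return {
            "euler": 0, "components": 0, "boundary_edges": 0,
            "manifold": False, "oriented": False,
            "vertices": 0, "edges": 0, "faces": 0,
        }
    edge_count: dict[frozenset, int] = {}
    directed: dict[tuple[int, int], int] = {}
    oriented = True
    for f in F:
        for i in range(3):
            e = (int(f[i]), int(f[(i + 1) % 3]))
            key = frozenset(e)
            edge_count[key] = edge_count.get(key, 0) + 1
            if e in directed:
                oriented = False
            directed[e] = directed.get(e, 0) + 1
    used = np.unique(F)
    n_edges = len(edge_count)
    boundary_edges = sum(1 for c in edge_count.values() if c == 1)
    edge_manifold = all(c <= 2 for c in edge_count.values())

    # face components via union-find over shared edges
    parent = list(range(len(F)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edge_faces: dict[frozenset, list[int]] = {}
    for ti, f in enumerate(F):
        for i in range(3):
            key = frozenset((int(f[i]), int(f[(i + 1) % 3])))
            edge_faces.setdefault(key, []).append(ti)
    for faces_on_edge in edge_faces.values():
        for t2 in faces_on_edge[1:]:
            parent[find(faces_on_edge[0])] = find(t2)
    components = len({find(t) for t in range(len(F))})

    # vertex fans
    vertex_faces: dict[int, list[int]] = {}
    for ti, f in enumerate(F):
        for v in f:
            vertex_faces.setdefault(int(v), []).append(ti)
    vertex_manifold = True
    for v, tris in vertex_faces.items():
        vp = {t: t for t in tris}

        def vfind(x):
            while vp[x] != x:
                vp[x] = vp[vp[x]]
                x = vp[x]
            return x

        by_other: dict[int, list[int]] = {}
        for t in tris:
            for o in F[t]:
                if o != v:
                    by_other.setdefault(int(o), []).append(t)
        for ts in by_other.values():
            for t2 in ts[1:]:
                vp[vfind(ts[0])] = vfind(t2)
        if len({vfind(t) for t in tris}) > 1:
            vertex_manifold = False
            break

    return {
        "euler": int(len(used) - n_edges + len(F)),
        "components": components,
        "boundary_edges": boundary_edges,
        "manifold": bool(edge_manifold and vertex_manifold),
        "oriented": bool(oriented and edge_manifold),
        "vertices": int(len(used)),
        "edges": n_edges,
        "faces": int(len(F)),
    }


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

@dataclass
class QualityReport:
    """Everything the pipeline reports about a final mesh."""

    n_vertices: int
    n_triangles: int
    edge_ratio_histogram: list[int]
    fraction_tau_atleast_08: float
    fraction_tau_below_03: float
    mean_edge_length: float
    topology: dict
    distance_stats: dict | None = None
    curvature_summary: dict | None = None
    parameters: dict = field(default_factory=dict)

    def fraction_below(self, tau0: float, taus: np.ndarray | None = None) -> float:
        hist = np.asarray(self.edge_ratio_histogram)
        full = int(tau0 * 10)
        return float(hist[:full].sum() / max(hist.sum(), 1))

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def quality_report(
    V: np.ndarray,
    F: np.ndarray,
    reference=None,
    with_curvature: bool = False,
    samples_per_triangle: int = 10,
    parameters: dict | None = None,
) -> QualityReport:
    """Assemble the full quality report for a mesh (optionally measured
    against a reference surface and with the per-vertex curvature map)."""
    taus = edge_ratios(V, F)
    E = V[F]
    lengths = np.linalg.norm(E - np.roll(E, -1, axis=1), axis=2)
    report = QualityReport(
        n_vertices=int(len(np.unique(F))),
        n_triangles=int(len(F)),
        edge_ratio_histogram=edge_ratio_histogram(taus),
        fraction_tau_atleast_08=float((taus >= TAU_GOOD).mean()),
        fraction_tau_below_03=float((taus < TAU_BAD).mean()),
        mean_edge_length=float(lengths.mean()),
        topology=topology_report(V, F),
        parameters=parameters or {},
    )
    if reference is not None:
        mean, mx, rms = surface_distance(
            (V, F), reference, samples_per_triangle=samples_per_triangle)
        report.distance_stats = {"mean": mean, "max": mx, "rms": rms}
    if with_curvature:
        curv = rms_curvature_map(V, F)
        report.curvature_summary = {
            "mean": float(curv.mean()),
            "median": float(np.median(curv)),
            "p95": float(np.percentile(curv, 95)),
        }
    return report
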