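"""Inward-facing normal estimation for the extracted point cloud.

For each sample the covariance matrix of its k nearest neighbors is formed
about the neighbor centroid; the eigenvector of the smallest eigenvalue is
the (unoriented) surface normal.  Orientation is resolved locally: every
sample knows the object voxel that generated it, and the normal's sign is
chosen to point from the sample toward that voxel's center — into the
vessel — which is the convention the Poisson stage expects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from vesselmesh.points import PointArrays
from vesselmesh.volume import BinaryVolume

DEFAULT_K = 10

_AXIS_UNIT = np.eye(3)


@dataclass
class OrientedPointCloud:
    """World-space points with inward-facing unit normals."""

    positions: np.ndarray  # (n, 3)
    normals: np.ndarray    # (n, 3), unit length, pointing into the object
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.positions.shape != self.normals.shape:
            raise ValueError("positions and normals must have the same shape")

    def __len__(self) -> int:
        return len(self.positions)


def knn(positions: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest Euclidean neighbors of each point, excluding
    the point itself (a duplicate position still excludes only the query's
    own row); ties broken by index order.  Returns an (n, k) int array."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    tree = cKDTree(positions)
    # query k+1 since the point itself is always returned at distance 0
    dist, idx = tree.query(positions, k=k + 1)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i][idx[i] != i]
        if len(row) >= k:
            out[i] = row[:k]
        else:  # exact-duplicate positions: self may not be in the k+1 set
            out[i] = np.concatenate([row, idx[i][-(k - len(row)):]])
    return out


def covariance_normal(p: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Unoriented unit normal at ``p``: the eigenvector of the neighbors'
    covariance matrix (about the neighbor centroid) with smallest eigenvalue.

    Raises for fewer than 3 neighbors or a neighborhood that is collinear or
    collapsed (two vanishing eigenvalues leave the normal undefined).
    """
    neighbors = np.asarray(neighbors, dtype=float)
    if neighbors.ndim != 2 or len(neighbors) < 3:
        raise ValueError("need at least 3 neighbors for a covariance normal")
    centered = neighbors - neighbors.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    scale = float(np.sum(np.square(centered)))
    if scale <= 0 or evals[1] <= 1e-12 * scale:
        raise ValueError("degenerate neighborhood: normal direction undefined")
    return evecs[:, 0]


def estimate_normals(positions: np.ndarray, k: int = DEFAULT_K) -> np.ndarray:
    """Unoriented covariance normals for a whole cloud (vectorized)."""
    positions = np.asarray(positions, dtype=float)
    nbr = positions[knn(positions, k)]            # (n, k, 3)
    centered = nbr - nbr.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    evals, evecs = np.linalg.eigh(cov)
    normals = evecs[:, :, 0]
    scale = np.einsum("nki,nki->n", centered, centered)
    bad = evals[:, 1] <= 1e-12 * scale
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} samples have degenerate (collinear) neighborhoods"
        )
    return normals


def orient_normals(
    points: PointArrays, raw_normals: np.ndarray, vol: BinaryVolume
) -> OrientedPointCloud:
    """Flip each normal so it points from the sample toward its source object
    voxel's center (inward).  A normal exactly orthogonal to that direction
    falls back to the face's inward axis."""
    raw_normals = np.asarray(raw_normals, dtype=float)
    norms = np.linalg.norm(raw_normals, axis=1, keepdims=True)
    normals = raw_normals / norms
    inward = vol.index_to_world(points.source_voxels) - points.positions
    dots = np.einsum("ni,ni->n", normals, inward)
    # tie-break exact zeros with the face-inward axis (-face_sign along face_axis)
    face_inward = -points.face_signs[:, None] * _AXIS_UNIT[points.face_axes]
    tie = dots == 0.0
    if np.any(tie):
        dots = np.where(
            tie, np.einsum("ni,ni->n", normals, face_inward), dots
        )
    normals = np.where(dots[:, None] < 0, -normals, normals)
    return OrientedPointCloud(points.positions.copy(), normals)


def build_oriented_cloud(
    points: PointArrays, vol: BinaryVolume, k: int = DEFAULT_K
) -> OrientedPointCloud:
    """Estimate and orient normals for extracted boundary samples."""
    raw = estimate_normals(points.positions, k=k)
    cloud = orient_normals(points, raw, vol)
    cloud.k = k
    return cloud
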