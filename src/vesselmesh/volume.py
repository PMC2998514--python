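"""Binary segmentation volumes, analytic phantoms, and mesh/volume I/O.

The pipeline input is a 3D occupancy grid (1 = vessel, 0 = background) with
anisotropic voxel spacing.  The world convention, shared by every module, is

    world = origin + index * spacing

with 0-based indices and voxel centers at integer indices; ``grid[i, j, k]``
indexes world axes (x, y, z) in that order.

Phantoms are analytic shapes with exact signed-distance functions (negative
inside).  Rasterizing one gives a :class:`BinaryVolume` whose ground-truth
surface is known in closed form, so every downstream stage can be validated
without clinical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh


class VolumeError(ValueError):
    """Raised for malformed or empty segmentation volumes."""


# --------------------------------------------------------------------------
# BinaryVolume
# --------------------------------------------------------------------------

@dataclass
class BinaryVolume:
    """3D occupancy grid with voxel spacing and world origin.

    Parameters
    ----------
    grid
        3D uint8 array of {0, 1}.  A one-voxel layer of zeros must surround
        the object; use :func:`BinaryVolume.from_array` to enforce it.
    spacing
        Per-axis voxel edge length (mm or unitless), strictly positive.
    origin
        World coordinate of the center of voxel (0, 0, 0).
    """

    grid: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.ascontiguousarray(self.grid)
        if self.grid.ndim != 3:
            raise VolumeError(f"expected a 3D volume, got ndim={self.grid.ndim}")
        vals = np.unique(self.grid)
        if not np.all(np.isin(vals, [0, 1])):
            raise VolumeError("grid cells must be exactly 0 or 1")
        self.grid = self.grid.astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise VolumeError(f"spacing must be strictly positive, got {self.spacing}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        spacing=(1.0, 1.0, 1.0),
        origin=(0.0, 0.0, 0.0),
    ) -> "BinaryVolume":
        """Binarize (nonzero -> 1), pad so a zero layer surrounds the object,
        and shift the origin to keep world coordinates of the data unchanged."""
        data = np.asarray(data)
        if data.ndim != 3:
            raise VolumeError(f"expected a 3D volume, got ndim={data.ndim}")
        grid = (data != 0).astype(np.uint8)
        if grid.sum() == 0:
            raise VolumeError("empty segmentation: volume contains no object voxels")
        spacing = np.asarray(spacing, dtype=float).reshape(3)
        origin = np.asarray(origin, dtype=float).reshape(3)
        # pad any face whose outermost layer touches the object
        pad_lo = [1 if grid.take(0, axis=a).any() else 0 for a in range(3)]
        pad_hi = [1 if grid.take(-1, axis=a).any() else 0 for a in range(3)]
        if any(pad_lo) or any(pad_hi):
            grid = np.pad(grid, list(zip(pad_lo, pad_hi)))
            origin = origin - np.array(pad_lo) * spacing
        return cls(grid, spacing, origin)

    # -- geometry ----------------------------------------------------------

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates of voxel centers (idx may be fractional, (..., 3))."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    @property
    def object_count(self) -> int:
        return int(self.grid.sum())

    def is_padded(self) -> bool:
        g = self.grid
        return not (
            g[0].any() or g[-1].any()
            or g[:, 0].any() or g[:, -1].any()
            or g[:, :, 0].any() or g[:, :, -1].any()
        )


# --------------------------------------------------------------------------
# Analytic phantoms
# --------------------------------------------------------------------------

def _segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment ab."""
    ab = b - a
    t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(pts - closest, axis=-1)


class AnalyticShape:
    """A bounded shape with an exact signed distance (negative inside)."""

    kind: str = "abstract"

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World-space axis-aligned bounding box (lo, hi)."""
        raise NotImplementedError

    def surface_samples(self, n: int = 2000) -> np.ndarray:
        """Deterministic points on the zero level set (for symmetric
        surface-distance measurements against meshes)."""
        raise NotImplementedError


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere directions."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclass
class Sphere(AnalyticShape):
    center: tuple = (0.0, 0.0, 0.0)
    radius: float = 10.0
    kind: str = "sphere"

    def signed_distance(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.linalg.norm(pts - np.asarray(self.center), axis=-1) - self.radius

    def bounds(self):
        c = np.asarray(self.center, dtype=float)
        return c - self.radius, c + self.radius

    def surface_samples(self, n: int = 2000) -> np.ndarray:
        return np.asarray(self.center) + self.radius * _fibonacci_sphere(n)


@dataclass
class Tube(AnalyticShape):
    """Capsule: a straight tube of given radius with rounded ends."""

    start: tuple = (0.0, 0.0, 0.0)
    end: tuple = (0.0, 0.0, 20.0)
    radius: float = 3.0
    kind: str = "tube"

    def signed_distance(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        a = np.asarray(self.start, dtype=float)
        b = np.asarray(self.end, dtype=float)
        return _segment_distance(pts, a, b) - self.radius

    def bounds(self):
        a = np.asarray(self.start, dtype=float)
        b = np.asarray(self.end, dtype=float)
        return np.minimum(a, b) - self.radius, np.maximum(a, b) + self.radius

    def surface_samples(self, n: int = 2000) -> np.ndarray:
        a = np.asarray(self.start, dtype=float)
        b = np.asarray(self.end, dtype=float)
        axis = b - a
        length = np.linalg.norm(axis)
        axis = axis / max(length, 1e-300)
        # area split between the cylindrical side and the two spherical caps
        side_area = 2 * np.pi * self.radius * length
        cap_area = 4 * np.pi * self.radius**2
        n_caps = max(int(n * cap_area / (cap_area + side_area)), 8)
        n_side = max(n - n_caps, 8)
        ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(ref, axis); e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        i = np.arange(n_side) + 0.5
        t = (i / n_side) * length
        ang = np.pi * (3.0 - np.sqrt(5.0)) * i
        side = (a + t[:, None] * axis
                + self.radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2))
        dirs = _fibonacci_sphere(n_caps)
        caps = np.where((dirs @ axis)[:, None] <= 0,
                        a + self.radius * dirs, b + self.radius * dirs)
        return np.concatenate([side, caps])


@dataclass
class Torus(AnalyticShape):
    """Torus with axis along z through ``center``."""

    center: tuple = (0.0, 0.0, 0.0)
    major_radius: float = 12.0
    minor_radius: float = 4.0
    kind: str = "torus"

    def signed_distance(self, pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float)) - np.asarray(self.center)
        rho = np.hypot(pts[..., 0], pts[..., 1]) - self.major_radius
        return np.hypot(rho, pts[..., 2]) - self.minor_radius

    def bounds(self):
        c = np.asarray(self.center, dtype=float)
        r = self.major_radius + self.minor_radius
        lo = c - np.array([r, r, self.minor_radius])
        hi = c + np.array([r, r, self.minor_radius])
        return lo, hi

    def surface_samples(self, n: int = 2000) -> np.ndarray:
        i = np.arange(n) + 0.5
        phi = 2 * np.pi * i / n
        theta = np.pi * (3.0 - np.sqrt(5.0)) * i  # incommensurate winding
        rho = self.major_radius + self.minor_radius * np.cos(theta)
        return np.asarray(self.center) + np.stack([
            rho * np.cos(phi), rho * np.sin(phi),
            self.minor_radius * np.sin(theta)], axis=1)


class _Union(AnalyticShape):
    """Union of shapes: pointwise minimum of signed distances."""

    def __init__(self, *shapes: AnalyticShape):
        self.shapes = shapes

    def signed_distance(self, pts):
        return np.min([s.signed_distance(pts) for s in self.shapes], axis=0)

    def bounds(self):
        los, his = zip(*(s.bounds() for s in self.shapes))
        return np.min(los, axis=0), np.max(his, axis=0)

    def surface_samples(self, n: int = 2000) -> np.ndarray:
        per = max(n // len(self.shapes), 16)
        pts = np.concatenate([s.surface_samples(per) for s in self.shapes])
        # a component's surface point interior to another component is not
        # on the union's surface
        keep = self.signed_distance(pts) > -1e-9
        return pts[keep]


@dataclass
class Bifurcation(_Union):
    """Y-junction: two equal-radius tubes sharing an endpoint at a set angle.

    The branches lie in the xz-plane, opening upward symmetrically about +z,
    so an ``angle_deg`` of 60 puts each branch 30 degrees off the z axis.
    """

    junction: tuple = (0.0, 0.0, 0.0)
    radius: float = 6.0
    length: float = 24.0
    angle_deg: float = 60.0
    kind: str = "bifurcation"

    def __post_init__(self):
        j = np.asarray(self.junction, dtype=float)
        half = np.deg2rad(self.angle_deg) / 2.0
        d1 = np.array([np.sin(half), 0.0, np.cos(half)])
        d2 = np.array([-np.sin(half), 0.0, np.cos(half)])
        super().__init__(
            Tube(tuple(j), tuple(j + self.length * d1), self.radius),
            Tube(tuple(j), tuple(j + self.length * d2), self.radius),
        )


@dataclass
class Dumbbell(_Union):
    """Two spheres of different radius joined by a thinner tube.

    The large/small radius contrast exercises curvature adaptivity: the mesh
    should use proportionally shorter edges over the small sphere.
    """

    center_large: tuple = (0.0, 0.0, 0.0)
    center_small: tuple = (30.0, 0.0, 0.0)
    radius_large: float = 15.0
    radius_small: float = 5.0
    neck_radius: float = 3.0
    kind: str = "dumbbell"

    def __post_init__(self):
        super().__init__(
            Sphere(self.center_large, self.radius_large),
            Sphere(self.center_small, self.radius_small),
            Tube(self.center_large, self.center_small, self.neck_radius),
        )


PHANTOMS = {
    "sphere": Sphere,
    "tube": Tube,
    "torus": Torus,
    "bifurcation": Bifurcation,
    "dumbbell": Dumbbell,
}


def rasterize(shape: AnalyticShape, spacing=(1.0, 1.0, 1.0), margin: int = 2) -> BinaryVolume:
    """Voxelize an analytic shape: a voxel is object iff its *center* lies
    strictly inside (signed distance < 0).

    ``margin`` background voxels (>= 1) are kept on every side.
    """
    if margin < 1:
        raise ValueError("margin must be >= 1")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    lo, hi = shape.bounds()
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("unbounded shape cannot be rasterized")
    # align the lattice so the bounding-box midpoint is exactly a voxel
    # center; a shape smaller than a voxel then still claims its center cell
    mid = (lo + hi) / 2.0
    origin = mid - spacing * np.ceil((mid - lo) / spacing + margin)
    shape_n = np.ceil((hi - origin) / spacing).astype(int) + margin + 1
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape_n), indexing="ij")
    centers = origin + np.stack([ii, jj, kk], axis=-1) * spacing
    sdf = shape.signed_distance(centers.reshape(-1, 3)).reshape(ii.shape)
    grid = (sdf < 0).astype(np.uint8)
    if grid.sum() == 0:
        raise VolumeError("rasterization produced an empty volume (shape thinner than spacing?)")
    return BinaryVolume.from_array(grid, spacing, origin)


# --------------------------------------------------------------------------
# Volume I/O
# --------------------------------------------------------------------------

def load_volume(path, fmt: str | None = None) -> BinaryVolume:
    """Read a segmentation volume from NIfTI, MetaImage, or raw+JSON sidecar.

    Nonzero values are mapped to 1; spacing/origin come from the header
    (defaults 1.0 / 0.0 for raw).  The returned volume is zero-padded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if fmt is None:
        if name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith((".mha", ".mhd")):
            fmt = "metaimage"
        elif name.endswith(".raw"):
            fmt = "raw"
        else:
            raise VolumeError(f"cannot infer volume format from {path.name!r}")
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
        spacing = np.asarray(img.GetSpacing(), dtype=float)
        origin = np.asarray(img.GetOrigin(), dtype=float)
    elif fmt == "raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise VolumeError(f"raw volume requires a JSON sidecar at {sidecar}")
        meta = json.loads(sidecar.read_text())
        data = np.fromfile(path, dtype=np.dtype(meta.get("dtype", "uint8")))
        data = data.reshape(meta["shape"])
        spacing = np.asarray(meta.get("spacing", [1.0, 1.0, 1.0]), dtype=float)
        origin = np.asarray(meta.get("origin", [0.0, 0.0, 0.0]), dtype=float)
    else:
        raise VolumeError(f"unknown volume format {fmt!r}")
    if data.ndim != 3:
        raise VolumeError(f"expected 3D data in {path.name}, got ndim={data.ndim}")
    return BinaryVolume.from_array(data, spacing, origin)


def save_volume(vol: BinaryVolume, path) -> None:
    """Write a volume as NIfTI, MetaImage, or raw+JSON (by extension)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.grid.astype(np.uint8), affine), str(path))
    elif name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.grid.transpose(2, 1, 0))
        img.SetSpacing(tuple(vol.spacing))
        img.SetOrigin(tuple(vol.origin))
        sitk.WriteImage(img, str(path))
    elif name.endswith(".raw"):
        vol.grid.astype(np.uint8).tofile(path)
        meta = {
            "shape": list(vol.grid.shape),
            "dtype": "uint8",
            "spacing": vol.spacing.tolist(),
            "origin": vol.origin.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    else:
        raise VolumeError(f"unknown volume format for {path.name!r}")


# --------------------------------------------------------------------------
# Mesh I/O
# --------------------------------------------------------------------------

_MESH_FORMATS = {".ply", ".obj", ".stl"}


def save_mesh(vertices: np.ndarray, faces: np.ndarray, path, fmt: str | None = None) -> None:
    """Write a triangle mesh as PLY (ascii), OBJ, or STL.

    PLY/OBJ round-trip vertices and connectivity exactly; STL stores
    unwelded triangle soup and loses shared-vertex connectivity.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    if len(vertices) == 0 or len(faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    path = Path(path)
    suffix = ("." + fmt.lower()) if fmt else path.suffix.lower()
    if suffix not in _MESH_FORMATS:
        raise ValueError(f"unknown mesh format {suffix!r}; use one of {sorted(_MESH_FORMATS)}")
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if suffix == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    else:
        mesh.export(str(path), file_type=suffix[1:])


def load_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a triangle mesh; returns (vertices, faces)."""
    mesh = trimesh.load(str(path), process=False, force="mesh")
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=int)
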