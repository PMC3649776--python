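"""Triangle meshes, point clouds, rigid transforms and sagittal mirroring.

All coordinates are millimeters. Rigid transforms are restricted to proper
rotations (det = +1): a registration step can therefore never silently flip
chirality. Reflections — needed to build the mirror model of the healthy
contralateral bone — are available only through :func:`mirror_mesh` /
:class:`MirrorPlane`, which keeps the left/right bookkeeping explicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import FormatError, ParameterError, PreconditionError, ValidationError

__all__ = [
    "SurfaceMesh",
    "PointCloud",
    "RigidTransform",
    "MirrorPlane",
    "read_mesh",
    "write_mesh",
    "mirror_mesh",
    "mirror_points",
    "apply_transform",
    "sample_point_cloud",
]


@dataclass
class SurfaceMesh:
    """Triangle mesh in mm coordinates.

    ``vertices`` is (N, 3) float; ``faces`` is (M, 3) int with entries in
    [0, N) and three distinct vertices per face. ``vertex_colors`` is an
    optional (N, 3) uint8 RGB array (used by the colorimetric export).
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be an (M, 3) array")
        if not np.isfinite(self.vertices).all():
            raise ValidationError("mesh vertices contain NaN/inf coordinates")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValidationError("face indices out of range")
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
                raise ValidationError("degenerate faces (repeated vertex index)")
        if self.vertex_colors is not None:
            self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.uint8)
            if self.vertex_colors.shape != (len(self.vertices), 3):
                raise ValidationError("vertex_colors must be (N, 3) uint8")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (M, 3, 3)."""
        return self.vertices[self.faces]

    def to_trimesh(self) -> trimesh.Trimesh:
        kw = {}
        if self.vertex_colors is not None:
            kw["vertex_colors"] = self.vertex_colors
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False, **kw)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, colors: bool = False) -> "SurfaceMesh":
        vc = None
        if colors and tm.visual.kind == "vertex":
            vc = np.asarray(tm.visual.vertex_colors)[:, :3]
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), vertex_colors=vc)

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def signed_volume(self) -> float:
        """Signed enclosed volume (mm^3); positive for outward-wound closed meshes."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)


@dataclass
class PointCloud:
    """K surface points in mm with optional unit normals."""

    points: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("points must be a (K, 3) array")
        if not np.isfinite(self.points).all():
            raise ValidationError("points contain NaN/inf")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.points.shape:
                raise ValidationError("normals must match points shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.abs(norms - 1.0).max(initial=0.0) > 1e-6:
                raise ValidationError("normals must be unit length (within 1e-6)")

    def __len__(self) -> int:
        return len(self.points)


_ORTHO_TOL = 1e-9


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation + translation, no scaling).

    The rotation is validated to be orthonormal with determinant +1, so a
    RigidTransform can never encode a reflection.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValidationError(f"rotation is not orthonormal (|R R^T - I| = {err:.2e})")
        det = np.linalg.det(self.rotation)
        if det < 0:
            raise ValidationError("improper rotation (det = -1): reflections are not rigid transforms here")
        if abs(det - 1.0) > 1e-6:
            raise ValidationError(f"rotation determinant {det} != +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValidationError("homogeneous matrix must be 4x4")
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self, path: str | Path) -> None:
        """Serialize as a row-major 4x4 homogeneous matrix."""
        Path(path).write_text(json.dumps({"matrix": self.to_matrix().tolist()}, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        try:
            data = json.loads(Path(path).read_text())
            return cls.from_matrix(np.asarray(data["matrix"]))
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"not a valid transform JSON: {path}") from exc

    def rotation_angle_deg(self) -> float:
        """Rotation magnitude in degrees (angle of the axis-angle form)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class MirrorPlane:
    """Plane given by a point on it and its unit normal, both in mm."""

    point_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.point_mm = np.asarray(self.point_mm, dtype=np.float64).reshape(3)
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        n = np.linalg.norm(self.normal)
        if n == 0 or not np.isfinite(n):
            raise ValidationError("mirror plane normal must be nonzero and finite")
        self.normal = self.normal / n

    @classmethod
    def sagittal(cls, x_mm: float = 0.0) -> "MirrorPlane":
        """Sagittal plane x = const in the synthetic frame (x = medial-lateral)."""
        return cls(np.array([x_mm, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))


def mirror_points(points: np.ndarray, plane: MirrorPlane) -> np.ndarray:
    """Reflect points across ``plane``: v -> v - 2((v - p).n)n."""
    pts = np.asarray(points, dtype=np.float64)
    d = (pts - plane.point_mm) @ plane.normal
    return pts - 2.0 * d[..., None] * plane.normal


def mirror_mesh(mesh: SurfaceMesh, plane: MirrorPlane) -> SurfaceMesh:
    """Reflect a mesh across a plane, reversing winding so outward orientation survives."""
    verts = mirror_points(mesh.vertices, plane)
    faces = mesh.faces[:, ::-1].copy()
    return SurfaceMesh(verts, faces, vertex_colors=None if mesh.vertex_colors is None
                       else mesh.vertex_colors.copy())


def apply_transform(obj: SurfaceMesh | PointCloud, t: RigidTransform):
    """Apply a rigid transform to a mesh or point cloud (normals rotate only)."""
    if isinstance(obj, SurfaceMesh):
        return SurfaceMesh(t.apply(obj.vertices), obj.faces.copy(),
                           vertex_colors=None if obj.vertex_colors is None else obj.vertex_colors.copy())
    if isinstance(obj, PointCloud):
        normals = None if obj.normals is None else obj.normals @ t.rotation.T
        return PointCloud(t.apply(obj.points), normals)
    raise ParameterError(f"cannot transform object of type {type(obj).__name__}")


def sample_point_cloud(mesh: SurfaceMesh, k: int, seed: int = 0) -> PointCloud:
    """Draw ``k`` points area-uniformly on the surface, with face normals.

    Deterministic given ``seed``. Each sampled point lies exactly on the
    plane of the face it was drawn from.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if mesh.n_faces < 1:
        raise PreconditionError("cannot sample an empty mesh")
    tm = mesh.to_trimesh()
    pts, fid = trimesh.sample.sample_surface(tm, k, seed=int(seed))
    normals = np.asarray(tm.face_normals)[fid]
    # guard against rare zero-area faces producing non-unit normals
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return PointCloud(np.asarray(pts, dtype=np.float64), normals / norms)


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read an STL (binary/ASCII) or PLY mesh; PLY vertex colors are preserved."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(path, process=False, force="mesh")
    except Exception as exc:  # trimesh raises assorted exceptions on corrupt input
        raise FormatError(f"cannot parse mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"no triangle geometry in {path}")
    if path.suffix.lower() == ".stl":
        tm.merge_vertices()  # STL stores an unindexed triangle soup
    return SurfaceMesh.from_trimesh(tm, colors=path.suffix.lower() == ".ply")


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write STL (binary) or PLY (binary little-endian; keeps vertex colors)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in {".stl", ".ply"}:
        raise FormatError(f"unsupported mesh format '{suffix}' (use .stl or .ply)")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.to_trimesh().export(path)
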