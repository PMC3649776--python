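"""Parametric distal-femur-like shapes with ground-truth landmarks.

No clinical scans ship with this package, so every downstream stage —
segmentation, mirroring, ABC measurement, screening, registration, scoring —
is exercised on synthetic anatomy with known ground truth.

The shape is a smooth union of two condylar ellipsoids and a cylindrical
shaft, built as an implicit signed field and meshed by marching cubes. The
synthetic frame is fixed and documented: x = medial-lateral (sagittal plane
at x = 0), y = anterior-posterior, z = proximal-distal. A canonical
right-side bone is generated first; a left-side bone is its exact mirror
image across x = 0, which makes chirality properties hold to machine
precision.

Ground-truth landmarks are placed analytically at the ellipsoid axis
extremes, so ``compute_abc`` on them reproduces the generative (A, B, C)
parameters exactly at zero noise. Surface noise displaces vertices along
their outward normals; each landmark inherits the displacement of its
nearest surface vertex, so measured ABC degrades gracefully with noise.

Tumor-like defects remove all vertices inside a (jittered) sphere and leave
an open boundary, emulating how tumor lysis erases anatomy and yields
incomplete host models.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .errors import DegenerateOutputError, ParameterError, PreconditionError
from .landmarks_abc import LANDMARK_NAMES, LandmarkSet, compute_abc, write_landmarks
from .mesh_core import SurfaceMesh, write_mesh
from .volume_segmentation import VoxelVolume

__all__ = [
    "FemurParams",
    "DefectSpec",
    "generate_femur",
    "apply_defect",
    "rasterize_to_volume",
    "generate_bank",
]


@dataclass(frozen=True)
class FemurParams:
    """Generative parameters of a synthetic distal femur.

    a_mm: transepicondylar width (the A measure).
    b_mm / c_mm: medial / lateral condyle anterior-posterior depth (B / C).
    shaft_length_mm, shaft_radius_mm: diaphyseal segment above the condyles.
    side: 'left' or 'right'; left is the exact mirror of right.
    noise_sd_mm: standard deviation of surface noise along vertex normals.
    resolution_mm: sampling pitch of the implicit field before meshing.
    """

    a_mm: float = 80.0
    b_mm: float = 60.0
    c_mm: float = 62.0
    shaft_length_mm: float = 100.0
    shaft_radius_mm: float = 15.0
    side: str = "right"
    noise_sd_mm: float = 0.0
    seed: int = 0
    resolution_mm: float = 1.5

    def validate(self) -> None:
        for name in ("a_mm", "b_mm", "c_mm", "shaft_length_mm", "shaft_radius_mm",
                     "resolution_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
        if self.b_mm > self.a_mm or self.c_mm > self.a_mm:
            raise ParameterError("condylar depths b_mm/c_mm must not exceed width a_mm")
        if self.side not in ("left", "right"):
            raise ParameterError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.noise_sd_mm < 0:
            raise ParameterError("noise_sd_mm must be >= 0")


@dataclass(frozen=True)
class DefectSpec:
    """Spherical tumor-like erosion: vertices within radius of center are removed."""

    center_mm: tuple
    radius_mm: float
    seed: int = 0
    jitter: float = 0.1  # relative per-vertex radius irregularity

    def validate(self) -> None:
        if self.radius_mm <= 0:
            raise ParameterError("defect radius_mm must be > 0")
        if len(tuple(self.center_mm)) != 3:
            raise ParameterError("defect center_mm must be a 3-vector")


def _ellipsoid_field(pts: np.ndarray, center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    # approximate signed distance: negative inside
    q = (pts - center) / axes
    return (np.linalg.norm(q, axis=-1) - 1.0) * axes.min()


def _capped_cylinder_field(pts: np.ndarray, center_xy: np.ndarray, z0: float,
                           z1: float, radius: float) -> np.ndarray:
    # exact SDF of a z-aligned capped cylinder
    dxy = np.linalg.norm(pts[..., :2] - center_xy, axis=-1) - radius
    zmid, zhalf = 0.5 * (z0 + z1), 0.5 * (z1 - z0)
    dz = np.abs(pts[..., 2] - zmid) - zhalf
    outside = np.sqrt(np.maximum(dxy, 0.0) ** 2 + np.maximum(dz, 0.0) ** 2)
    inside = np.minimum(np.maximum(dxy, dz), 0.0)
    return outside + inside


def _femur_field(pts: np.ndarray, p: FemurParams) -> np.ndarray:
    """Smooth-union signed field of the canonical right-side femur."""
    a, b, c = p.a_mm, p.b_mm, p.c_mm
    # condyle ellipsoids: x-extremes at +/- a/2, y-extremes at +/- b/2 (c/2)
    med = _ellipsoid_field(pts, np.array([a / 4.0, 0.0, 0.0]),
                           np.array([a / 4.0, b / 2.0, 0.40 * b]))
    lat = _ellipsoid_field(pts, np.array([-a / 4.0, 0.0, 0.0]),
                           np.array([a / 4.0, c / 2.0, 0.40 * c]))
    # shaft slightly medial and posterior: makes the bone genuinely chiral
    shaft = _capped_cylinder_field(
        pts, np.array([0.06 * a, -0.08 * b]), 0.0, p.shaft_length_mm,
        p.shaft_radius_mm)
    k = 2.0  # mm, blending length of the soft union
    stack = np.stack([med, lat, shaft], axis=-1)
    m = stack.min(axis=-1, keepdims=True)
    return (m - k * np.log(np.exp(-(stack - m) / k).sum(axis=-1, keepdims=True)))[..., 0]


def _ideal_landmarks(p: FemurParams) -> LandmarkSet:
    a, b, c = p.a_mm, p.b_mm, p.c_mm
    pts = {
        "ME": [a / 2.0, 0.0, 0.0],
        "LE": [-a / 2.0, 0.0, 0.0],
        "MA": [a / 4.0, b / 2.0, 0.0],
        "MP": [a / 4.0, -b / 2.0, 0.0],
        "LA": [-a / 4.0, c / 2.0, 0.0],
        "LP": [-a / 4.0, -c / 2.0, 0.0],
    }
    return LandmarkSet(pts)


def generate_femur(params: FemurParams) -> tuple[SurfaceMesh, LandmarkSet]:
    """Generate a closed synthetic femur mesh plus its six ground-truth landmarks.

    Deterministic given ``params.seed``. At ``noise_sd_mm = 0`` the landmark
    ABC round-trip is exact and left/right outputs are exact mirror images.
    """
    params.validate()
    p = params
    res = p.resolution_mm
    a, b, c = p.a_mm, p.b_mm, p.c_mm
    pad = 6.0 + 2 * res
    lo = np.array([-a / 2.0 - pad, -max(b, c) / 2.0 - pad, -0.40 * max(b, c) - pad])
    hi = np.array([a / 2.0 + pad, max(b, c) / 2.0 + pad, p.shaft_length_mm + pad])
    shape = np.ceil((hi - lo) / res).astype(int) + 1
    xs = [lo[i] + np.arange(shape[i]) * res for i in range(3)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
    field = _femur_field(grid, p)
    verts, faces, _, _ = marching_cubes(field.astype(np.float32), level=0.0,
                                        spacing=(res, res, res))
    verts = verts + lo
    mesh = SurfaceMesh(verts, faces)
    if mesh.signed_volume() < 0:
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1].copy())
    landmarks = _ideal_landmarks(p)

    if p.noise_sd_mm > 0:
        rng = np.random.default_rng(p.seed)
        tm = mesh.to_trimesh()
        normals = np.asarray(tm.vertex_normals)
        disp = rng.normal(0.0, p.noise_sd_mm, size=len(mesh.vertices))[:, None] * normals
        # landmarks ride along with their nearest surface vertex
        tree = cKDTree(mesh.vertices)
        _, nearest = tree.query(landmarks.as_array())
        landmarks = LandmarkSet.from_array(landmarks.as_array() + disp[nearest])
        mesh = SurfaceMesh(mesh.vertices + disp, mesh.faces)

    if p.side == "left":
        v = mesh.vertices.copy()
        v[:, 0] = -v[:, 0]
        mesh = SurfaceMesh(v, mesh.faces[:, ::-1].copy())
        lm = landmarks.as_array()
        lm[:, 0] = -lm[:, 0]
        landmarks = LandmarkSet.from_array(lm)
    return mesh, landmarks


def apply_defect(mesh: SurfaceMesh, spec: DefectSpec) -> SurfaceMesh:
    """Erode a tumor-like region: drop vertices near the defect center.

    The boundary is left open (no hole filling) to emulate incomplete
    tumoral bone models. Per-vertex radius jitter (seeded) makes the crater
    rim irregular. Raises if nothing would remain.
    """
    spec.validate()
    center = np.asarray(spec.center_mm, dtype=np.float64)
    d = np.linalg.norm(mesh.vertices - center, axis=1)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        radii = spec.radius_mm * (1.0 + spec.jitter * rng.uniform(-1, 1, len(d)))
    else:
        radii = np.full(len(d), spec.radius_mm)
    remove = d < radii
    if not remove.any():
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy())
    keep = ~remove
    if not keep.any():
        raise DegenerateOutputError("defect removes the entire mesh")
    new_index = np.cumsum(keep) - 1
    face_keep = keep[mesh.faces].all(axis=1)
    faces = new_index[mesh.faces[face_keep]]
    if len(faces) == 0:
        raise DegenerateOutputError("defect removes all faces")
    # drop vertices that became unreferenced
    used = np.zeros(int(keep.sum()), dtype=bool)
    used[faces.ravel()] = True
    remap = np.cumsum(used) - 1
    return SurfaceMesh(mesh.vertices[keep][used], remap[faces])


def rasterize_to_volume(mesh: SurfaceMesh, spacing_mm=0.5, inside_value: float = 1000.0,
                        outside_value: float = 0.0, noise_sd: float = 0.0,
                        seed: int = 0) -> VoxelVolume:
    """Emulated CT acquisition: voxelize a closed mesh on a regular grid.

    Voxel centers strictly inside the mesh get ``inside_value``, the rest
    ``outside_value``; Gaussian noise of ``noise_sd`` is added everywhere.
    The grid covers the mesh bounding box with at least a two-voxel margin.
    Inside/outside is decided by parity of surface crossings along +z rays
    through each voxel column (exact for closed meshes; ray origins carry a
    sub-micrometer lateral offset so rays never hit edges exactly).
    """
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=np.float64), (3,)).copy()
    if (spacing <= 0).any():
        raise ParameterError("spacing must be > 0")
    if mesh.n_faces == 0 or not mesh.is_watertight():
        raise PreconditionError("rasterization requires a closed (watertight) mesh")

    vmin = mesh.vertices.min(axis=0)
    vmax = mesh.vertices.max(axis=0)
    origin = vmin - 2.0 * spacing
    shape = np.ceil((vmax - origin) / spacing).astype(int) + 3
    nx, ny, nz = (int(s) for s in shape)

    # sub-voxel irrational-ish ray offsets avoid edge-on-ray degeneracies
    ox = origin[0] + spacing[0] * 1e-6 * np.sqrt(2.0)
    oy = origin[1] + spacing[1] * 1e-6 * np.sqrt(3.0)

    tri = mesh.triangles
    x1, y1, z1 = tri[:, 0, 0], tri[:, 0, 1], tri[:, 0, 2]
    x2, y2, z2 = tri[:, 1, 0], tri[:, 1, 1], tri[:, 1, 2]
    x3, y3, z3 = tri[:, 2, 0], tri[:, 2, 1], tri[:, 2, 2]
    det = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
    ok = np.abs(det) > 1e-14  # skip triangles vertical to the xy plane

    txmin = tri[:, :, 0].min(axis=1)
    txmax = tri[:, :, 0].max(axis=1)
    tymin = tri[:, :, 1].min(axis=1)
    tymax = tri[:, :, 1].max(axis=1)
    i0 = np.ceil((txmin - ox) / spacing[0]).astype(np.int64)
    i1 = np.floor((txmax - ox) / spacing[0]).astype(np.int64)
    j0 = np.ceil((tymin - oy) / spacing[1]).astype(np.int64)
    j1 = np.floor((tymax - oy) / spacing[1]).astype(np.int64)
    wi = np.maximum(i1 - i0 + 1, 0)
    wj = np.maximum(j1 - j0 + 1, 0)
    ncols = np.where(ok, wi * wj, 0)

    total = int(ncols.sum())
    crossings = np.zeros(nx * ny * nz, dtype=np.int16)
    if total:
        tid = np.repeat(np.arange(len(tri)), ncols)
        starts = np.concatenate(([0], np.cumsum(ncols)))
        pos = np.arange(total) - np.repeat(starts[:-1], ncols)
        di = pos // wj[tid]
        dj = pos % wj[tid]
        ii = i0[tid] + di
        jj = j0[tid] + dj
        px = ox + ii * spacing[0]
        py = oy + jj * spacing[1]
        # barycentric coordinates of the (x, y) projection
        dinv = 1.0 / det[tid]
        s = ((px - x1[tid]) * (y3[tid] - y1[tid]) - (py - y1[tid]) * (x3[tid] - x1[tid])) * dinv
        t = ((py - y1[tid]) * (x2[tid] - x1[tid]) - (px - x1[tid]) * (y2[tid] - y1[tid])) * dinv
        hit = (s >= 0.0) & (t >= 0.0) & (s + t <= 1.0)
        if hit.any():
            s, t = s[hit], t[hit]
            th = tid[hit]
            zc = (1.0 - s - t) * z1[th] + s * z2[th] + t * z3[th]
            k0 = np.floor((zc - origin[2]) / spacing[2]).astype(np.int64) + 1
            valid = (k0 >= 0) & (k0 < nz)
            flat = (ii[hit][valid] * ny + jj[hit][valid]) * nz + k0[valid]
            np.add.at(crossings, flat, 1)

    inside = (np.cumsum(crossings.reshape(nx, ny, nz), axis=2) % 2).astype(bool)
    data = np.where(inside, np.float64(inside_value), np.float64(outside_value))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return VoxelVolume(data, spacing, origin)


def _format_float(x: float) -> str:
    return repr(float(x))


def generate_bank(n: int, out_dir: str | Path, abc_mean=(80.0, 60.0, 62.0),
                  abc_sd=(4.0, 3.0, 3.0), seed: int = 0, side: str = "both",
                  noise_sd_mm: float = 0.0, resolution_mm: float = 1.5,
                  shaft_length_mm: float = 100.0):
    """Write a synthetic donor bank: meshes, landmark files, and the index CSV.

    Donor ABC dimensions are drawn from independent normals (mean/sd per
    measure); implausible draws (non-positive, or condyle depth exceeding
    width) are redrawn. ``side`` is 'left', 'right', or 'both' (random
    50/50). Each record's stored ABC is measured from its stored landmarks.
    Fully deterministic given ``seed``; returns the :class:`~vbb.bank_index.BankIndex`.
    """
    from .bank_index import BankIndex, BankRecord, build_index

    if n < 1:
        raise ParameterError("n must be >= 1")
    abc_mean = np.asarray(abc_mean, dtype=np.float64)
    abc_sd = np.asarray(abc_sd, dtype=np.float64)
    if (abc_sd < 0).any():
        raise ParameterError("abc_sd entries must be >= 0")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"bank directory not writable: {out_dir}: {exc}") from exc

    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        for _ in range(100):
            abc = rng.normal(abc_mean, abc_sd)
            if abc.min() > 1.0 and abc[1] <= abc[0] and abc[2] <= abc[0]:
                break
        else:
            raise ParameterError("abc distribution yields no plausible donors")
        donor_side = side if side in ("left", "right") else \
            ("left" if rng.random() < 0.5 else "right")
        donor_id = f"donor_{i:04d}"
        params = FemurParams(a_mm=float(abc[0]), b_mm=float(abc[1]), c_mm=float(abc[2]),
                             shaft_length_mm=shaft_length_mm,
                             shaft_radius_mm=0.19 * float(abc[0]), side=donor_side,
                             noise_sd_mm=noise_sd_mm,
                             seed=int(rng.integers(0, 2**31 - 1)),
                             resolution_mm=resolution_mm)
        mesh, landmarks = generate_femur(params)
        mesh_path = out_dir / f"{donor_id}.stl"
        lm_path = out_dir / f"{donor_id}.landmarks.json"
        write_mesh(mesh, mesh_path)
        write_landmarks(landmarks, lm_path)
        records.append(BankRecord(donor_id=donor_id, side=donor_side, bone="distal_femur",
                                  abc=compute_abc(landmarks), mesh_path=mesh_path.name,
                                  landmarks_path=lm_path.name))

    csv_path = out_dir / "bank.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["donor_id", "side", "bone", "a_mm", "b_mm", "c_mm",
                         "mesh_path", "landmarks_path"])
        for r in records:
            writer.writerow([r.donor_id, r.side, r.bone, _format_float(r.abc.a_mm),
                             _format_float(r.abc.b_mm), _format_float(r.abc.c_mm),
                             r.mesh_path, r.landmarks_path])
    return build_index(records, base_dir=out_dir)
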