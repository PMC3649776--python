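"""Rigid registration of host (mirror) and donor bone models.

Two initializations are provided: a closed-form least-squares alignment of
the six named landmarks (Kabsch/Procrustes without scaling) and, for
diaphyseal or transepiphyseal segments where natural landmarks cannot be
placed, a centroid + principal-axes alignment. Refinement is trimmed
iterative closest point (ICP) with point-to-surface correspondences:
trimming discards the worst fraction of correspondences each iteration,
which makes the fit robust to the missing regions of incomplete tumoral
host models.

Scaling is never estimated: allograft selection compares true bone sizes,
so a scale-adjusted fit would be meaningless. All recovered transforms are
proper rotations (det = +1); chirality can never flip during registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AmbiguityWarning, ConfigurationError, DegeneracyError, ParameterError, PreconditionError
from .geometry import MeshQuery
from .landmarks_abc import LandmarkSet
from .mesh_core import PointCloud, RigidTransform, SurfaceMesh, sample_point_cloud

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "rigid_fit",
    "landmark_align",
    "icp_register",
    "principal_axes_init",
]


@dataclass
class RegistrationConfig:
    """Tunables of the trimmed-ICP refinement.

    trim_fraction: fraction of worst correspondences dropped per iteration
    (0.1 default; raise toward 0.3 for heavily incomplete hosts).
    convergence_tol_mm: stop when the trimmed mean distance changes less
    than this between iterations. sample_size bounds the number of source
    points used; seed controls the subsampling only.
    """

    max_iterations: int = 100
    convergence_tol_mm: float = 1e-4
    trim_fraction: float = 0.1
    sample_size: int = 5000
    seed: int = 0
    init_mode: str = "landmarks"  # landmarks | principal_axes | identity

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ParameterError("trim_fraction must be in [0, 0.5)")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.convergence_tol_mm <= 0:
            raise ParameterError("convergence_tol_mm must be > 0")
        if self.init_mode not in ("landmarks", "principal_axes", "identity"):
            raise ParameterError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    iterations_used: int
    final_mean_distance_mm: float
    converged: bool
    mean_history: list = field(default_factory=list)


def rigid_fit(source_pts: np.ndarray, target_pts: np.ndarray) -> RigidTransform:
    """Closed-form least-squares proper rigid transform source -> target.

    Kabsch/Umeyama without scaling; the reflection case of the SVD is
    resolved toward det(R) = +1.
    """
    P = np.asarray(source_pts, dtype=np.float64)
    Q = np.asarray(target_pts, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or len(P) < 3:
        raise ParameterError("need matching (n>=3, 3) point arrays")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cq - R @ cp)


def landmark_align(source: LandmarkSet, target: LandmarkSet) -> RigidTransform:
    """Align the six source landmarks onto the six target landmarks by name.

    Both sets must describe the same chirality (mirror the host first).
    Raises :class:`DegeneracyError` when the landmarks are (near) collinear,
    where the rotation about the line would be undetermined.
    """
    P = source.as_array()
    Q = target.as_array()
    centered = P - P.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegeneracyError("landmarks are collinear: rotation undetermined")
    return rigid_fit(P, Q)


def icp_register(source_cloud: PointCloud, target: SurfaceMesh | MeshQuery,
                 init: RigidTransform | None = None,
                 config: RegistrationConfig | None = None) -> RegistrationResult:
    """Trimmed ICP: refine ``init`` so the source cloud fits the target surface.

    Each iteration finds the exact nearest surface point for every
    transformed source point, discards the worst ``trim_fraction`` by
    distance, and re-fits the rigid transform in closed form on the
    retained pairs. The trimmed mean distance is non-increasing across
    iterations; iteration stops when it changes by less than
    ``convergence_tol_mm`` or after ``max_iterations``.
    """
    cfg = config or RegistrationConfig()
    if len(source_cloud) < 3:
        raise PreconditionError("ICP needs at least 3 source points")
    query = target if isinstance(target, MeshQuery) else MeshQuery(target)

    pts = source_cloud.points
    if len(pts) > cfg.sample_size:
        rng = np.random.default_rng(cfg.seed)
        pts = pts[rng.choice(len(pts), cfg.sample_size, replace=False)]
    m = int(np.ceil((1.0 - cfg.trim_fraction) * len(pts)))
    if m < 3:
        raise ConfigurationError("trimming leaves fewer than 3 correspondences")

    t = init or RigidTransform.identity()
    history: list = []
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        moved = t.apply(pts)
        d, closest, _ = query.query(moved)
        keep = np.argpartition(d, m - 1)[:m]
        mean_d = float(d[keep].mean())
        history.append(mean_d)
        t = rigid_fit(pts[keep], closest[keep])
        if len(history) >= 2 and abs(history[-2] - mean_d) < cfg.convergence_tol_mm:
            converged = True
            break

    d, _, _ = query.query(t.apply(pts))
    final = float(np.sort(d)[:m].mean())
    return RegistrationResult(transform=t, iterations_used=iterations,
                              final_mean_distance_mm=final, converged=converged,
                              mean_history=history)


_SIGN_CANDIDATES = ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))


def _proper_axes(points: np.ndarray) -> tuple:
    """Centroid, principal axes (columns, ascending variance, det +1), eigenvalues."""
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    evals, evecs = np.linalg.eigh(cov)
    if np.linalg.det(evecs) < 0:
        evecs[:, 0] = -evecs[:, 0]
    return c, evecs, evals


def principal_axes_init(source_cloud: PointCloud, target: SurfaceMesh | MeshQuery,
                        seed: int = 0, eval_points: int = 500) -> RigidTransform:
    """Landmark-free initialization: align centroids and principal axes.

    The axis-sign ambiguity leaves four proper-rotation candidates; the one
    with the smallest post-alignment mean surface distance wins. When the
    inertia is near-degenerate (adjacent principal-moment ratio < 1.01, as
    for a sphere) an :class:`AmbiguityWarning` is emitted and only the
    centroid translation is applied.
    """
    query = target if isinstance(target, MeshQuery) else MeshQuery(target)
    tgt = sample_point_cloud(query.mesh, max(2000, eval_points), seed=seed).points
    cs, Vs, ls = _proper_axes(source_cloud.points)
    ct, Vt, lt = _proper_axes(tgt)

    ratios = np.concatenate([ls[1:] / np.maximum(ls[:-1], 1e-30),
                             lt[1:] / np.maximum(lt[:-1], 1e-30)])
    if (ratios < 1.01).any():
        warnings.warn("principal moments nearly degenerate: axis alignment is "
                      "ambiguous, falling back to centroid translation",
                      AmbiguityWarning, stacklevel=2)
        return RigidTransform(np.eye(3), ct - cs)

    pts = source_cloud.points
    if len(pts) > eval_points:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), eval_points, replace=False)]

    best = None
    best_score = np.inf
    for signs in _SIGN_CANDIDATES:
        R = Vt @ np.diag(signs).astype(float) @ Vs.T
        cand = RigidTransform(R, ct - R @ cs)
        d, _, _ = query.query(cand.apply(pts))
        score = float(d.mean())
        if score < best_score:
            best, best_score = cand, score
    return best
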