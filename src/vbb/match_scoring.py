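"""Goodness-of-match between a host mirror model and donor surfaces.

After registration, per-point distances from the host surface point cloud
to the donor surface quantify local mismatch; their mean is the headline
goodness-of-match score, reported together with RMS, one-directional
maximum (Hausdorff) and 95th percentile. Distances run host -> donor by
default: the clinical question is how well the donor covers the host's
required geometry, and the frequently incomplete host model would make the
reverse direction misleading. A colorimetric export paints the distances
onto the surface for visual inspection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps

from .bank_index import BankRecord
from .errors import ParameterError, PreconditionError, ValidationError
from .geometry import MeshQuery
from .landmarks_abc import LandmarkSet, read_landmarks
from .mesh_core import PointCloud, SurfaceMesh, read_mesh, sample_point_cloud
from .registration import (RegistrationConfig, RegistrationResult, icp_register,
                           landmark_align, principal_axes_init)

__all__ = [
    "DistanceField",
    "MatchScore",
    "ColorMapSpec",
    "CandidateMatch",
    "surface_distances",
    "match_score",
    "colorimetric_export",
    "rank_candidates",
]


@dataclass
class DistanceField:
    """Per-point unsigned distances (mm), aligned 1:1 with a point set."""

    distances_mm: np.ndarray
    direction: str = "host_to_donor"
    signed: bool = False

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=np.float64).reshape(-1)
        if len(self.distances_mm) == 0:
            raise PreconditionError("distance field must be non-empty")
        if not np.isfinite(self.distances_mm).all():
            raise ValidationError("distances contain NaN/inf")
        if not self.signed and (self.distances_mm < 0).any():
            raise ValidationError("unsigned distances must be >= 0")

    def __len__(self) -> int:
        return len(self.distances_mm)


@dataclass
class MatchScore:
    """Summary of a host->donor distance field; ``mean_mm`` is the ranking key."""

    mean_mm: float
    rms_mm: float
    max_mm: float
    p95_mm: float
    n_points: int

    def as_dict(self) -> dict:
        return {"mean_mm": self.mean_mm, "rms_mm": self.rms_mm,
                "max_mm": self.max_mm, "p95_mm": self.p95_mm,
                "n_points": self.n_points}


@dataclass
class ColorMapSpec:
    """Distance-to-color mapping: clamp to [lower, upper] then apply colormap."""

    lower_mm: float = 0.0
    upper_mm: float = 5.0
    colormap: str = "coolwarm"

    def __post_init__(self) -> None:
        if not self.lower_mm < self.upper_mm:
            raise ParameterError("lower_mm must be < upper_mm")

    def colors(self, distances: np.ndarray) -> np.ndarray:
        """uint8 RGB per distance value."""
        u = (np.clip(distances, self.lower_mm, self.upper_mm) - self.lower_mm) \
            / (self.upper_mm - self.lower_mm)
        rgba = colormaps[self.colormap](u)
        return (np.asarray(rgba)[:, :3] * 255).round().astype(np.uint8)


def surface_distances(source: PointCloud, target: SurfaceMesh | MeshQuery,
                      direction: str = "host_to_donor") -> DistanceField:
    """Exact distance from every source point to the nearest point anywhere on
    the target surface (point-to-triangle, not point-to-vertex).

    Inputs are assumed already registered into a common frame.
    """
    if len(source) == 0:
        raise PreconditionError("source cloud is empty")
    query = target if isinstance(target, MeshQuery) else MeshQuery(target)
    d, _, _ = query.query(source.points)
    return DistanceField(d, direction=direction)


def match_score(fielddata: DistanceField) -> MatchScore:
    """Mean / RMS / max / 95th-percentile summary of a distance field.

    The percentile uses linear interpolation between order statistics.
    """
    d = np.abs(fielddata.distances_mm)
    return MatchScore(
        mean_mm=float(d.mean()),
        rms_mm=float(np.sqrt((d**2).mean())),
        max_mm=float(d.max()),
        p95_mm=float(np.percentile(d, 95.0, method="linear")),
        n_points=len(d),
    )


def colorimetric_export(geometry: SurfaceMesh | PointCloud, fielddata: DistanceField,
                        spec: ColorMapSpec, path: str | Path) -> None:
    """Write a PLY colored by local distance, plus a JSON legend alongside.

    The field must be aligned to the geometry: one distance per mesh vertex
    (or per cloud point). Out-of-range distances are clamped to the ends of
    the color scale.
    """
    import trimesh

    path = Path(path)
    n = len(geometry.vertices) if isinstance(geometry, SurfaceMesh) else len(geometry)
    if len(fielddata) != n:
        raise ValidationError(
            f"distance field length {len(fielddata)} != geometry size {n}")
    rgb = spec.colors(fielddata.distances_mm)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(geometry, SurfaceMesh):
        colored = SurfaceMesh(geometry.vertices, geometry.faces, vertex_colors=rgb)
        colored.to_trimesh().export(path)
    else:
        trimesh.PointCloud(geometry.points, colors=np.hstack(
            [rgb, np.full((n, 1), 255, np.uint8)])).export(path)
    legend = {"lower_mm": spec.lower_mm, "upper_mm": spec.upper_mm,
              "colormap": spec.colormap, "direction": fielddata.direction,
              "units": "mm", "clamped": True}
    Path(str(path) + ".legend.json").write_text(json.dumps(legend, indent=2) + "\n")


@dataclass
class CandidateMatch:
    """Per-donor outcome of the registration + scoring stage."""

    donor_id: str
    score: MatchScore
    registration: RegistrationResult
    init_mode: str
    distance_field: DistanceField = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "donor_id": self.donor_id,
            "score": self.score.as_dict(),
            "transform_matrix": self.registration.transform.to_matrix().tolist(),
            "icp_iterations": self.registration.iterations_used,
            "icp_converged": self.registration.converged,
            "init_mode": self.init_mode,
        }


def rank_candidates(host_mesh: SurfaceMesh, host_landmarks: LandmarkSet | None,
                    candidates: list, config: RegistrationConfig | None = None,
                    score_points: int = 5000, seed: int = 0,
                    resolve=None) -> list:
    """Register and score each candidate donor; return matches sorted by mean.

    For each :class:`BankRecord` the donor mesh is loaded, registration is
    initialized from landmark correspondence when both landmark sets exist
    (principal axes otherwise), refined with trimmed ICP, and the host ->
    donor surface distance field is summarized. Sorting is ascending by
    mean distance, ties by donor_id. Unreadable candidates are skipped with
    a warning rather than failing the run.
    """
    if not candidates:
        raise PreconditionError("need at least one candidate")
    cfg = config or RegistrationConfig()
    resolve = resolve or (lambda p: Path(p))
    cloud = sample_point_cloud(host_mesh, min(score_points, max(3, score_points)),
                               seed=seed)

    results = []
    for record in candidates:
        if not isinstance(record, BankRecord):
            raise ParameterError("candidates must be BankRecord instances")
        try:
            donor_mesh = read_mesh(resolve(record.mesh_path))
        except Exception as exc:
            warnings.warn(f"skipping candidate {record.donor_id}: {exc}", stacklevel=2)
            continue
        query = MeshQuery(donor_mesh)
        if host_landmarks is not None and record.landmarks_path:
            try:
                donor_lm = read_landmarks(resolve(record.landmarks_path))
                init = landmark_align(host_landmarks, donor_lm)
                init_mode = "landmarks"
            except Exception as exc:
                warnings.warn(f"candidate {record.donor_id}: landmark init failed "
                              f"({exc}); using principal axes", stacklevel=2)
                init = principal_axes_init(cloud, query, seed=cfg.seed)
                init_mode = "principal_axes"
        else:
            init = principal_axes_init(cloud, query, seed=cfg.seed)
            init_mode = "principal_axes"
        reg = icp_register(cloud, query, init=init, config=cfg)
        moved = PointCloud(reg.transform.apply(cloud.points))
        fielddata = surface_distances(moved, query)
        results.append(CandidateMatch(donor_id=record.donor_id,
                                      score=match_score(fielddata),
                                      registration=reg, init_mode=init_mode,
                                      distance_field=fielddata))
    results.sort(key=lambda r: (r.score.mean_mm, r.donor_id))
    return results
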