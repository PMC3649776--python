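"""End-to-end allograft selection: one call from host data to a ranked report.

Stages: (optional) segmentation of a CT-like volume into a bone mesh →
mirroring of the healthy side across the sagittal plane → ABC measurement →
size screening of the bank → trimmed-ICP registration of each screened
candidate → surface-distance scoring → ranked report with per-candidate
transforms and colored donor surfaces. Every stochastic stage derives from
one seed, so a run is fully reproducible; a manifest (config hash, package
version, seed) is embedded in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np

from . import __version__
from .bank_index import read_bank_csv, screen
from .errors import ConfigurationError
from .landmarks_abc import compute_abc, mirror_landmarks, read_landmarks, transform_landmarks
from .match_scoring import ColorMapSpec, colorimetric_export, rank_candidates
from .mesh_core import MirrorPlane, PointCloud, mirror_mesh, read_mesh, sample_point_cloud, write_mesh
from .registration import RegistrationConfig
from .volume_segmentation import (DEFAULT_BONE_THRESHOLD_HU, extract_surface,
                                  largest_component, read_volume, threshold_segment)

__all__ = ["WorkflowConfig", "select_best_allograft"]

log = logging.getLogger("vbb.workflow")


@dataclass
class WorkflowConfig:
    """Inputs and tunables of one selection run.

    ``host_path`` may be a volume (.nii/.nii.gz/.nrrd; segmented first) or a
    mesh (.stl/.ply). When ``host_is_healthy_side`` is true the input is the
    intact contralateral bone and is mirrored across ``mirror_plane_*`` to
    obtain resected-side geometry. ``resected_side`` drives the chirality
    filter during screening.
    """

    host_path: str
    bank_csv: str
    out_dir: str
    host_landmarks_path: str | None = None
    host_is_healthy_side: bool = True
    resected_side: str | None = None
    mirror_plane_point: tuple = (0.0, 0.0, 0.0)
    mirror_plane_normal: tuple = (1.0, 0.0, 0.0)
    threshold_low: float = DEFAULT_BONE_THRESHOLD_HU
    threshold_high: float = float("inf")
    screening_k: int = 5
    screening_weights: tuple = (1.0, 1.0, 1.0)
    allow_contralateral: bool = False
    registration: RegistrationConfig = dataclass_field(default_factory=RegistrationConfig)
    score_points: int = 5000
    color_lower_mm: float = 0.0
    color_upper_mm: float = 5.0
    colormap: str = "coolwarm"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "WorkflowConfig":
        """Load from TOML or JSON; registration options live in a sub-table."""
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        reg = data.pop("registration", {})
        cfg = cls(**data)
        if reg:
            cfg.registration = RegistrationConfig(**reg)
        return cfg

    def canonical_json(self) -> str:
        d = dict(self.__dict__)
        d["registration"] = dict(self.registration.__dict__)
        return json.dumps(d, sort_keys=True, default=str)


def _round_floats(obj, ndigits=9):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def select_best_allograft(config: WorkflowConfig) -> dict:
    """Run the whole selection workflow; write artifacts and return the report.

    Artifacts under ``config.out_dir``: the (mirrored) host mesh, the host
    ABC row, the screening list, per-candidate transforms, colored donor
    surfaces, and ``report.json`` with the full ranking and a manifest.
    """
    t_start = time.time()
    host_path = Path(config.host_path)
    bank_path = Path(config.bank_csv)
    if not host_path.exists():
        raise ConfigurationError(f"host input not found: {host_path}")
    if not bank_path.exists():
        raise ConfigurationError(f"bank CSV not found: {bank_path}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- host model -------------------------------------------------------
    name = host_path.name.lower()
    if name.endswith((".nii", ".nii.gz", ".nrrd")):
        log.info("segmenting host volume %s", host_path)
        vol = read_volume(host_path)
        mask = largest_component(threshold_segment(vol, config.threshold_low,
                                                   config.threshold_high))
        host_mesh = extract_surface(mask)
    else:
        host_mesh = read_mesh(host_path)
    host_landmarks = (read_landmarks(config.host_landmarks_path)
                      if config.host_landmarks_path else None)

    if config.host_is_healthy_side:
        plane = MirrorPlane(np.asarray(config.mirror_plane_point),
                            np.asarray(config.mirror_plane_normal))
        host_mesh = mirror_mesh(host_mesh, plane)
        if host_landmarks is not None:
            host_landmarks = mirror_landmarks(host_landmarks, plane)
        log.info("mirrored healthy-side host across the sagittal plane")
    write_mesh(host_mesh, out_dir / "host_model.stl")

    # --- ABC + screening --------------------------------------------------
    index = read_bank_csv(bank_path)
    side = None if config.allow_contralateral else config.resected_side
    if host_landmarks is not None:
        abc = compute_abc(host_landmarks)
        (out_dir / "host_abc.csv").write_text(
            "a_mm,b_mm,c_mm\n"
            f"{abc.a_mm!r},{abc.b_mm!r},{abc.c_mm!r}\n")
        screening = screen(index, abc, k=config.screening_k,
                           weights=config.screening_weights, side=side)
        candidates = [index[e.donor_id] for e in screening.entries]
        screening_payload = [
            {"donor_id": e.donor_id, "abc_distance_mm": e.abc_distance_mm,
             "delta_a_mm": e.delta_a_mm, "delta_b_mm": e.delta_b_mm,
             "delta_c_mm": e.delta_c_mm}
            for e in screening.entries]
    else:
        # diaphyseal/transepiphyseal path: no landmarks, no ABC screening —
        # every (side-compatible) donor goes to surface matching
        abc = None
        candidates = [r for r in index.records if side is None or r.side == side]
        screening_payload = [{"donor_id": r.donor_id} for r in candidates]
    (out_dir / "screening.json").write_text(
        json.dumps(_round_floats(screening_payload), indent=2) + "\n")
    log.info("screening kept %d candidate(s)", len(candidates))
    if not candidates:
        raise ConfigurationError("no candidates pass screening filters")

    # --- registration + scoring ------------------------------------------
    matches = rank_candidates(host_mesh, host_landmarks, candidates,
                              config=config.registration,
                              score_points=config.score_points,
                              seed=config.seed, resolve=index.resolve_path)
    if not matches:
        raise ConfigurationError("every candidate failed registration/scoring")

    spec = ColorMapSpec(config.color_lower_mm, config.color_upper_mm, config.colormap)
    tdir = out_dir / "transforms"
    cdir = out_dir / "colored"
    tdir.mkdir(exist_ok=True)
    cdir.mkdir(exist_ok=True)
    host_cloud = sample_point_cloud(host_mesh, min(config.score_points, 5000),
                                    seed=config.seed)
    for m in matches:
        m.registration.transform.to_json(tdir / f"{m.donor_id}.json")
        moved = PointCloud(m.registration.transform.apply(host_cloud.points))
        colorimetric_export(moved, m.distance_field, spec,
                            cdir / f"{m.donor_id}.ply")

    report = {
        "best_donor_id": matches[0].donor_id,
        "ranking": [_round_floats(m.as_dict()) for m in matches],
        "host_abc_mm": None if abc is None else
            _round_floats({"a_mm": abc.a_mm, "b_mm": abc.b_mm, "c_mm": abc.c_mm}),
        "screening": _round_floats(screening_payload),
        "manifest": {
            "tool": "vbb",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                config.canonical_json().encode()).hexdigest(),
        },
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    log.info("workflow finished in %.1f s; best donor: %s",
             time.time() - t_start, matches[0].donor_id)
    return report
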