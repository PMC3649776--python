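"""Six distal-femur landmarks and the three ABC size measures.

A (transepicondylar width), B (medial condyle anterior-posterior depth) and
C (lateral condyle anterior-posterior depth) are 3D Euclidean distances
between named landmark pairs:

    A = |ME - LE|,  B = |MA - MP|,  C = |LA - LP|

where ME/LE are the medial/lateral epicondyles and MA/MP (LA/LP) are the
anterior/posterior extremes of the medial (lateral) condyle. Landmarks are
operator-placed inputs (JSON annotation files); this module never tries to
detect them automatically.

Mirroring keeps anatomical names: reflecting a left-side landmark set across
the sagittal plane yields right-side geometry, and "medial" remains medial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError
from .mesh_core import MirrorPlane, RigidTransform, mirror_points

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkSet",
    "ABCMeasurement",
    "compute_abc",
    "mirror_landmarks",
    "transform_landmarks",
    "read_landmarks",
    "write_landmarks",
]

LANDMARK_NAMES = ("ME", "LE", "MA", "MP", "LA", "LP")


@dataclass
class LandmarkSet:
    """Exactly the six named anatomical points, in mm."""

    points: dict

    def __post_init__(self) -> None:
        pts = {}
        for name, value in self.points.items():
            arr = np.asarray(value, dtype=np.float64).reshape(-1)
            if arr.shape != (3,) or not np.isfinite(arr).all():
                raise ValidationError(f"landmark {name!r} must be a finite 3-vector")
            pts[name] = arr
        missing = [n for n in LANDMARK_NAMES if n not in pts]
        if missing:
            raise ValidationError(f"missing landmarks: {', '.join(missing)}")
        extra = [n for n in pts if n not in LANDMARK_NAMES]
        if extra:
            raise ValidationError(f"unknown landmarks: {', '.join(sorted(extra))}")
        self.points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def as_array(self) -> np.ndarray:
        """(6, 3) array in canonical name order ME, LE, MA, MP, LA, LP."""
        return np.stack([self.points[n] for n in LANDMARK_NAMES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=np.float64)
        return cls(dict(zip(LANDMARK_NAMES, arr)))


@dataclass
class ABCMeasurement:
    a_mm: float
    b_mm: float
    c_mm: float

    def __post_init__(self) -> None:
        for name in ("a_mm", "b_mm", "c_mm"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
            setattr(self, name, v)

    def as_array(self) -> np.ndarray:
        return np.array([self.a_mm, self.b_mm, self.c_mm])


def compute_abc(landmarks: LandmarkSet) -> ABCMeasurement:
    """The three screening measures as 3D Euclidean landmark-pair distances."""
    p = landmarks.points
    return ABCMeasurement(
        a_mm=float(np.linalg.norm(p["ME"] - p["LE"])),
        b_mm=float(np.linalg.norm(p["MA"] - p["MP"])),
        c_mm=float(np.linalg.norm(p["LA"] - p["LP"])),
    )


def mirror_landmarks(landmarks: LandmarkSet, plane: MirrorPlane) -> LandmarkSet:
    """Reflect every landmark; names are kept (medial stays medial)."""
    arr = mirror_points(landmarks.as_array(), plane)
    return LandmarkSet.from_array(arr)


def transform_landmarks(landmarks: LandmarkSet, t: RigidTransform) -> LandmarkSet:
    return LandmarkSet.from_array(t.apply(landmarks.as_array()))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a JSON file mapping the six landmark names to [x, y, z] in mm."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read landmark file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"landmark file {path} must be a JSON object")
    return LandmarkSet(data)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {n: [float(v) for v in landmarks[n]] for n in LANDMARK_NAMES}
    path.write_text(json.dumps(payload, indent=2) + "\n")
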