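"""The virtual bone bank table and its ABC size-screening query.

Screening is the cheap first stage of donor selection: rank the bank by
distance between donor and host (A, B, C) measurements and forward the
closest few candidates to full surface matching. The default metric is the
(optionally weighted) Euclidean distance in ABC space; a max-absolute-delta
metric is available for callers who think in per-measure tolerances.

By default screening matches donors of the same chirality as the host's
resected side — the healthy side is mirrored precisely to obtain
resected-side geometry — and a flag relaxes this.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyResultWarning, FormatError, ParameterError, ValidationError
from .landmarks_abc import ABCMeasurement

__all__ = [
    "BankRecord",
    "BankIndex",
    "ScreeningEntry",
    "ScreeningResult",
    "build_index",
    "read_bank_csv",
    "write_bank_csv",
    "screen",
]

BANK_CSV_COLUMNS = ["donor_id", "side", "bone", "a_mm", "b_mm", "c_mm",
                    "mesh_path", "landmarks_path"]


@dataclass
class BankRecord:
    donor_id: str
    side: str
    bone: str
    abc: ABCMeasurement
    mesh_path: str | None = None
    landmarks_path: str | None = None

    def __post_init__(self) -> None:
        if not self.donor_id:
            raise ValidationError("donor_id must be non-empty")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class BankIndex:
    records: list
    base_dir: Path | None = None
    _by_id: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {r.donor_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, donor_id: str) -> BankRecord:
        return self._by_id[donor_id]

    def __contains__(self, donor_id: str) -> bool:
        return donor_id in self._by_id

    def resolve_path(self, rel: str) -> Path:
        p = Path(rel)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p


@dataclass
class ScreeningEntry:
    donor_id: str
    abc_distance_mm: float
    delta_a_mm: float
    delta_b_mm: float
    delta_c_mm: float


@dataclass
class ScreeningResult:
    """Donor candidates sorted ascending by ABC distance, ties by donor_id."""

    entries: list

    def __len__(self) -> int:
        return len(self.entries)

    def donor_ids(self) -> list:
        return [e.donor_id for e in self.entries]


def build_index(records, base_dir: str | Path | None = None) -> BankIndex:
    """Validate records (unique ids, valid measurements) into a searchable index."""
    records = list(records)
    if len(records) < 1:
        raise ValidationError("a bank needs at least one record")
    seen = set()
    for r in records:
        if not isinstance(r, BankRecord):
            raise ValidationError(f"not a BankRecord: {r!r}")
        if r.donor_id in seen:
            raise ValidationError(f"duplicate donor_id: {r.donor_id!r}")
        seen.add(r.donor_id)
    return BankIndex(records, base_dir=None if base_dir is None else Path(base_dir))


def read_bank_csv(path: str | Path) -> BankIndex:
    """Load a bank table; mesh/landmark paths resolve relative to the CSV."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"bank CSV not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"donor_id": str})
    except Exception as exc:
        raise FormatError(f"cannot parse bank CSV {path}: {exc}") from exc
    missing = [c for c in BANK_CSV_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise FormatError(f"bank CSV {path} lacks columns: {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(BankRecord(
            donor_id=str(d["donor_id"]), side=str(d["side"]), bone=str(d["bone"]),
            abc=ABCMeasurement(float(d["a_mm"]), float(d["b_mm"]), float(d["c_mm"])),
            mesh_path=None if pd.isna(d.get("mesh_path")) else str(d["mesh_path"]),
            landmarks_path=None if pd.isna(d.get("landmarks_path")) else str(d["landmarks_path"]),
        ))
    return build_index(records, base_dir=path.parent)


def write_bank_csv(index: BankIndex, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(BANK_CSV_COLUMNS)
        for r in index.records:
            writer.writerow([r.donor_id, r.side, r.bone, repr(r.abc.a_mm),
                             repr(r.abc.b_mm), repr(r.abc.c_mm),
                             r.mesh_path or "", r.landmarks_path or ""])


def screen(index: BankIndex, host_abc: ABCMeasurement, k: int = 5,
           weights=(1.0, 1.0, 1.0), side: str | None = None,
           bone: str | None = None, metric: str = "euclidean") -> ScreeningResult:
    """Rank donors by ABC distance to the host and return the top ``k``.

    distance = sqrt(w_a dA^2 + w_b dB^2 + w_c dC^2) (metric='euclidean'), or
    max(w_i |d_i|) (metric='max_abs'). Ordering is deterministic: ascending
    distance, ties broken lexicographically by donor_id.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    w = np.asarray(weights, dtype=np.float64).reshape(3)
    if (w <= 0).any():
        raise ParameterError("weights must all be > 0")
    if metric not in ("euclidean", "max_abs"):
        raise ParameterError(f"unknown metric {metric!r}")

    candidates = [r for r in index.records
                  if (side is None or r.side == side)
                  and (bone is None or r.bone == bone)]
    if not candidates:
        warnings.warn("no donors pass the screening filters",
                      EmptyResultWarning, stacklevel=2)
        return ScreeningResult([])

    host = host_abc.as_array()
    deltas = np.stack([r.abc.as_array() for r in candidates]) - host
    if metric == "euclidean":
        dist = np.sqrt((w * deltas**2).sum(axis=1))
    else:
        dist = (w * np.abs(deltas)).max(axis=1)

    order = sorted(range(len(candidates)), key=lambda i: (dist[i], candidates[i].donor_id))
    entries = [ScreeningEntry(candidates[i].donor_id, float(dist[i]),
                              float(deltas[i, 0]), float(deltas[i, 1]), float(deltas[i, 2]))
               for i in order[:k]]
    return ScreeningResult(entries)
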