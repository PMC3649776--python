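"""Exact nearest point-on-triangle-mesh queries.

Distances are point-to-triangle (closest point anywhere on a face, not just
at vertices), which is what surface comparison between independently
tessellated bones requires. A KD-tree over triangle centroids prunes
candidates with a provably safe radius, so results equal the exhaustive
point-to-every-triangle minimum to floating-point accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import PreconditionError
from .mesh_core import SurfaceMesh

__all__ = ["closest_point_on_triangles", "MeshQuery"]


def _dot(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", a, b)


def _closest_on_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = _dot(ab, ab)
    t = np.where(denom > 0, _dot(p - a, ab) / np.where(denom > 0, denom, 1.0), 0.0)
    return a + np.clip(t, 0.0, 1.0)[:, None] * ab


def closest_point_on_triangles(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Pairwise closest point on triangle i for point i.

    ``points`` is (n, 3); ``tris`` is (n, 3, 3). Implements the standard
    Voronoi-region case analysis, with a segment-based fallback for
    degenerate (zero-area) triangles.
    """
    p = np.asarray(points, dtype=np.float64)
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = _dot(ab, ap)
    d2 = _dot(ac, ap)
    m = (d1 <= 0) & (d2 <= 0)  # vertex region A
    out[m] = a[m]
    done |= m

    bp = p - b
    d3 = _dot(ab, bp)
    d4 = _dot(ac, bp)
    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex region B
    out[m] = b[m]
    done |= m

    cp = p - c
    d5 = _dot(ab, cp)
    d6 = _dot(ac, cp)
    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex region C
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    if m.any():
        t = d1[m] / (d1[m] - d3[m])
        out[m] = a[m] + t[:, None] * ab[m]
        done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
    if m.any():
        t = d2[m] / (d2[m] - d6[m])
        out[m] = a[m] + t[:, None] * ac[m]
        done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    if m.any():
        t = (d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m]))
        out[m] = b[m] + t[:, None] * (c[m] - b[m])
        done |= m

    m = ~done  # interior
    if m.any():
        denom = va[m] + vb[m] + vc[m]
        ok = denom > 0
        mi = np.flatnonzero(m)
        good = mi[ok]
        v = (vb[good] / denom[ok])[:, None]
        w = (vc[good] / denom[ok])[:, None]
        out[good] = a[good] + v * ab[good] + w * ac[good]
        # degenerate triangles: closest point lies on one of the edges
        bad = mi[~ok]
        if len(bad):
            cands = np.stack([
                _closest_on_segment(p[bad], a[bad], b[bad]),
                _closest_on_segment(p[bad], b[bad], c[bad]),
                _closest_on_segment(p[bad], a[bad], c[bad]),
            ])
            d = np.linalg.norm(cands - p[bad], axis=2)
            out[bad] = cands[np.argmin(d, axis=0), np.arange(len(bad))]
    return out


class MeshQuery:
    """Reusable exact nearest-surface-point query structure for one mesh.

    Build once per target mesh; ``query`` maps arbitrary points to their
    closest surface points, distances, and owning face indices.
    """

    def __init__(self, mesh: SurfaceMesh):
        if mesh.n_faces == 0:
            raise PreconditionError("cannot build distance query for an empty mesh")
        self.mesh = mesh
        self._tris = mesh.triangles
        self._centroids = self._tris.mean(axis=1)
        # triangle circumscribing radius about the centroid: bounds how much
        # closer a triangle can be than its centroid
        self._radius = np.linalg.norm(
            self._tris - self._centroids[:, None, :], axis=2).max(axis=1)
        self._rmax = float(self._radius.max())
        self._tree_centroids = cKDTree(self._centroids)
        self._tree_vertices = cKDTree(mesh.vertices)

    def query(self, points: np.ndarray, chunk: int = 20000):
        """Return (distances, closest_points, face_indices) for each point.

        Candidate faces per point are all faces whose centroid lies within
        (nearest-vertex distance + max triangle radius): any face closer
        than the current best must contain a point within the nearest-vertex
        bound, hence its centroid is inside that ball — so the pruned search
        is exact.
        """
        pts = np.asarray(points, dtype=np.float64)
        squeeze = pts.ndim == 1
        pts = np.atleast_2d(pts)
        n = len(pts)
        dist = np.empty(n)
        closest = np.empty((n, 3))
        fidx = np.empty(n, dtype=np.int64)
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            self._query_block(pts[lo:hi], dist[lo:hi], closest[lo:hi], fidx[lo:hi])
        if squeeze:
            return dist[0], closest[0], fidx[0]
        return dist, closest, fidx

    def _query_block(self, pts, dist_out, closest_out, fidx_out):
        d_ub, _ = self._tree_vertices.query(pts)
        radii = d_ub + self._rmax + 1e-9
        cand = self._tree_centroids.query_ball_point(pts, radii)
        counts = np.fromiter((len(c) for c in cand), dtype=np.int64, count=len(pts))
        tflat = np.fromiter((t for c in cand for t in c), dtype=np.int64,
                            count=int(counts.sum()))
        pflat = np.repeat(np.arange(len(pts)), counts)
        cp = closest_point_on_triangles(pts[pflat], self._tris[tflat])
        d = np.linalg.norm(cp - pts[pflat], axis=1)
        # first-minimum per point via a stable lexical sort
        order = np.lexsort((d, pflat))
        first = np.searchsorted(pflat[order], np.arange(len(pts)))
        best = order[first]
        dist_out[:] = d[best]
        closest_out[:] = cp[best]
        fidx_out[:] = tflat[best]
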