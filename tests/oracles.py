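"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithms from the package: the
point-triangle closest point is computed as the minimum over the in-plane
projection (when its barycentric coordinates are interior) and the three
edge segments, and nearest-on-mesh is an exhaustive scan of every triangle.
"""

import numpy as np


def _closest_on_segment(p, a, b):
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return a
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    return a + t * ab


def point_triangle_distance_oracle(p, tri):
    """Min distance from a point to one triangle: plane projection + edges."""
    a, b, c = tri
    candidates = [_closest_on_segment(p, a, b), _closest_on_segment(p, b, c),
                  _closest_on_segment(p, a, c)]
    n = np.cross(b - a, c - a)
    n2 = float(n @ n)
    if n2 > 0:
        proj = p - ((p - a) @ n) / n2 * n
        v0, v1, v2 = c - a, b - a, proj - a
        d00, d01, d02 = float(v0 @ v0), float(v0 @ v1), float(v0 @ v2)
        d11, d12 = float(v1 @ v1), float(v1 @ v2)
        den = d00 * d11 - d01 * d01
        if den > 0:
            u = (d11 * d02 - d01 * d12) / den
            v = (d00 * d12 - d01 * d02) / den
            if u >= 0 and v >= 0 and u + v <= 1:
                candidates.append(proj)
    return min(np.linalg.norm(p - q) for q in candidates)


def surface_distance_oracle(points, triangles):
    """Exhaustive point-to-every-triangle minimum distance."""
    return np.array([min(point_triangle_distance_oracle(p, t) for t in triangles)
                     for p in points])


def surface_distance_oracle_vectorized(points, triangles):
    """Exhaustive nearest-distance scan, vectorized over triangles per point.

    Same mathematics as :func:`surface_distance_oracle` (plane projection
    when interior + three edge segments), kept independent of the package's
    Voronoi-region implementation.
    """
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]
    n = np.cross(b - a, c - a)
    n2 = np.einsum("ij,ij->i", n, n)
    edges = [(a, b), (b, c), (a, c)]
    edge_dir = [(e1 - e0) for e0, e1 in edges]
    edge_len2 = [np.maximum(np.einsum("ij,ij->i", d, d), 1e-300) for d in edge_dir]
    v0, v1 = c - a, b - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    den = d00 * d11 - d01 * d01

    out = np.empty(len(points))
    for i, p in enumerate(points):
        best = np.full(len(a), np.inf)
        for (e0, _), d, l2 in zip(edges, edge_dir, edge_len2):
            t = np.clip(np.einsum("ij,ij->i", p - e0, d) / l2, 0.0, 1.0)
            q = e0 + t[:, None] * d
            best = np.minimum(best, np.linalg.norm(p - q, axis=1))
        valid = n2 > 0
        proj = p - ((np.einsum("ij,ij->i", p - a, n) / np.where(valid, n2, 1.0))[:, None] * n)
        v2 = proj - a
        d02 = np.einsum("ij,ij->i", v0, v2)
        d12 = np.einsum("ij,ij->i", v1, v2)
        ok = valid & (den > 0)
        u = np.where(ok, (d11 * d02 - d01 * d12) / np.where(ok, den, 1.0), -1.0)
        v = np.where(ok, (d00 * d12 - d01 * d02) / np.where(ok, den, 1.0), -1.0)
        interior = ok & (u >= 0) & (v >= 0) & (u + v <= 1)
        plane_d = np.where(interior, np.linalg.norm(p - proj, axis=1), np.inf)
        out[i] = min(best.min(), plane_d.min())
    return out


def screening_oracle(host_abc, donor_abcs, donor_ids, weights=(1.0, 1.0, 1.0)):
    """Exhaustive weighted-Euclidean ABC ranking with lexicographic tie-break."""
    w = np.asarray(weights, float)
    host = np.asarray(host_abc, float)
    dists = [float(np.sqrt((w * (np.asarray(d, float) - host) ** 2).sum()))
             for d in donor_abcs]
    return sorted(zip(donor_ids, dists), key=lambda x: (x[1], x[0]))
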