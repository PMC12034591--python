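"""Point-to-triangle-mesh distance queries.

Vectorized closest-point-on-triangle (the standard region-classification
algorithm) with a KD-tree candidate prefilter over triangle centroids.
These queries drive the point-to-surface residuals of the registration
objective; the brute-force path over all triangles is kept as a public
function because small problems use it directly and tests use it as an
oracle for the prefiltered path.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, tri_vertices: np.ndarray) -> np.ndarray:
    """Closest point on triangle i to point i (paired, vectorized).

    Parameters
    ----------
    points : (P, 3)
    tri_vertices : (P, 3, 3) — triangle corners a, b, c per point

    Returns
    -------
    (P, 3) closest points.
    """
    p = np.asarray(points, dtype=float)
    a = tri_vertices[:, 0]
    b = tri_vertices[:, 1]
    c = tri_vertices[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge regions
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def nearest_triangles_brute(points: np.ndarray, nodes: np.ndarray, tris: np.ndarray):
    """Exact nearest triangle per point by scanning every triangle.

    Returns ``(tri_idx, closest_pts, dists)``. Ties broken by lowest
    triangle index (argmin convention). O(P*T); fine for small meshes and
    used as the oracle for the prefiltered query.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    P, T = len(points), len(tris)
    tv = nodes[tris]  # (T, 3, 3)
    best_d = np.full(P, np.inf)
    best_i = np.zeros(P, dtype=np.int64)
    best_c = np.zeros((P, 3))
    # chunk over triangles to bound memory
    chunk = max(1, int(4e6 // max(P, 1)))
    for s in range(0, T, chunk):
        e = min(T, s + chunk)
        n_t = e - s
        pp = np.repeat(points, n_t, axis=0)
        tt = np.tile(tv[s:e], (P, 1, 1))
        cp = closest_point_on_triangles(pp, tt).reshape(P, n_t, 3)
        d = np.linalg.norm(cp - points[:, None, :], axis=2)
        j = np.argmin(d, axis=1)
        dj = d[np.arange(P), j]
        upd = dj < best_d - 1e-15
        best_d[upd] = dj[upd]
        best_i[upd] = j[upd] + s
        best_c[upd] = cp[np.arange(P), j][upd]
    return best_i, best_c, best_d


class SurfaceDistanceQuery:
    """Nearest-surface-triangle queries against a fixed triangulation.

    Uses a KD-tree on triangle centroids to shortlist ``k`` candidate
    triangles per point, then the exact closest-point computation on the
    shortlist. Falls back to the brute-force scan for small meshes, where
    it is both exact and fast.
    """

    def __init__(self, nodes: np.ndarray, tris: np.ndarray, k: int = 32,
                 brute_below: int = 200):
        if len(tris) == 0:
            raise ValueError("empty surface triangulation")
        self.nodes = np.asarray(nodes, dtype=float)
        self.tris = np.asarray(tris, dtype=np.int64)
        self.k = min(k, len(tris))
        self.brute = len(tris) <= brute_below
        if not self.brute:
            self._tree = cKDTree(self.nodes[self.tris].mean(axis=1))

    def query(self, points: np.ndarray):
        """Return ``(tri_idx, closest_pts, dists)`` for each query point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.brute:
            return nearest_triangles_brute(points, self.nodes, self.tris)
        _, cand = self._tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        P, K = cand.shape
        pp = np.repeat(points, K, axis=0)
        tv = self.nodes[self.tris[cand.ravel()]]
        cp = closest_point_on_triangles(pp, tv).reshape(P, K, 3)
        d = np.linalg.norm(cp - points[:, None, :], axis=2)
        # ties (edge/vertex-equidistant triangles) break toward the lowest
        # triangle index, matching the brute-force scan
        dmin = d.min(axis=1, keepdims=True)
        tied = d <= dmin * (1 + 1e-12) + 1e-12
        masked = np.where(tied, cand, np.iinfo(np.int64).max)
        pick_tri = masked.min(axis=1)
        j = np.argmax(masked == pick_tri[:, None], axis=1)
        ar = np.arange(P)
        return cand[ar, j], cp[ar, j], d[ar, j]


def triangle_barycentric(tri_vertices: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Barycentric weights of points w.r.t. paired triangles (P, 3, 3)."""
    a, b, c = tri_vertices[:, 0], tri_vertices[:, 1], tri_vertices[:, 2]
    v0, v1, v2 = b - a, c - a, points - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    return np.column_stack([1.0 - v - w, v, w])
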