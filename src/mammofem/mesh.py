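"""Labeled tetrahedral meshes and the geometric utilities built on them.

The central container is :class:`LabeledTetMesh`: a tetrahedral breast model
with per-element tissue labels, an extracted (outward-oriented) boundary
triangulation, and the node sets that drive the mechanics — the fixed chest
midline strip, the chest-side contact candidates, and the ordered
inframammary-fold endpoint chain used by the anchoring structure.

All coordinates are millimetres in a right-handed patient frame; the
anterior direction (away from the chest wall) is +z by convention of the
phantom module, and gravity is supplied explicitly wherever it matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree


class TissueLabel(IntEnum):
    SKIN = 0
    SUPERFICIAL_ADIPOSE = 1
    GLAND = 2
    DEEP_ADIPOSE = 3
    TUMOR = 4


LABEL_NAMES = {
    TissueLabel.SKIN: "skin",
    TissueLabel.SUPERFICIAL_ADIPOSE: "superficial_adipose",
    TissueLabel.GLAND: "gland",
    TissueLabel.DEEP_ADIPOSE: "deep_adipose",
    TissueLabel.TUMOR: "tumor",
}


class MeshError(ValueError):
    """Raised for invalid or degenerate mesh input."""


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def orient_tets(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Return tets with vertex order flipped where needed so volumes > 0."""
    tets = np.asarray(tets).copy()
    vol = tet_volumes(nodes, tets)
    neg = vol < 0
    tets[neg, 1], tets[neg, 2] = tets[neg, 2], tets[neg, 1].copy()
    return tets


def extract_surface(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Boundary triangles of a tet mesh, oriented outward.

    A face is on the boundary iff it belongs to exactly one tetrahedron.
    Orientation: for face (a, b, c) with opposite vertex d in its owning
    tet, the outward normal satisfies ((b-a) x (c-a)) . (d-a) < 0.
    """
    # local faces with the opposite vertex recorded
    faces_local = np.array([[1, 2, 3, 0], [0, 3, 2, 1], [0, 1, 3, 2], [0, 2, 1, 3]])
    faces = tets[:, faces_local.reshape(-1)].reshape(-1, 4)
    tri, opp = faces[:, :3], faces[:, 3]
    key = np.sort(tri, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    bidx = first[counts == 1]
    tri, opp = tri[bidx], opp[bidx]
    n = np.cross(nodes[tri[:, 1]] - nodes[tri[:, 0]], nodes[tri[:, 2]] - nodes[tri[:, 0]])
    inward = np.einsum("ij,ij->i", n, nodes[opp] - nodes[tri[:, 0]]) > 0
    tri[inward] = tri[inward][:, [0, 2, 1]]
    return tri


def triangle_normals(nodes: np.ndarray, tris: np.ndarray, unit: bool = True) -> np.ndarray:
    n = np.cross(nodes[tris[:, 1]] - nodes[tris[:, 0]], nodes[tris[:, 2]] - nodes[tris[:, 0]])
    if unit:
        ln = np.linalg.norm(n, axis=1, keepdims=True)
        ln[ln == 0] = 1.0
        n = n / ln
    return n


def vertex_normals(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Area-weighted average of incident triangle normals, normalized.

    Returned for every node in ``nodes``; nodes not referenced by any
    triangle get a zero normal.
    """
    fn = triangle_normals(nodes, tris, unit=False)  # area-weighted (2*area*unit)
    vn = np.zeros_like(nodes)
    for k in range(3):
        np.add.at(vn, tris[:, k], fn)
    ln = np.linalg.norm(vn, axis=1, keepdims=True)
    ln[ln == 0] = 1.0
    return vn / ln


@dataclass
class LabeledTetMesh:
    """Tetrahedral breast model with tissue labels and mechanical node sets.

    Attributes
    ----------
    nodes : (N, 3) float array, mm
    tets : (M, 4) int array, positively oriented
    labels : (M,) int array of :class:`TissueLabel`
    surface_tris : (T, 3) int array, outward oriented boundary
    fixed_nodes : int array — Dirichlet set (chest midline strip)
    chest_nodes : int array — chest-side nodes, the contact candidates
    endpoint_chain : int array — ordered inframammary-fold nodes
        (mid-chest end first, axilla end last)
    chest_distance : (N,) float array, mm — distance of each node from the
        chest-wall surface measured along the anterior axis; used by the
        deep-adipose layer assignment
    landmarks : (3, 3) rigid-alignment triplet (right/left sternoclavicular
        joints, lower sternum) in the model frame, or None
    fiducials : (3, 3) prone fiducial positions (nipple, two vessel
        bifurcations), or None
    meta : free-form provenance (phantom parameters, frame notes, ...)
    """

    nodes: np.ndarray
    tets: np.ndarray
    labels: np.ndarray
    surface_tris: np.ndarray
    fixed_nodes: np.ndarray
    chest_nodes: np.ndarray
    endpoint_chain: np.ndarray
    chest_distance: np.ndarray | None = None
    landmarks: np.ndarray | None = None
    fiducials: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.surface_tris = np.asarray(self.surface_tris, dtype=np.int64)
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        self.chest_nodes = np.asarray(self.chest_nodes, dtype=np.int64)
        self.endpoint_chain = np.asarray(self.endpoint_chain, dtype=np.int64)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        n = len(self.nodes)
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= n:
            raise MeshError("tet indices out of range")
        if len(self.labels) != len(self.tets):
            raise MeshError("labels/tets length mismatch")
        vol = tet_volumes(self.nodes, self.tets)
        if (vol <= 0).any():
            bad = int(np.argmin(vol))
            raise MeshError(f"non-positive tet volume at element {bad}")
        if self.fixed_nodes.size == 0:
            raise MeshError("fixed_nodes is empty; rigid modes unconstrained")
        unknown = ~np.isin(self.labels, [int(t) for t in TissueLabel])
        if unknown.any():
            raise MeshError(f"unknown tissue label at element {int(np.argmax(unknown))}")

    # -- convenience ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def total_volume(self, label: int | None = None) -> float:
        vol = tet_volumes(self.nodes, self.tets)
        if label is None:
            return float(vol.sum())
        return float(vol[self.labels == label].sum())

    def surface_node_indices(self) -> np.ndarray:
        return np.unique(self.surface_tris)


# -- point location and interpolation -----------------------------------

def barycentric_coordinates(nodes, tets, tet_idx, points):
    """Barycentric coordinates of ``points`` in the given tets (per row)."""
    v = nodes[tets[tet_idx]]
    T = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=2)
    rhs = points - v[:, 0]
    lam = np.linalg.solve(T, rhs[..., None])[..., 0]
    return np.concatenate([1.0 - lam.sum(axis=1, keepdims=True), lam], axis=1)


def find_containing_tets(mesh: LabeledTetMesh, points: np.ndarray, k: int = 48):
    """Locate the tetrahedron containing each point.

    Queries the ``k`` nearest element centroids and picks the first
    candidate whose barycentric coordinates are all nonnegative; if a point
    sits just outside the mesh (boundary round-off), the candidate with the
    least-negative coordinate is used.

    Returns ``(tet_indices, bary)`` with ``bary`` of shape (P, 4).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    cent = mesh.element_centroids()
    tree = cKDTree(cent)
    k = min(k, len(cent))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    out_idx = np.empty(len(points), dtype=np.int64)
    out_bary = np.empty((len(points), 4))
    for i, p in enumerate(points):
        ci = cand[i]
        lam = barycentric_coordinates(mesh.nodes, mesh.tets, ci, np.repeat(p[None], len(ci), 0))
        score = lam.min(axis=1)
        j = int(np.argmax(score))
        inside = np.nonzero(score >= -1e-10)[0]
        if inside.size:
            j = int(inside[0])
        out_idx[i] = ci[j]
        out_bary[i] = lam[j]
    return out_idx, out_bary


def interpolate_displacement(mesh: LabeledTetMesh, u: np.ndarray, points: np.ndarray,
                             location=None) -> np.ndarray:
    """Barycentric interpolation of a nodal field ``u`` (N, 3) at points.

    ``location`` may carry a precomputed ``(tet_idx, bary)`` pair from
    :func:`find_containing_tets` to avoid repeated point location.
    """
    u = np.asarray(u, dtype=float).reshape(-1, 3)
    if location is None:
        location = find_containing_tets(mesh, points)
    tet_idx, bary = location
    verts = mesh.tets[tet_idx]
    return np.einsum("pk,pkd->pd", bary, u[verts])


# -- structured test geometry -------------------------------------------

def structured_block(nx: int, ny: int, nz: int, lx: float = 1.0, ly: float = 1.0,
                     lz: float = 1.0):
    """Structured tetrahedral block: each grid cell split into 6 tets.

    Returns ``(nodes, tets)``; used for patch tests and oracles.
    """
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # Kuhn triangulation of the unit cube (6 tets sharing the main diagonal)
    kuhn = [(0, 1, 3, 7), (0, 3, 2, 7), (0, 2, 6, 7),
            (0, 6, 4, 7), (0, 4, 5, 7), (0, 5, 1, 7)]
    corner = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
              (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ids = [nid(i + di, j + dj, k + dk) for (di, dj, dk) in corner]
                for t in kuhn:
                    tets.append([ids[v] for v in t])
    tets = orient_tets(nodes, np.asarray(tets, dtype=np.int64))
    return nodes, tets
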