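"""Shared fixtures: small phantoms, icospheres, and block meshes."""

import numpy as np
import pytest

import mammofem as mf
from mammofem.mesh import orient_tets


@pytest.fixture(scope="session")
def small_phantom():
    """~500-node phantom reused by the heavier integration tests."""
    params = mf.PhantomParams(target_node_count=500, seed=2)
    return params, mf.generate_breast_phantom(params)


@pytest.fixture(scope="session")
def default_phantom():
    """Default-size phantom (the published node-count range)."""
    params = mf.PhantomParams()
    return params, mf.generate_breast_phantom(params)


def make_icosphere(subdivisions: int = 2, radius: float = 1.0):
    """Icosphere triangulation (vertices, faces) built by edge subdivision."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    for _ in range(subdivisions):
        cache = {}
        verts_list = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = (np.array(verts_list[i]) + np.array(verts_list[j])) / 2.0
                m /= np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(tuple(m))
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
        verts = verts_list
    v = np.array(verts) * radius
    return v, np.array(faces, dtype=np.int64)


@pytest.fixture
def icosphere():
    return make_icosphere


def two_tet_mesh():
    """Two tetrahedra sharing a face; the smallest assembly exercise."""
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [1, 1, 1]])
    tets = orient_tets(nodes, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]))
    return nodes, tets
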