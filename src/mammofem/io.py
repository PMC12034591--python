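"""Plain-text mesh and point-cloud I/O.

Meshes are exchanged as legacy ASCII VTK unstructured grids (with tissue
labels as cell data and optional displacement point data) or Gmsh 2.2
ASCII; surfaces as ASCII PLY; point clouds as PLY or CSV with an x,y,z
header (mm). A YAML sidecar records the coordinate frame and the
phantom/anchoring metadata needed to rebuild the run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .mesh import LabeledTetMesh


# -- VTK legacy unstructured grid ----------------------------------------

def save_vtk(path, mesh: LabeledTetMesh, displacement: np.ndarray | None = None,
             title: str = "mammofem mesh") -> None:
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_elements
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {n} double"]
    lines += [" ".join(f"{v:.17g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in mesh.tets]
    lines.append(f"CELL_TYPES {m}")
    lines += ["10"] * m
    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS tissue_label int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(l)) for l in mesh.labels]
    if displacement is not None:
        u = np.asarray(displacement, float).reshape(n, 3)
        lines.append(f"POINT_DATA {n}")
        lines.append("VECTORS displacement double")
        lines += [" ".join(f"{v:.17g}" for v in row) for row in u]
    path.write_text("\n".join(lines) + "\n")


def load_vtk(path):
    """Read nodes, tets, labels (and displacement if present) back."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    nodes = tets = labels = disp = None
    for line in it:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "POINTS":
            cnt = int(parts[1])
            nodes = np.array([[float(v) for v in next(it).split()]
                              for _ in range(cnt)])
        elif parts[0] == "CELLS":
            cnt = int(parts[1])
            tets = np.array([[int(v) for v in next(it).split()[1:]]
                             for _ in range(cnt)], dtype=np.int64)
        elif parts[0] == "SCALARS" and parts[1] == "tissue_label":
            next(it)  # LOOKUP_TABLE
            labels = np.array([int(next(it)) for _ in range(len(tets))],
                              dtype=np.int64)
        elif parts[0] == "VECTORS" and parts[1] == "displacement":
            disp = np.array([[float(v) for v in next(it).split()]
                             for _ in range(len(nodes))])
    return nodes, tets, labels, disp


# -- Gmsh 2.2 ASCII ------------------------------------------------------

def save_msh(path, mesh: LabeledTetMesh) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat",
             "$Nodes", str(mesh.n_nodes)]
    lines += [f"{i + 1} " + " ".join(f"{v:.17g}" for v in p)
              for i, p in enumerate(mesh.nodes)]
    lines += ["$EndNodes", "$Elements", str(mesh.n_elements)]
    # element type 4 = 4-node tetrahedron; physical tag carries the label
    lines += [f"{i + 1} 4 2 {int(mesh.labels[i])} 0 "
              + " ".join(str(v + 1) for v in t)
              for i, t in enumerate(mesh.tets)]
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def load_msh(path):
    text = Path(path).read_text().split("\n")
    i_nodes = text.index("$Nodes")
    n = int(text[i_nodes + 1])
    nodes = np.array([[float(v) for v in text[i_nodes + 2 + k].split()[1:4]]
                      for k in range(n)])
    i_el = text.index("$Elements")
    m = int(text[i_el + 1])
    tets, labels = [], []
    for k in range(m):
        parts = text[i_el + 2 + k].split()
        if parts[1] != "4":
            continue
        ntags = int(parts[2])
        labels.append(int(parts[3]))
        tets.append([int(v) - 1 for v in parts[3 + ntags:7 + ntags]])
    return nodes, np.asarray(tets, np.int64), np.asarray(labels, np.int64)


# -- PLY / CSV point data ------------------------------------------------

def save_ply(path, points: np.ndarray, faces: np.ndarray | None = None) -> None:
    points = np.atleast_2d(points)
    lines = ["ply", "format ascii 1.0", f"element vertex {len(points)}",
             "property double x", "property double y", "property double z"]
    if faces is not None:
        lines += [f"element face {len(faces)}",
                  "property list uchar int vertex_indices"]
    lines.append("end_header")
    lines += [" ".join(f"{v:.17g}" for v in p) for p in points]
    if faces is not None:
        lines += ["3 " + " ".join(str(int(v)) for v in f) for f in faces]
    Path(path).write_text("\n".join(lines) + "\n")


def save_points_csv(path, points: np.ndarray) -> None:
    points = np.atleast_2d(points)
    with open(path, "w") as fh:
        fh.write("x,y,z\n")
        for p in points:
            fh.write(f"{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}\n")


def load_points_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)


# -- sidecars ------------------------------------------------------------

def save_sidecar(path, mesh: LabeledTetMesh) -> None:
    """YAML sidecar: frame declaration, node sets, anchoring chain."""
    params = mesh.meta.get("phantom_params")
    doc = {
        "frame": mesh.meta.get("frame", "right-handed, mm"),
        "gravity_axis": "z (prone +z, supine -z)",
        "fixed_nodes": [int(i) for i in mesh.fixed_nodes],
        "chest_nodes": [int(i) for i in mesh.chest_nodes],
        "anchoring": {
            "endpoint_chain": [int(i) for i in mesh.endpoint_chain],
            "root": [float(v) for v in mesh.meta.get(
                "anchoring_root", np.zeros(3))],
        },
        "landmarks": None if mesh.landmarks is None else mesh.landmarks.tolist(),
        "fiducials": None if mesh.fiducials is None else mesh.fiducials.tolist(),
    }
    if params is not None:
        doc["phantom_params"] = {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in vars(params).items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_anchoring_sidecar(path):
    """Endpoint indices + root from the JSON/CSV/YAML anchoring sidecar."""
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
    else:
        doc = yaml.safe_load(path.read_text())
    anch = doc.get("anchoring", doc)
    return (np.asarray(anch["endpoint_chain"], dtype=np.int64),
            np.asarray(anch["root"], dtype=float))
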