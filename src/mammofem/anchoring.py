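"""Anchoring-structure constraint forces along the inframammary fold.

The deep fascia loosely tethers the breast to the chest wall along the
inframammary fold, from the mid-chest to the axilla. It is modeled as a
root point on the chest wall below the nipple plus an ordered chain of
endpoint nodes on the fold. Two tension-only force families act on each
endpoint i:

* a root-to-endpoint force, active once the root-to-endpoint vector q_i
  exceeds its rest length u0_i:

      f_c = w_a * (|q_i| - u0_i) / (u0_i * |q_i|) * q_i

* a neighbor force for each adjacent endpoint j, active once the
  separation s_ij exceeds its rest separation s0_ij, directed along q_i
  (the membranous fascia pulls in the root direction):

      f_n = w_a * (|s_ij| - |s0_ij|) / (|s0_ij| * |q_i|) * q_i

Both are slack (exactly zero) below rest length. Rest lengths are captured
from the initial, undeformed prone configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AnchoringStructure:
    """Root point, ordered endpoint chain, and rest state.

    ``endpoints`` are mesh node indices ordered along the fold (mid-chest
    end first); ``u0`` are the rest lengths |q_i| and ``s0`` the rest
    separation vectors between consecutive endpoints, both taken from the
    initial configuration.
    """

    root: np.ndarray
    endpoints: np.ndarray
    u0: np.ndarray
    s0: np.ndarray  # (E-1, 3) rest vectors x[i+1] - x[i]
    w_a: float = 1e-4

    def __post_init__(self):
        self.root = np.asarray(self.root, dtype=float)
        self.endpoints = np.asarray(self.endpoints, dtype=np.int64)
        self.u0 = np.asarray(self.u0, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float).reshape(-1, 3)
        if len(np.unique(self.endpoints)) != len(self.endpoints):
            raise ValueError("anchoring endpoints must be distinct")
        if (self.u0 <= 0).any():
            raise ValueError("rest lengths u0 must be positive")
        if len(self.s0) != max(len(self.endpoints) - 1, 0):
            raise ValueError("s0 must have one rest vector per adjacent pair")
        if self.w_a < 0:
            raise ValueError("w_a must be >= 0")


def build_anchoring(mesh, w_a: float = 1e-4, root: np.ndarray | None = None) -> AnchoringStructure:
    """Anchoring structure from a mesh's endpoint chain and stored root.

    The root defaults to the mesh's recorded chest-wall projection of the
    nipple (``mesh.meta['anchoring_root']``).
    """
    if root is None:
        root = np.asarray(mesh.meta.get("anchoring_root"), dtype=float)
        if root is None or root.shape != (3,):
            raise ValueError("mesh carries no anchoring root; pass root=")
    chain = np.asarray(mesh.endpoint_chain, dtype=np.int64)
    if chain.size == 0:
        raise ValueError("mesh has an empty endpoint chain")
    x = mesh.nodes[chain]
    u0 = np.linalg.norm(x - root, axis=1)
    s0 = x[1:] - x[:-1]
    return AnchoringStructure(root=root, endpoints=chain, u0=u0, s0=s0, w_a=w_a)


def root_endpoint_force(q_i: np.ndarray, u0_i: float, w_a: float) -> np.ndarray:
    """Tension-only root-to-endpoint force f_c at one endpoint."""
    if u0_i <= 0:
        raise ValueError("u0 must be positive")
    q = np.asarray(q_i, dtype=float)
    qn = float(np.linalg.norm(q))
    if qn == 0.0 or qn < u0_i:
        # coincident root/endpoint is degenerate: no defined direction
        return np.zeros(3)
    return w_a * (qn - u0_i) / (u0_i * qn) * q


def neighbor_force(s_ij: np.ndarray, s0_ij: np.ndarray, q_i: np.ndarray,
                   w_a: float) -> np.ndarray:
    """Stretch-activated adjacent-endpoint force f_n, directed along q_i."""
    s = np.asarray(s_ij, dtype=float)
    s0 = np.asarray(s0_ij, dtype=float)
    q = np.asarray(q_i, dtype=float)
    sn = float(np.linalg.norm(s))
    s0n = float(np.linalg.norm(s0))
    qn = float(np.linalg.norm(q))
    if s0n <= 0:
        raise ValueError("|s0| must be positive")
    if sn < s0n or qn == 0.0:
        return np.zeros(3)
    return w_a * (sn - s0n) / (s0n * qn) * q


def anchoring_forces(deformed_nodes: np.ndarray, anchor: AnchoringStructure,
                     n_nodes: int | None = None) -> np.ndarray:
    """Total anchoring load vector F_a (3N,).

    Each endpoint receives f_c plus the neighbor forces from its adjacent
    endpoints in the chain; all other nodes receive zero.
    """
    nodes = np.asarray(deformed_nodes, dtype=float)
    if n_nodes is None:
        n_nodes = len(nodes)
    ep = anchor.endpoints
    if ep.max(initial=-1) >= n_nodes:
        raise IndexError("anchoring endpoint index out of mesh range")
    F = np.zeros((n_nodes, 3))
    if anchor.w_a == 0 or ep.size == 0:
        return F.ravel()
    x = nodes[ep]
    q = x - anchor.root
    for i in range(len(ep)):
        f = root_endpoint_force(q[i], anchor.u0[i], anchor.w_a)
        for j in (i - 1, i + 1):
            if 0 <= j < len(ep):
                s = x[j] - x[i]
                s0 = anchor.s0[min(i, j)] * (1.0 if j > i else -1.0)
                f = f + neighbor_force(s, s0, q[i], anchor.w_a)
        F[ep[i]] = f
    if not np.all(np.isfinite(F)):
        raise FloatingPointError("non-finite anchoring force")
    return F.ravel()
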