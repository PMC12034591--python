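"""Penalty contact against a quadric chest-wall surface.

The supine chest wall is represented by a second-order surface fitted to
the chest-wall point cloud. The fit uses an explicit height-field form

    z' = c1 x'^2 + c2 y'^2 + c3 x'y' + c4 x' + c5 y' + c6

in a local frame whose z' axis is the normal of the cloud's best-fit plane;
this avoids the trivial-solution ambiguity of a general implicit quadric.
Penetration of a node is measured along the local z' axis (a vertical
projection rather than a true closest-point search — fast, robust, and its
approximation error is bounded in the tests against a dense-sampling
oracle). Penetrating nodes receive the penalty force

    f_i = w_p * E_i

where E_i is the vector from the node to its projected surface point,
pointing out of the wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ContactError(ValueError):
    pass


@dataclass
class QuadricSurface:
    """Height-field quadric in a local orthonormal frame.

    ``rotation`` rows are the local axes (e1, e2, n) expressed in world
    coordinates; ``origin`` is the cloud centroid. The +n side is outside
    the wall: points with local z' below the surface height penetrate.
    """

    origin: np.ndarray
    rotation: np.ndarray  # (3, 3), rows e1, e2, n
    coefficients: np.ndarray  # (6,) c1..c6
    residual_rms: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ContactError("non-finite quadric coefficients")

    @property
    def inside_direction(self) -> np.ndarray:
        """World direction pointing into the wall (penetration side)."""
        return -self.rotation[2]

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.rotation.T

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        c = self.coefficients
        return c[0] * x * x + c[1] * y * y + c[2] * x * y + c[3] * x + c[4] * y + c[5]

    def surface_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """World-frame points of the surface at local coordinates (x, y)."""
        local = np.column_stack([x, y, self.height(x, y)])
        return local @ self.rotation + self.origin


def _design_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x * x, y * y, x * y, x, y, np.ones_like(x)])


def fit_quadric_surface(chest_points: np.ndarray, outside_hint=None) -> QuadricSurface:
    """Least-squares second-order surface through a chest-wall cloud.

    The local frame comes from the cloud's best-fit plane (SVD); the
    height-field coefficients minimize the squared vertical residuals.
    ``outside_hint`` orients the +n axis (defaults to world +z, the
    anterior direction in the phantom frame).

    Raises :class:`ContactError` for fewer than 6 points or a
    rank-deficient design (e.g. all points on a line).
    """
    pts = np.atleast_2d(np.asarray(chest_points, dtype=float))
    if len(pts) < 6:
        raise ContactError(f"need at least 6 chest points for a quadric fit, "
                           f"got {len(pts)}")
    origin = pts.mean(axis=0)
    centered = pts - origin
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    n = Vt[2]
    hint = np.asarray([0.0, 0.0, 1.0] if outside_hint is None else outside_hint, float)
    if n @ hint < 0:
        n = -n
    e1 = Vt[0]
    e2 = np.cross(n, e1)
    R = np.vstack([e1, e2, n])

    local = centered @ R.T
    A = _design_matrix(local[:, 0], local[:, 1])
    rank = np.linalg.matrix_rank(A)
    if rank < 6:
        raise ContactError(f"rank-deficient quadric design (rank {rank} < 6); "
                           "chest points are degenerate")
    coeffs, res, *_ = np.linalg.lstsq(A, local[:, 2], rcond=None)
    fitted = A @ coeffs
    rms = float(np.sqrt(np.mean((fitted - local[:, 2]) ** 2)))
    return QuadricSurface(origin=origin, rotation=R, coefficients=coeffs,
                          residual_rms=rms)


def penetration(points: np.ndarray, surface: QuadricSurface) -> np.ndarray:
    """Penetration vectors E_i (mm) for each point; zero when outside.

    A point with local height below the surface gets the vector from the
    point up to its vertical projection on the surface (pointing out of
    the wall); its norm is the penetration depth.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    local = surface.to_local(pts)
    h = surface.height(local[:, 0], local[:, 1])
    depth = h - local[:, 2]  # > 0 means below the wall
    depth = np.maximum(depth, 0.0)
    return depth[:, None] * surface.rotation[2][None, :]


def penetration_depth(points: np.ndarray, surface: QuadricSurface) -> np.ndarray:
    return np.linalg.norm(penetration(points, surface), axis=1)


def contact_forces(deformed_nodes: np.ndarray, chest_node_set: np.ndarray,
                   surface: QuadricSurface, w_p: float) -> np.ndarray:
    """Penalty load vector F_p (3N,): w_p * E_i at penetrating chest nodes.

    Only nodes in ``chest_node_set`` (the posterior, chest-side surface)
    are contact candidates; every other node gets zero.
    """
    if w_p < 0:
        raise ValueError("w_p must be >= 0")
    nodes = np.asarray(deformed_nodes, dtype=float)
    F = np.zeros_like(nodes)
    chest = np.asarray(chest_node_set, dtype=np.int64)
    if w_p == 0 or chest.size == 0:
        return F.ravel()
    E = penetration(nodes[chest], surface)
    F[chest] = w_p * E
    return F.ravel()


def calibrate_penalty_weight(max_penetration_fn, target_depth: float = 0.5,
                             powers=range(-2, 5)) -> float:
    """Smallest power of ten for which the equilibrium max penetration
    drops below ``target_depth`` mm.

    ``max_penetration_fn(w_p)`` must run the coupled solve and return the
    max penetration depth. Returns the largest candidate if none meets the
    target (with the caller expected to inspect the run log).
    """
    w = None
    for p in powers:
        w = 10.0 ** p
        if max_penetration_fn(w) < target_depth:
            return w
    return w
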