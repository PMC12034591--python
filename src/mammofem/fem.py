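"""Linear tetrahedral elasticity for the breast model.

Constant-strain (P1) tetrahedra with an isotropic Hooke law, assembled into
a sparse global stiffness. The force balance solved throughout the package
is

    K u = F_g + F_p + F_a + B alpha

with gravity loads F_g, penalty contact forces F_p against the chest-wall
surface, anchoring constraint forces F_a along the inframammary fold, and
an optional observation-driven term (a linear combination of deformation
bases, handled by the registration module).

Units are mm / kPa / mN internally: 1 kPa * 1 mm^2 = 1 mN, and gravity
loads convert (kg/m^3) * (m/s^2) * mm^3 -> mN via the factor 1e-6.

Near-incompressibility (nu = 0.495) causes volumetric locking in pure
displacement P1 elements; this is accepted and documented — mesh
refinement, not a mixed formulation, is the mitigation here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import LabeledTetMesh, TissueLabel, tet_volumes

#: converts density [kg/m^3] * gravity [m/s^2] * volume [mm^3] to mN
GRAVITY_FORCE_SCALE = 1e-6

#: standard gravitational acceleration, m/s^2
STANDARD_GRAVITY = 9.81

DEGENERATE_VOLUME_TOL = 1e-12


class FEMError(RuntimeError):
    pass


@dataclass
class MaterialField:
    """Per-element Young's modulus [kPa] and a global Poisson ratio."""

    E_per_element: np.ndarray
    poisson: float = 0.495

    def __post_init__(self):
        self.E_per_element = np.asarray(self.E_per_element, dtype=float)
        if (self.E_per_element <= 0).any():
            raise ValueError("Young's moduli must be positive")
        if not 0.0 < self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")


@dataclass
class SimulationConfig:
    """Forward-simulation configuration.

    ``gravity_vector`` is the net load change from prone to supine. The
    prone model was acquired loaded by gravity along +z (anterior); turning
    the patient supine reverses it, and since the linear model carries the
    prone pre-stress with it, the net change is 2 g along -z by default
    (1 g is selectable by halving the vector).
    """

    gravity_vector: tuple = (0.0, 0.0, -2 * STANDARD_GRAVITY)  # m/s^2
    tissue_density: float = 1000.0  # kg/m^3
    w_p: float = 100.0  # contact penalty weight, mN/mm per node (calibrated)
    w_a: float = 1e-4  # anchoring weight
    E_deep: float = 0.83  # deep-adipose Young's modulus, kPa
    outer_iterations: int = 80
    convergence_tol: float = 0.01  # mm, max nodal update between iterations
    relaxation: float = 0.5  # under-relaxation of the contact/anchoring loop

    def __post_init__(self):
        if self.tissue_density < 0:
            raise ValueError("tissue_density must be >= 0")
        if self.w_p < 0 or self.w_a < 0:
            raise ValueError("penalty and anchoring weights must be >= 0")


# -- material assignment -------------------------------------------------

def assign_tissue_stiffness(mesh: LabeledTetMesh, E_skin: float = 4.0,
                            E_gland: float = 9.75, E_deep: float = 0.83,
                            deep_layer_thickness: float | None = None,
                            poisson: float = 0.495) -> MaterialField:
    """Map tissue labels to Young's moduli (the semi-fluid layering).

    Skin gets ``E_skin``; gland and superficial adipose share ``E_gland``
    (the superficial fascial system binds them); the tumor is not assigned
    its own stiffness and defaults to the gland's; adipose within the deep
    layer against the chest wall gets the reduced ``E_deep`` that models
    fluid-like mobility.

    If ``deep_layer_thickness`` is given, the deep layer is re-derived
    geometrically: adipose elements whose centroid lies within that
    distance of the chest-wall surface get ``E_deep`` (thickness 0 means no
    element does). Otherwise the mesh's stored labels decide.
    """
    labels = mesh.labels
    known = np.isin(labels, [int(t) for t in TissueLabel])
    if not known.all():
        raise ValueError(f"unknown tissue label at element {int(np.argmax(~known))}")

    E = np.empty(len(labels), dtype=float)
    E[labels == TissueLabel.SKIN] = E_skin
    E[labels == TissueLabel.GLAND] = E_gland
    E[labels == TissueLabel.TUMOR] = E_gland
    E[labels == TissueLabel.SUPERFICIAL_ADIPOSE] = E_gland
    E[labels == TissueLabel.DEEP_ADIPOSE] = E_deep

    if deep_layer_thickness is not None:
        if deep_layer_thickness < 0:
            raise ValueError("deep_layer_thickness must be >= 0")
        if mesh.chest_distance is None:
            raise ValueError("mesh lacks chest_distance; cannot re-derive deep layer")
        cdist = mesh.chest_distance[mesh.tets].mean(axis=1)
        adipose = np.isin(labels, [TissueLabel.DEEP_ADIPOSE, TissueLabel.SUPERFICIAL_ADIPOSE])
        deep = adipose & (cdist < deep_layer_thickness)
        E[adipose] = E_gland
        E[deep] = E_deep
    return MaterialField(E, poisson)


# -- element and global stiffness ----------------------------------------

def isotropic_elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 Hooke matrix in Voigt order (xx, yy, zz, xy, yz, zx)."""
    c = E / ((1 + nu) * (1 - 2 * nu))
    D = np.zeros((6, 6))
    D[:3, :3] = c * nu
    D[np.arange(3), np.arange(3)] = c * (1 - nu)
    D[np.arange(3, 6), np.arange(3, 6)] = c * (1 - 2 * nu) / 2.0
    return D


def _shape_gradients(tet_coords: np.ndarray):
    """Gradients of the 4 linear shape functions and the tet volume."""
    a = np.asarray(tet_coords, dtype=float)
    J = a[1:] - a[0]  # rows: edge vectors
    vol = np.linalg.det(J) / 6.0
    if vol <= DEGENERATE_VOLUME_TOL:
        raise FEMError(f"degenerate tetrahedron (volume {vol:.3e} mm^3)")
    g = np.empty((4, 3))
    g[1:] = np.linalg.inv(J).T  # rows are grad(lambda_2..4)
    g[0] = -g[1:].sum(axis=0)
    return g, vol


def _strain_matrix(grads: np.ndarray) -> np.ndarray:
    """6x12 B matrix from shape-function gradients (engineering shear)."""
    B = np.zeros((6, 12))
    for i in range(4):
        gx, gy, gz = grads[i]
        c = 3 * i
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def element_stiffness(tet_coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness of a constant-strain tetrahedron: V * B^T D B."""
    grads, vol = _shape_gradients(tet_coords)
    B = _strain_matrix(grads)
    D = isotropic_elasticity_matrix(E, nu)
    return vol * (B.T @ D @ B)


def assemble_stiffness(mesh: LabeledTetMesh, materials: MaterialField) -> sp.csr_matrix:
    """Assemble the global sparse stiffness matrix (3N x 3N)."""
    if len(materials.E_per_element) != mesh.n_elements:
        raise ValueError("materials/elements length mismatch")
    nodes, tets = mesh.nodes, mesh.tets
    M = len(tets)
    nu = materials.poisson

    # vectorized shape gradients for all elements
    a = nodes[tets]  # (M, 4, 3)
    J = a[:, 1:] - a[:, :1]  # (M, 3, 3)
    vol = np.linalg.det(J) / 6.0
    if (vol <= DEGENERATE_VOLUME_TOL).any():
        bad = int(np.argmin(vol))
        raise FEMError(f"degenerate tetrahedron at element {bad} "
                       f"(volume {vol[bad]:.3e} mm^3)")
    invJ = np.linalg.inv(J)  # (M, 3, 3)
    g = np.empty((M, 4, 3))
    g[:, 1:] = np.transpose(invJ, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)

    B = np.zeros((M, 6, 12))
    for i in range(4):
        gx, gy, gz = g[:, i, 0], g[:, i, 1], g[:, i, 2]
        c = 3 * i
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx

    D0 = isotropic_elasticity_matrix(1.0, nu)
    scale = materials.E_per_element * vol  # linear in E
    Ke = np.einsum("m,mki,kl,mlj->mij", scale, B, D0, B, optimize=True)

    dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(M, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes,) * 2)
    return K.tocsr()


# -- loads ---------------------------------------------------------------

def gravity_load(mesh: LabeledTetMesh, density: float, g) -> np.ndarray:
    """Consistent body load: rho * V * g per element, V/4 to each node [mN].

    ``density`` in kg/m^3, ``g`` in m/s^2, volumes in mm^3; the returned
    nodal forces are in mN (the mm-kPa unit system).
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    g = np.asarray(g, dtype=float)
    F = np.zeros((mesh.n_nodes, 3))
    if density == 0 or not g.any():
        return F.ravel()
    vol = tet_volumes(mesh.nodes, mesh.tets)
    fe = (density * GRAVITY_FORCE_SCALE / 4.0) * vol[:, None] * g[None, :]
    for k in range(4):
        np.add.at(F, mesh.tets[:, k], fe)
    return F.ravel()


# -- solve ---------------------------------------------------------------

def _free_dof_mask(n_nodes: int, fixed_nodes: np.ndarray) -> np.ndarray:
    mask = np.ones(3 * n_nodes, dtype=bool)
    idx = (3 * np.asarray(fixed_nodes, dtype=np.int64)[:, None] + np.arange(3)).ravel()
    mask[idx] = False
    return mask


def solve_displacement(K: sp.spmatrix, F_total: np.ndarray,
                       fixed_nodes: np.ndarray) -> np.ndarray:
    """Solve K u = F with homogeneous Dirichlet conditions on fixed nodes.

    Dirichlet dofs are removed by row/column elimination. Raises
    :class:`FEMError` if the reduced system is singular (typically an
    insufficient fixed boundary).
    """
    fixed_nodes = np.asarray(fixed_nodes, dtype=np.int64)
    if fixed_nodes.size == 0:
        raise FEMError("fixed_nodes is empty; the system has rigid modes — "
                       "check the boundary conditions")
    n3 = K.shape[0]
    mask = _free_dof_mask(n3 // 3, fixed_nodes)
    Kred = K[mask][:, mask].tocsc()
    Fred = np.asarray(F_total, dtype=float).ravel()[mask]
    u = np.zeros(n3)
    if not np.any(Fred):
        return u
    try:
        ured = spla.spsolve(Kred, Fred)
    except RuntimeError as exc:  # pragma: no cover - singular factor
        raise FEMError(f"singular reduced stiffness ({exc}); check that the "
                       "fixed boundary removes all rigid modes") from exc
    if not np.all(np.isfinite(ured)):
        raise FEMError("singular reduced stiffness (non-finite solution); "
                       "check that the fixed boundary removes all rigid modes")
    res = np.linalg.norm(Kred @ ured - Fred) / np.linalg.norm(Fred)
    if res > 1e-8:
        raise FEMError(f"linear solve residual {res:.2e} exceeds 1e-8")
    u[mask] = ured
    return u


def make_solver(K: sp.spmatrix, fixed_nodes: np.ndarray):
    """Factorize the reduced stiffness once; return ``solve(F) -> u``.

    Used wherever many right-hand sides share one stiffness (deformation
    bases, the contact/anchoring fixed-point loop).
    """
    fixed_nodes = np.asarray(fixed_nodes, dtype=np.int64)
    if fixed_nodes.size == 0:
        raise FEMError("fixed_nodes is empty; the system has rigid modes")
    n3 = K.shape[0]
    mask = _free_dof_mask(n3 // 3, fixed_nodes)
    factor = spla.factorized(K[mask][:, mask].tocsc())

    def solve(F: np.ndarray) -> np.ndarray:
        u = np.zeros(n3)
        Fred = np.asarray(F, dtype=float).ravel()[mask]
        if np.any(Fred):
            ured = factor(Fred)
            if not np.all(np.isfinite(ured)):
                raise FEMError("singular reduced stiffness (non-finite solution)")
            u[mask] = ured
        return u

    return solve


# -- coupled forward simulation ------------------------------------------

@dataclass
class ForwardResult:
    u: np.ndarray  # (N, 3) displacement, mm
    converged: bool
    residual_history: list = field(default_factory=list)
    iterations: int = 0


def forward_simulate(mesh: LabeledTetMesh, materials: MaterialField,
                     sim: SimulationConfig, wall=None, anchor=None,
                     basis_displacement: np.ndarray | None = None,
                     extra_fixed: np.ndarray | None = None,
                     K: sp.spmatrix | None = None,
                     F_g: np.ndarray | None = None,
                     u_init: np.ndarray | None = None,
                     solver_cache: dict | None = None) -> ForwardResult:
    """Equilibrium under gravity + contact + anchoring (+ a fixed basis term).

    The penalty contact force w_p * E_i is stiff relative to the soft
    tissue, so it is handled implicitly: the active chest-side nodes
    contribute a penalty stiffness w_p * n n^T to the system matrix while
    their tangential position on the quadric (and the small anchoring
    forces) are lagged one iteration — a semi-smooth active-set iteration
    that converges in a handful of refactorizations. At the converged
    state the contact force equals w_p * E_i evaluated at the deformed
    configuration, exactly the penalty balance.

    ``basis_displacement`` (N, 3), if given, is the observation-driven
    displacement contribution B alpha, held fixed during the loop; the
    returned displacement includes it.
    """
    from . import anchoring as anch_mod

    fixed = mesh.fixed_nodes
    if extra_fixed is not None and len(extra_fixed):
        fixed = np.unique(np.concatenate([fixed, np.asarray(extra_fixed, np.int64)]))
    if K is None:
        K = assemble_stiffness(mesh, materials)
    if F_g is None:
        F_g = gravity_load(mesh, sim.tissue_density, sim.gravity_vector)

    n = mesh.n_nodes
    ub = (np.zeros((n, 3)) if basis_displacement is None
          else np.asarray(basis_displacement, float).reshape(n, 3))

    has_contact = wall is not None and sim.w_p > 0 and len(mesh.chest_nodes) > 0
    has_anchor = anchor is not None and anchor.w_a > 0

    if not has_contact and not has_anchor:
        u = solve_displacement(K, F_g, fixed).reshape(n, 3) + ub
        return ForwardResult(u=u, converged=True, residual_history=[0.0],
                             iterations=1)

    chest = mesh.chest_nodes
    nw = wall.rotation[2] if has_contact else None  # wall outward normal
    u_mech = (np.zeros((n, 3)) if u_init is None
              else np.asarray(u_init, float).reshape(n, 3).copy())
    active_prev = None
    if solver_cache is None:
        solver_cache = {}  # active-set key -> factorized solver
    history = []
    converged = False
    it = 0
    for it in range(1, sim.outer_iterations + 1):
        x = mesh.nodes + u_mech + ub
        F = F_g.copy()
        if has_anchor:
            F = F + anch_mod.anchoring_forces(x, anchor, n)

        if has_contact:
            local = wall.to_local(x[chest])
            depth = wall.height(local[:, 0], local[:, 1]) - local[:, 2]
            if active_prev is None:
                active = depth > -1e-9
            else:
                # hysteresis keeps marginal nodes from flapping the active
                # set (and forcing refactorization) every iteration
                active = active_prev.copy()
                active[depth > 1e-9] = True
                active[depth < -0.05] = False
            # gap of the unloaded (mechanics-free) position at the lagged
            # tangential location: depth(u) = a - n . u for each node
            a = depth + u_mech[chest] @ nw
            act_idx = chest[active]
            P = np.outer(nw, nw) * sim.w_p
            rows = (3 * act_idx[:, None, None] + np.arange(3)[None, :, None]
                    ) * np.ones(3, dtype=np.int64)[None, None, :]
            cols = (3 * act_idx[:, None, None] + np.arange(3)[None, None, :]
                    ) * np.ones(3, dtype=np.int64)[None, :, None]
            data = np.broadcast_to(P, (len(act_idx), 3, 3))
            key = active.tobytes()
            if key not in solver_cache:
                K_aug = K + sp.coo_matrix(
                    (data.ravel(), (rows.ravel(), cols.ravel())), shape=K.shape)
                if len(solver_cache) >= 6:
                    solver_cache.pop(next(iter(solver_cache)))
                solver_cache[key] = make_solver(K_aug, fixed)
            solver = solver_cache[key]
            Fc = np.zeros((n, 3))
            Fc[act_idx] = sim.w_p * a[active, None] * nw[None, :]
            F = F + Fc.ravel()
        else:
            active = None
            if "plain" not in solver_cache:
                solver_cache["plain"] = make_solver(K, fixed)
            solver = solver_cache["plain"]

        u_new = solver(F).reshape(n, 3)
        du = float(np.abs(u_new - u_mech).max())
        history.append(du)
        # full first step, then under-relaxation to damp active-set flapping
        theta = 1.0 if it == 1 else sim.relaxation
        u_mech = u_mech + theta * (u_new - u_mech)
        same_active = (active is None or
                       (active_prev is not None and np.array_equal(active, active_prev)))
        active_prev = active
        if du < sim.convergence_tol and same_active:
            converged = True
            break
    return ForwardResult(u=u_mech + ub, converged=converged,
                         residual_history=history, iterations=it)
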