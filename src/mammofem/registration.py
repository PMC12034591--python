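"""Observation-driven registration of the prone model to the supine state.

The unknown load that the finite-element balance cannot predict (the net
effect of everything the mechanical model omits) is represented as a
linear combination of deformation bases: precomputed displacement
responses of the constrained model to unit point loads at surface control
points. With the model displacement

    u(alpha) = u_base + B alpha

(u_base the equilibrium under gravity, contact and anchoring), the weights
alpha are fit to the supine observation by minimizing

    F(alpha) = sum_skin ((S_i n) . p_i)^2 + sum_chest ((S_i n) . p_i)^2
             + sum_fiducial |p_i|^2 + lambda1 |alpha| + lambda2 sum_i K_i

where the first two sums are signed point-to-nearest-polygon distances of
the observed clouds to the deformed model surface, the fiducial term is a
plain Euclidean distance, |alpha| is the Euclidean norm (not squared), and
K_i is the per-node surface smoothness measure (sum of inner products of
the node normal with its incident triangle normals). A Levenberg-
Marquardt iteration minimizes F; an outer fixed-point loop alternates the
alpha update with re-solving the contact/anchoring equilibrium (whose
forces depend on the deformed shape) and refreshing the closest-point
correspondences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import anchoring as anch_mod
from . import contact as contact_mod
from . import fem
from .geometry import SurfaceDistanceQuery, triangle_barycentric
from .mesh import (LabeledTetMesh, find_containing_tets, triangle_normals,
                   vertex_normals)


class RegistrationError(RuntimeError):
    pass


class RegistrationDivergence(RegistrationError):
    def __init__(self, msg, trace):
        super().__init__(msg)
        self.trace = trace


@dataclass
class ObservationSet:
    """Supine observation: point clouds, fiducials, alignment landmarks.

    ``fiducials`` rows are the nipple and two vessel bifurcations;
    ``landmarks`` rows are the right/left sternoclavicular joints and the
    lower sternum (the rigid pre-alignment triplet).
    """

    skin_points: np.ndarray
    chest_points: np.ndarray
    fiducials: np.ndarray
    landmarks: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.skin_points = np.atleast_2d(np.asarray(self.skin_points, float))
        self.chest_points = np.atleast_2d(np.asarray(self.chest_points, float))
        self.fiducials = np.atleast_2d(np.asarray(self.fiducials, float))
        if len(self.skin_points) < 1 or len(self.chest_points) < 1:
            raise ValueError("observation clouds must be nonempty")
        for arr in (self.skin_points, self.chest_points, self.fiducials):
            if not np.all(np.isfinite(arr)):
                raise ValueError("observation contains non-finite coordinates")

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "ObservationSet":
        lm = None if self.landmarks is None else self.landmarks @ R.T + t
        return ObservationSet(self.skin_points @ R.T + t,
                              self.chest_points @ R.T + t,
                              self.fiducials @ R.T + t, lm, dict(self.meta))


@dataclass
class RegistrationConfig:
    """Registration parameters (defaults follow the simulation table)."""

    lambda1: float = 0.01  # weight-magnitude regularizer
    lambda2: float = 0.6  # surface-smoothness term weight
    n_control_points: int = 70
    max_lm_iterations: int = 30
    lm_tolerance: float = 1e-10  # gradient inf-norm stopping threshold
    outer_iterations: int = 5
    outer_tol: float = 0.05  # mm, surface RMS change between outer iterations
    control_seed: int = 0
    norm_epsilon: float = 1e-8  # smooth |alpha| near zero
    divergence_factor: float = 3.0
    prealigned: bool = False

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization parameters must be >= 0")


@dataclass
class DeformationBasis:
    """Columns are unit-point-load displacement responses (3N x m).

    m = 3 * n_control_points (one column per control point and axis);
    every column is normalized to unit maximum nodal displacement.
    """

    basis_vectors: np.ndarray
    control_points: np.ndarray
    skipped: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def m(self) -> int:
        return self.basis_vectors.shape[1]

    def displacement(self, alpha: np.ndarray) -> np.ndarray:
        return (self.basis_vectors @ np.asarray(alpha, float)).reshape(-1, 3)


@dataclass
class RegistrationResult:
    u_final: np.ndarray  # (N, 3) mm
    alpha_hat: np.ndarray
    objective_trace: list
    deformed_tumor: np.ndarray | None
    diagnostics: dict = field(default_factory=dict)


# -- rigid pre-alignment -------------------------------------------------

def rigid_align_from_landmarks(source: np.ndarray, target: np.ndarray):
    """Least-squares rigid transform (R, t) mapping source onto target.

    Kabsch with the proper-rotation constraint (det R = +1); raises for
    collinear triplets.
    """
    src = np.atleast_2d(np.asarray(source, float))
    tgt = np.atleast_2d(np.asarray(target, float))
    if src.shape != tgt.shape or len(src) < 3:
        raise ValueError("need matching landmark sets of >= 3 points")
    for name, pts in (("source", src), ("target", tgt)):
        c = pts - pts.mean(axis=0)
        area = np.linalg.norm(np.cross(c[1] - c[0], c[2] - c[0]))
        scale = max(np.linalg.norm(c, axis=1).max(), 1e-30)
        if area < 1e-9 * scale**2:
            raise ValueError(f"collinear {name} landmark triplet; rigid "
                             "alignment is degenerate")
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ct - R @ cs
    return R, t


# -- deformation bases ---------------------------------------------------

def select_control_points(mesh: LabeledTetMesh, n: int = 70, seed: int = 0) -> np.ndarray:
    """Farthest-point sampling of ``n`` anterior surface nodes.

    Control points live on the skin-side surface (chest-side and fixed
    nodes excluded) so the bases span observable surface deformation.
    Deterministic for a given seed.
    """
    surf = mesh.surface_node_indices()
    excl = set(mesh.chest_nodes.tolist()) | set(mesh.fixed_nodes.tolist())
    cand = np.array([i for i in surf if i not in excl], dtype=np.int64)
    if len(cand) == 0:
        raise RegistrationError("no anterior surface nodes available for control points")
    n = min(n, len(cand))
    rng = np.random.default_rng(seed)
    pts = mesh.nodes[cand]
    chosen = [int(rng.integers(len(cand)))]
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for _ in range(1, n):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return cand[np.array(chosen)]


def build_deformation_bases(mesh: LabeledTetMesh, solver, control_points) -> DeformationBasis:
    """One basis column per control point and axis: the displacement
    response to a unit point load there, normalized to unit max nodal
    displacement. Control points on the fixed boundary are skipped with a
    warning (their response is identically zero)."""
    import warnings

    control_points = np.asarray(control_points, dtype=np.int64)
    fixed = set(mesh.fixed_nodes.tolist())
    cols, kept, skipped = [], [], []
    n3 = 3 * mesh.n_nodes
    for cp in control_points:
        if int(cp) in fixed:
            skipped.append(int(cp))
            continue
        for ax in range(3):
            F = np.zeros(n3)
            F[3 * cp + ax] = 1.0
            u = solver(F)
            scale = np.linalg.norm(u.reshape(-1, 3), axis=1).max()
            if scale <= 0:
                raise RegistrationError(f"zero basis response at control point {cp}")
            cols.append(u / scale)
        kept.append(int(cp))
    if skipped:
        warnings.warn(f"skipped {len(skipped)} control points on the fixed boundary")
    if not cols:
        raise RegistrationError("no usable control points")
    return DeformationBasis(np.column_stack(cols), np.asarray(kept, np.int64),
                            np.asarray(skipped, np.int64))


# -- residual machinery --------------------------------------------------

def point_to_surface_residual(points: np.ndarray, surface_nodes: np.ndarray,
                              surface_tris: np.ndarray, query=None):
    """Signed distance of each data point along the normal of its nearest
    surface polygon.

    Returns ``(residuals, tri_idx, closest_points, normals, bary)``; the
    residual is n . (p - c) with c the closest point on the nearest
    triangle and n that triangle's outward unit normal.
    """
    if len(surface_tris) == 0:
        raise ValueError("empty surface")
    if query is None:
        query = SurfaceDistanceQuery(surface_nodes, surface_tris)
    tri_idx, closest, _ = query.query(points)
    normals = triangle_normals(surface_nodes, surface_tris[tri_idx])
    pts = np.atleast_2d(np.asarray(points, float))
    r = np.einsum("ij,ij->i", normals, pts - closest)
    bary = triangle_barycentric(surface_nodes[surface_tris[tri_idx]], closest)
    return r, tri_idx, closest, normals, bary


def smoothness_term(surface_nodes: np.ndarray, surface_tris: np.ndarray) -> np.ndarray:
    """Per-node smoothness K_i: sum over incident triangles of the inner
    product between the (area-weighted) node normal and the triangle
    normal. Flat regions give K_i = (incident triangle count); creases
    give strictly less. Nodes not on the surface get zero."""
    tn = triangle_normals(surface_nodes, surface_tris)
    vn = vertex_normals(surface_nodes, surface_tris)
    K = np.zeros(len(surface_nodes))
    for k in range(3):
        d = np.einsum("td,td->t", vn[surface_tris[:, k]], tn)
        np.add.at(K, surface_tris[:, k], d)
    return K


@dataclass
class ModelState:
    """Everything the objective needs about the mechanical model."""

    mesh: LabeledTetMesh
    materials: fem.MaterialField
    sim: fem.SimulationConfig
    K: object
    solver: object
    basis: DeformationBasis
    anterior_tris: np.ndarray
    posterior_tris: np.ndarray
    fixed: np.ndarray
    F_g: np.ndarray
    fid_location: tuple
    u_base: np.ndarray  # (N, 3) equilibrium under F_g + F_p + F_a
    wall: contact_mod.QuadricSurface | None = None
    anchor: anch_mod.AnchoringStructure | None = None
    fid_jacobian: np.ndarray | None = None  # (3*n_fid, m), constant

    def displacement(self, alpha: np.ndarray) -> np.ndarray:
        return self.u_base + self.basis.displacement(alpha)


def _split_surface(mesh: LabeledTetMesh):
    on_chest = np.zeros(mesh.n_nodes, dtype=bool)
    on_chest[mesh.chest_nodes] = True
    all_chest = on_chest[mesh.surface_tris].all(axis=1)
    return mesh.surface_tris[~all_chest], mesh.surface_tris[all_chest]


def prepare_model(mesh: LabeledTetMesh, materials: fem.MaterialField,
                  sim: fem.SimulationConfig, config: RegistrationConfig,
                  anchor=None, fix_chest: bool = False) -> ModelState:
    """Assemble, factorize, and build the deformation bases once."""
    fixed = mesh.fixed_nodes
    if fix_chest:
        fixed = np.unique(np.concatenate([fixed, mesh.chest_nodes]))
    K = fem.assemble_stiffness(mesh, materials)
    solver = fem.make_solver(K, fixed)
    cps = select_control_points(mesh, config.n_control_points, config.control_seed)
    basis = build_deformation_bases(mesh, solver, cps)
    anterior, posterior = _split_surface(mesh)
    F_g = fem.gravity_load(mesh, sim.tissue_density, sim.gravity_vector)
    fid_loc = (None if mesh.fiducials is None
               else find_containing_tets(mesh, mesh.fiducials))
    state = ModelState(mesh=mesh, materials=materials, sim=sim, K=K, solver=solver,
                       basis=basis, anterior_tris=anterior, posterior_tris=posterior,
                       fixed=fixed, F_g=F_g, fid_location=fid_loc,
                       u_base=np.zeros((mesh.n_nodes, 3)), anchor=anchor)
    if fid_loc is not None:
        tet_idx, bary = fid_loc
        rows = []
        for p in range(len(tet_idx)):
            verts = mesh.tets[tet_idx[p]]
            for d in range(3):
                row = np.zeros(3 * mesh.n_nodes)
                row[3 * verts + d] = bary[p]
                rows.append(row)
        state.fid_jacobian = np.asarray(rows) @ basis.basis_vectors
        state._fid_interp = np.asarray(rows)
    return state


def _fiducial_positions(state: ModelState, u: np.ndarray) -> np.ndarray:
    interp = state._fid_interp @ u.ravel()
    return state.mesh.fiducials + interp.reshape(-1, 3)


def _geometric_residuals(state: ModelState, obs: ObservationSet, alpha, with_jac):
    """Stacked skin/chest/fiducial residuals and (optionally) the Jacobian
    linearized at the current closest-point correspondences."""
    mesh = state.mesh
    u = state.displacement(alpha)
    deformed = mesh.nodes + u
    B = state.basis.basis_vectors
    m = state.basis.m

    parts, jacs = [], []
    for pts, tris in ((obs.skin_points, state.anterior_tris),
                      (obs.chest_points, state.posterior_tris)):
        r, tri_idx, _, normals, bary = point_to_surface_residual(pts, deformed, tris)
        parts.append(r)
        if with_jac:
            verts = tris[tri_idx]  # (P, 3)
            dof = (3 * verts[:, :, None] + np.arange(3)[None, None, :])
            Bv = B[dof.reshape(len(pts), 9)]  # (P, 9, m)
            Bv = Bv.reshape(len(pts), 3, 3, m)
            J = -np.einsum("pk,pd,pkdm->pm", bary, normals, Bv, optimize=True)
            jacs.append(J)

    fid = _fiducial_positions(state, u)
    r_fid = (fid - obs.fiducials).ravel()
    parts.append(r_fid)
    if with_jac:
        jacs.append(state.fid_jacobian)
        return np.concatenate(parts), np.vstack(jacs)
    return np.concatenate(parts), None


def _smoothness_total(state: ModelState, alpha) -> float:
    deformed = state.mesh.nodes + state.displacement(alpha)
    return float(smoothness_term(deformed, state.anterior_tris).sum())


def _smoothness_total_batch(nodes_batch: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Total smoothness sum for a batch of node configurations (B, N, 3)."""
    v = nodes_batch[:, tris]  # (B, T, 3, 3)
    fn = np.cross(v[:, :, 1] - v[:, :, 0], v[:, :, 2] - v[:, :, 0])
    ln = np.linalg.norm(fn, axis=2, keepdims=True)
    ln[ln == 0] = 1.0
    tn = fn / ln
    vn = np.zeros_like(nodes_batch)
    for k in range(3):
        np.add.at(vn, (slice(None), tris[:, k]), fn)
    lv = np.linalg.norm(vn, axis=2, keepdims=True)
    lv[lv == 0] = 1.0
    vn = vn / lv
    total = np.zeros(len(nodes_batch))
    for k in range(3):
        total += np.einsum("btd,btd->b", vn[:, tris[:, k]], tn)
    return total


def _smoothness_gradient(state: ModelState, alpha, s0: float, fd_step: float) -> np.ndarray:
    """Forward-difference gradient of the smoothness sum w.r.t. alpha,
    evaluated for all basis directions in one vectorized batch."""
    base = state.mesh.nodes + state.displacement(alpha)
    m = state.basis.m
    cols = state.basis.basis_vectors.reshape(state.mesh.n_nodes, 3, m)
    batch = base[None, :, :] + fd_step * np.moveaxis(cols, 2, 0)
    totals = _smoothness_total_batch(batch, state.anterior_tris)
    return (totals - s0) / fd_step


def objective_terms(alpha, state: ModelState, obs: ObservationSet,
                    config: RegistrationConfig) -> dict:
    """Term-wise decomposition of F(alpha); values sum exactly to F."""
    alpha = np.asarray(alpha, dtype=float)
    r, _ = _geometric_residuals(state, obs, alpha, with_jac=False)
    n_skin, n_chest = len(obs.skin_points), len(obs.chest_points)
    if not np.all(np.isfinite(r)):
        raise RegistrationError("non-finite residual in the objective "
                                f"(first at index {int(np.argmax(~np.isfinite(r)))})")
    terms = {
        "skin": float(np.sum(r[:n_skin] ** 2)),
        "chest": float(np.sum(r[n_skin:n_skin + n_chest] ** 2)),
        "fiducial": float(np.sum(r[n_skin + n_chest:] ** 2)),
        "alpha_norm": float(config.lambda1 * np.linalg.norm(alpha)),
        "smoothness": (float(config.lambda2 * _smoothness_total(state, alpha))
                       if config.lambda2 > 0 else 0.0),
    }
    return terms


def objective(alpha, state: ModelState, obs: ObservationSet,
              config: RegistrationConfig) -> float:
    """The registration objective F(alpha)."""
    return float(sum(objective_terms(alpha, state, obs, config).values()))


# -- Levenberg-Marquardt -------------------------------------------------

def levenberg_marquardt(residual_jac, x0, max_iterations=50, gtol=1e-10,
                        xtol=1e-12, mu0=1e-4):
    """Generic damped Gauss-Newton (Levenberg-Marquardt) minimizer of
    ``sum(r(x)^2)``.

    ``residual_jac(x, need_jac)`` returns ``(r, J)`` (J may be None when
    ``need_jac`` is false — trial points are evaluated residual-only).
    Steps solve (J^T J + mu I) d = -J^T r; only cost-decreasing steps are
    accepted, with the damping mu adapted. Returns ``(x_best, info)``
    where info carries the cost trace, termination reason, and a warning
    flag when damping escalation could not find a descent step.
    """
    x = np.asarray(x0, dtype=float).copy()
    r, J = residual_jac(x, True)
    cost = float(r @ r)
    mu = mu0
    trace = [cost]
    reason, warning = "max_iterations", False
    for _ in range(max_iterations):
        g = J.T @ r
        if np.linalg.norm(g, np.inf) < gtol:
            reason = "gradient"
            break
        H = J.T @ J
        accepted = False
        for _esc in range(12):
            try:
                d = np.linalg.solve(H + mu * np.eye(len(x)), -g)
            except np.linalg.LinAlgError:
                mu *= 4.0
                continue
            x_new = x + d
            r_new, _ = residual_jac(x_new, False)
            c_new = float(r_new @ r_new)
            if c_new < cost:
                x, cost = x_new, c_new
                r, J = residual_jac(x_new, True)
                mu = max(mu / 3.0, 1e-14)
                accepted = True
                trace.append(cost)
                break
            mu *= 4.0
        if not accepted:
            reason, warning = "no_descent", True
            break
        if np.linalg.norm(d) < xtol * (np.linalg.norm(x) + xtol):
            reason = "step"
            break
    return x, {"cost_trace": trace, "reason": reason, "warning": warning,
               "n_iterations": len(trace) - 1}


def optimize_alpha(initial_alpha, state: ModelState, obs: ObservationSet,
                   config: RegistrationConfig):
    """One LM pass over alpha with u_base frozen.

    The geometric residuals are re-linearized at the current closest-point
    correspondences inside every LM evaluation; the regularizers enter as
    augmented residual rows (|alpha| via a smooth square root, the
    smoothness sum via a shifted square root whose constant offset cannot
    affect the minimizer).
    """
    m = state.basis.m
    lam1, lam2 = config.lambda1, config.lambda2
    eps = config.norm_epsilon
    # constant shift keeping the smoothness residual row real
    smooth_shift = 3.0 * len(state.anterior_tris) + 1.0
    fd_step = 1e-4

    def residual_jac(alpha, need_jac):
        r, J = _geometric_residuals(state, obs, alpha, with_jac=need_jac)
        rows_r = [r]
        rows_J = [J] if need_jac else None
        if lam1 > 0:
            nrm = np.sqrt(alpha @ alpha + eps * eps)
            rows_r.append(np.array([np.sqrt(lam1) * nrm ** 0.5]))
            if need_jac:
                grad = np.sqrt(lam1) * 0.5 * nrm ** (-0.5) * (alpha / nrm)
                rows_J.append(grad[None, :])
        if lam2 > 0:
            s0 = _smoothness_total(state, alpha)
            val = np.sqrt(lam2 * (s0 + smooth_shift))
            rows_r.append(np.array([val]))
            if need_jac:
                grad_s = _smoothness_gradient(state, alpha, s0, fd_step)
                rows_J.append((lam2 * grad_s / (2.0 * val))[None, :])
        return np.concatenate(rows_r), np.vstack(rows_J) if need_jac else None

    alpha0 = np.zeros(m) if initial_alpha is None else np.asarray(initial_alpha, float)
    alpha_hat, info = levenberg_marquardt(
        residual_jac, alpha0, max_iterations=config.max_lm_iterations,
        gtol=config.lm_tolerance)
    return alpha_hat, info


# -- full pipeline -------------------------------------------------------

def run_registration(mesh: LabeledTetMesh, materials: fem.MaterialField,
                     sim: fem.SimulationConfig, anchor, observation,
                     config: RegistrationConfig | None = None,
                     tumor_points: np.ndarray | None = None,
                     state: ModelState | None = None,
                     fix_chest: bool = False) -> RegistrationResult:
    """Full prone-to-supine registration.

    Alternates (i) the contact/anchoring equilibrium with the current
    basis displacement held fixed, (ii) closest-point correspondence
    refresh, and (iii) the LM update of alpha, until the surface RMS
    change falls below ``outer_tol`` or the outer iteration budget runs
    out. ``observation=None`` reduces exactly to the pure forward
    simulation (no bases applied).

    Ablation switches: ``fix_chest`` adds the chest-side nodes to the
    Dirichlet set; ``anchor=None`` (or w_a = 0) disables anchoring; the
    deep-adipose stiffness is whatever ``materials`` carries.
    """
    config = config or RegistrationConfig()

    if observation is None:
        wall = None if fix_chest else state.wall if state is not None else None
        fwd = fem.forward_simulate(mesh, materials, sim, wall=wall, anchor=anchor,
                                   extra_fixed=mesh.chest_nodes if fix_chest else None)
        u = fwd.u
        tum = None if tumor_points is None else _advect(mesh, u, tumor_points)
        return RegistrationResult(u_final=u, alpha_hat=np.zeros(0),
                                  objective_trace=[],
                                  deformed_tumor=tum,
                                  diagnostics={"forward_only": True,
                                               "converged": fwd.converged})

    obs = observation
    rigid = None
    if not config.prealigned and obs.landmarks is not None and mesh.landmarks is not None:
        R, t = rigid_align_from_landmarks(obs.landmarks, mesh.landmarks)
        obs = obs.transformed(R, t)
        rigid = (R, t)

    wall = contact_mod.fit_quadric_surface(obs.chest_points)
    if state is None:
        state = prepare_model(mesh, materials, sim, config, anchor=anchor,
                              fix_chest=fix_chest)
    state.wall = None if fix_chest else wall
    state.anchor = anchor

    n = mesh.n_nodes
    alpha = np.zeros(state.basis.m)
    trace, lm_infos = [], []
    prev_surf = None
    surf_idx = mesh.surface_node_indices()
    best = None
    fwd_cache: dict = {}
    u_warm = None
    for outer in range(1, config.outer_iterations + 1):
        ub = state.basis.displacement(alpha)
        fwd = fem.forward_simulate(
            mesh, materials, sim, wall=state.wall, anchor=state.anchor,
            basis_displacement=ub, K=state.K, F_g=state.F_g,
            extra_fixed=mesh.chest_nodes if fix_chest else None,
            u_init=u_warm, solver_cache=fwd_cache)
        u_warm = fwd.u - ub
        state.u_base = u_warm

        alpha, info = optimize_alpha(alpha, state, obs, config)
        lm_infos.append(info)
        F = objective(alpha, state, obs, config)
        trace.append(F)
        if best is None or F <= best[0]:
            best = (F, alpha.copy(), state.u_base.copy())
        if len(trace) >= 2 and F > config.divergence_factor * min(trace[:-1]) \
                and F > min(trace[:-1]) + 1.0:
            raise RegistrationDivergence(
                f"objective diverged at outer iteration {outer} "
                f"({min(trace[:-1]):.4g} -> {F:.4g})", trace)

        u_surf = state.displacement(alpha)[surf_idx]
        if prev_surf is not None:
            rms = float(np.sqrt(np.mean(np.sum((u_surf - prev_surf) ** 2, axis=1))))
            if rms < config.outer_tol:
                prev_surf = u_surf
                break
        prev_surf = u_surf

    F, alpha, u_base = best
    state.u_base = u_base
    u_final = state.displacement(alpha)
    terms = objective_terms(alpha, state, obs, config)
    tum = None if tumor_points is None else _advect(mesh, u_final, tumor_points)
    skin_r, *_ = point_to_surface_residual(obs.skin_points, mesh.nodes + u_final,
                                           state.anterior_tris)
    diagnostics = {
        "objective_terms": terms,
        "surface_rms": float(np.sqrt(np.mean(skin_r ** 2))),
        "lm": lm_infos,
        "rigid_transform": rigid,
        "wall_coefficients": state.wall.coefficients.tolist() if state.wall else None,
        "outer_iterations": len(trace),
    }
    return RegistrationResult(u_final=u_final, alpha_hat=alpha,
                              objective_trace=trace, deformed_tumor=tum,
                              diagnostics=diagnostics)


def _advect(mesh: LabeledTetMesh, u: np.ndarray, points: np.ndarray) -> np.ndarray:
    from .mesh import interpolate_displacement
    return np.asarray(points, float) + interpolate_displacement(mesh, u, points)
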