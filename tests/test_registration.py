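"""Rigid alignment, deformation bases, residuals, LM, and the pipeline."""

import numpy as np
import pytest

import mammofem as mf
from mammofem import anchoring, fem
from mammofem import registration as reg

from conftest import make_icosphere


def rotation(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


TRIPLET = np.array([[0.0, 0, 0], [10, 0, 0], [0, 7, 3]])


class TestRigidAlign:
    def test_identity(self):
        R, t = reg.rigid_align_from_landmarks(TRIPLET, TRIPLET)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0.0, atol=1e-12)

    def test_exact_transform_recovery(self):
        R0 = rotation([1, 2, 3], 0.7)
        t0 = np.array([5.0, -3.0, 2.0])
        target = TRIPLET @ R0.T + t0
        R, t = reg.rigid_align_from_landmarks(TRIPLET, target)
        assert np.max(np.abs(R - R0)) < 1e-10
        assert np.max(np.abs(t - t0)) < 1e-10

    def test_reflection_still_proper_rotation(self):
        target = TRIPLET.copy()
        target[:, 0] *= -1  # mirrored correspondence
        R, t = reg.rigid_align_from_landmarks(TRIPLET, target)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_collinear_raises(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            reg.rigid_align_from_landmarks(line, TRIPLET)


@pytest.fixture(scope="module")
def model_state(small_phantom_module):
    params, mesh = small_phantom_module
    mats = fem.assign_tissue_stiffness(mesh)
    sim = fem.SimulationConfig(gravity_vector=(0, 0, 0), w_p=0.0, w_a=0.0)
    cfg = reg.RegistrationConfig(lambda1=0.0, lambda2=0.0,
                                 n_control_points=12, control_seed=1)
    return reg.prepare_model(mesh, mats, sim, cfg), cfg


@pytest.fixture(scope="module")
def small_phantom_module():
    params = mf.PhantomParams(target_node_count=500, seed=2)
    return params, mf.generate_breast_phantom(params)


class TestDeformationBases:
    def test_column_count_three_per_control_point(self, model_state):
        state, _ = model_state
        assert state.basis.m == 3 * len(state.basis.control_points)

    def test_basis_reproduces_direct_solve(self, model_state):
        """A basis column times its normalization equals the direct FEM
        response to the same unit point load."""
        state, _ = model_state
        cp = state.basis.control_points[0]
        F = np.zeros(3 * state.mesh.n_nodes)
        F[3 * cp] = 1.0
        u_direct = state.solver(F)
        col = state.basis.basis_vectors[:, 0]
        scale = np.linalg.norm(u_direct.reshape(-1, 3), axis=1).max()
        assert np.max(np.abs(col * scale - u_direct)) < 1e-10 * scale

    def test_single_alpha_entry_scales_column(self, model_state):
        state, _ = model_state
        alpha = np.zeros(state.basis.m)
        alpha[4] = 2.5
        u = state.basis.displacement(alpha)
        assert np.allclose(u.ravel(), 2.5 * state.basis.basis_vectors[:, 4],
                           atol=1e-15)

    def test_fixed_control_points_skipped_with_warning(self, small_phantom_module):
        _, mesh = small_phantom_module
        mats = fem.assign_tissue_stiffness(mesh)
        K = fem.assemble_stiffness(mesh, mats)
        solver = fem.make_solver(K, mesh.fixed_nodes)
        cps = np.concatenate([mesh.fixed_nodes[:1],
                              [reg.select_control_points(mesh, 1, 0)[0]]])
        with pytest.warns(UserWarning, match="skipped"):
            basis = reg.build_deformation_bases(mesh, solver, cps)
        assert basis.m == 3

    def test_control_point_selection_deterministic(self, small_phantom_module):
        _, mesh = small_phantom_module
        a = reg.select_control_points(mesh, 10, seed=3)
        b = reg.select_control_points(mesh, 10, seed=3)
        assert np.array_equal(a, b)


class TestSurfaceResidual:
    def test_point_on_surface_zero(self):
        verts, faces = make_icosphere(1, 5.0)
        p = verts[faces[0]].mean(axis=0)
        r, *_ = reg.point_to_surface_residual(np.array([p]), verts, faces)
        assert abs(r[0]) < 1e-12

    def test_height_above_flat_patch(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        h = 0.37
        r, *_ = reg.point_to_surface_residual(np.array([[0.4, 0.4, h]]),
                                              verts, faces)
        assert r[0] == pytest.approx(h, abs=1e-12)

    def test_matches_all_triangle_oracle_on_icosphere(self):
        """Signed distance agrees with a brute-force scan over every
        triangle for random probes around an icosphere."""
        verts, faces = make_icosphere(2, 8.0)
        rng = np.random.default_rng(6)
        pts = rng.uniform(-12, 12, size=(40, 3))
        r, tri_idx, closest, normals, _ = reg.point_to_surface_residual(
            pts, verts, faces)
        from mammofem.geometry import nearest_triangles_brute
        from mammofem.mesh import triangle_normals
        bi, bc, bd = nearest_triangles_brute(pts, verts, faces)
        bn = triangle_normals(verts, faces[bi])
        expected = np.einsum("ij,ij->i", bn, pts - bc)
        same = tri_idx == bi
        assert np.allclose(r[same], expected[same], atol=1e-9)
        # any index disagreement must be an exact distance tie between
        # adjacent triangles (edge/vertex closest point)
        d_query = np.linalg.norm(pts - closest, axis=1)
        assert np.allclose(d_query[~same], bd[~same], atol=1e-9)

    def test_empty_surface_raises(self):
        with pytest.raises(ValueError, match="empty"):
            reg.point_to_surface_residual(np.zeros((1, 3)), np.zeros((0, 3)),
                                          np.zeros((0, 3), dtype=int))


class TestSmoothness:
    def test_flat_patch_interior_equals_incidence_count(self):
        # regular grid strip: interior nodes see all-parallel normals
        nx = 5
        xs = np.arange(nx, dtype=float)
        verts = np.array([[x, y, 0.0] for y in range(3) for x in xs])
        faces = []
        for j in range(2):
            for i in range(nx - 1):
                a = j * nx + i
                faces += [[a, a + 1, a + nx], [a + 1, a + nx + 1, a + nx]]
        faces = np.array(faces)
        K = reg.smoothness_term(verts, faces)
        counts = np.zeros(len(verts))
        for f in faces:
            for v in f:
                counts[v] += 1
        interior = [nx + i for i in range(1, nx - 1)]
        assert np.allclose(K[interior], counts[interior], atol=1e-12)

    def test_crease_strictly_smaller(self):
        """Folding a flat pair of triangles along the shared edge lowers
        the smoothness of the crease nodes."""
        flat = np.array([[0.0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, -1, 0]])
        faces = np.array([[0, 2, 1], [0, 1, 3]])
        bent = flat.copy()
        bent[3, 2] = 0.8  # fold the second triangle up
        K_flat = reg.smoothness_term(flat, faces)
        K_bent = reg.smoothness_term(bent, faces)
        assert K_bent[0] < K_flat[0]
        assert K_bent[1] < K_flat[1]

    def test_refinement_approaches_smooth_limit(self):
        """On successively refined icospheres the average per-triangle
        normal alignment K_i / degree rises toward the smooth-surface
        limit of 1."""
        means = []
        for sub in (0, 1, 2):
            verts, faces = make_icosphere(sub, 1.0)
            K = reg.smoothness_term(verts, faces)
            deg = np.zeros(len(verts))
            for f in faces:
                for v in f:
                    deg[v] += 1
            means.append(float(np.mean(K / deg)))
        assert means[0] < means[1] < means[2] < 1.0


class TestObjectiveAndLM:
    def test_exact_fit_objective_zero(self, model_state):
        """With the clouds and fiducials exactly on the model and no
        regularizers, F = 0."""
        state, cfg = model_state
        mesh = state.mesh
        surf = mesh.surface_node_indices()
        on_chest = np.zeros(mesh.n_nodes, bool)
        on_chest[mesh.chest_nodes] = True
        obs = reg.ObservationSet(
            skin_points=mesh.nodes[surf[~on_chest[surf]]][:50],
            chest_points=mesh.nodes[mesh.chest_nodes][:30],
            fiducials=mesh.fiducials)
        state.u_base = np.zeros((mesh.n_nodes, 3))
        F = reg.objective(np.zeros(state.basis.m), state, obs, cfg)
        assert F < 1e-18

    def test_hand_computed_plane_residuals(self, model_state):
        """Two data points at known plane distances d1, d2 from the model
        give F = d1^2 + d2^2 without regularizers."""
        state, cfg = model_state
        mesh = state.mesh
        from mammofem.mesh import triangle_normals
        d1, d2 = 0.3, 0.7
        # probes straight above a skin and a chest triangle centroid
        tn_a = triangle_normals(mesh.nodes, state.anterior_tris)
        tn_p = triangle_normals(mesh.nodes, state.posterior_tris)
        p1 = mesh.nodes[state.anterior_tris[5]].mean(axis=0) + d1 * tn_a[5]
        p2 = mesh.nodes[state.posterior_tris[3]].mean(axis=0) + d2 * tn_p[3]
        obs = reg.ObservationSet(
            skin_points=p1[None], chest_points=p2[None],
            fiducials=mesh.fiducials)
        state.u_base = np.zeros((mesh.n_nodes, 3))
        terms = reg.objective_terms(np.zeros(state.basis.m), state, obs, cfg)
        assert terms["skin"] == pytest.approx(d1**2, rel=1e-9)
        assert terms["chest"] == pytest.approx(d2**2, rel=1e-9)
        assert terms["fiducial"] == pytest.approx(0.0, abs=1e-18)

    def test_alpha_norm_term_is_linear(self, model_state):
        state, _ = model_state
        cfg = reg.RegistrationConfig(lambda1=0.01, lambda2=0.0,
                                     n_control_points=12)
        mesh = state.mesh
        obs = reg.ObservationSet(skin_points=mesh.nodes[:5],
                                 chest_points=mesh.nodes[:5],
                                 fiducials=mesh.fiducials)
        state.u_base = np.zeros((mesh.n_nodes, 3))
        rng = np.random.default_rng(0)
        alpha = 1e-6 * rng.normal(size=state.basis.m)
        t1 = reg.objective_terms(alpha, state, obs, cfg)["alpha_norm"]
        t2 = reg.objective_terms(2 * alpha, state, obs, cfg)["alpha_norm"]
        assert t2 == pytest.approx(2 * t1, rel=1e-12)
        assert t1 == pytest.approx(0.01 * np.linalg.norm(alpha), rel=1e-12)

    def test_objective_decomposition_sums_exactly(self, model_state):
        state, _ = model_state
        cfg = reg.RegistrationConfig(lambda1=0.01, lambda2=0.6,
                                     n_control_points=12)
        mesh = state.mesh
        obs = reg.ObservationSet(skin_points=mesh.nodes[:20] + 0.1,
                                 chest_points=mesh.nodes[mesh.chest_nodes][:10],
                                 fiducials=mesh.fiducials + 0.05)
        state.u_base = np.zeros((mesh.n_nodes, 3))
        alpha = 0.01 * np.ones(state.basis.m)
        terms = reg.objective_terms(alpha, state, obs, cfg)
        F = reg.objective(alpha, state, obs, cfg)
        assert F == pytest.approx(sum(terms.values()), rel=1e-12)

    def test_lm_matches_closed_form_on_linear_problem(self):
        """For linear residuals r = A x - b the LM fixed point is the
        normal-equations solution."""
        rng = np.random.default_rng(3)
        A = rng.normal(size=(12, 4))
        b = rng.normal(size=12)

        def rj(x, need_jac):
            return A @ x - b, A if need_jac else None

        x, info = reg.levenberg_marquardt(rj, np.zeros(4), max_iterations=100,
                                          gtol=1e-14)
        x_star = np.linalg.lstsq(A, b, rcond=None)[0]
        assert np.max(np.abs(x - x_star)) < 1e-8
        assert np.all(np.diff(info["cost_trace"]) <= 0)

    def test_lm_cost_trace_never_increases(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(20, 6))
        b = rng.normal(size=20)

        def rj(x, need_jac):
            r = A @ x - b + 0.05 * np.sin(x).sum()
            J = A + 0.05 * np.cos(x)[None, :] if need_jac else None
            return r, J

        _, info = reg.levenberg_marquardt(rj, np.ones(6), max_iterations=50)
        assert np.all(np.diff(info["cost_trace"]) <= 0)

    def test_null_problem_alpha_stays_zero(self, model_state):
        """Observation equal to the undeformed model: the fitted alpha
        induces (numerically) no displacement."""
        state, cfg = model_state
        mesh = state.mesh
        surf = mesh.surface_node_indices()
        on_chest = np.zeros(mesh.n_nodes, bool)
        on_chest[mesh.chest_nodes] = True
        obs = reg.ObservationSet(
            skin_points=mesh.nodes[surf[~on_chest[surf]]],
            chest_points=mesh.nodes[mesh.chest_nodes],
            fiducials=mesh.fiducials)
        state.u_base = np.zeros((mesh.n_nodes, 3))
        alpha, _ = reg.optimize_alpha(None, state, obs, cfg)
        u = state.basis.displacement(alpha)
        assert np.linalg.norm(u, axis=1).max() < 1e-6


class TestRunRegistration:
    def test_forward_reduction_bitwise(self, small_phantom_module):
        """With no observation the pipeline is exactly the forward
        simulation, bit for bit."""
        params, mesh = small_phantom_module
        mats = fem.assign_tissue_stiffness(mesh)
        sim = fem.SimulationConfig()
        anchor = anchoring.build_anchoring(mesh, sim.w_a)
        res = reg.run_registration(mesh, mats, sim, anchor, observation=None)
        fwd = fem.forward_simulate(mesh, mats, sim, wall=None, anchor=anchor)
        assert np.array_equal(res.u_final, fwd.u)

    def test_recovery_beats_rigid_baseline(self, small_phantom_module):
        """Registering a forward-simulated noise-free observation lowers
        the tumor centroid error below the no-deformation baseline."""
        params, mesh = small_phantom_module
        mats = fem.assign_tissue_stiffness(mesh)
        sim = fem.SimulationConfig()
        obs, truth = mf.generate_supine_observation(
            mesh, mats, sim, noise_sd=0.0, seed=8, n_surface=500, n_chest=250)
        anchor = anchoring.build_anchoring(mesh, sim.w_a)
        cfg = reg.RegistrationConfig(n_control_points=12, max_lm_iterations=8,
                                     outer_iterations=2)
        res = reg.run_registration(mesh, mats, sim, anchor, obs, cfg,
                                   tumor_points=truth.prone_tumor_points)
        from mammofem.evaluation import centroid_error
        err = centroid_error(res.deformed_tumor, truth.supine_tumor_points)
        baseline = centroid_error(truth.prone_tumor_points,
                                  truth.supine_tumor_points)
        assert err < baseline
        assert len(res.objective_trace) >= 1

    def test_rigid_perturbation_is_undone(self, small_phantom_module):
        """The landmark pre-alignment recovers the simulated CT frame."""
        params, mesh = small_phantom_module
        mats = fem.assign_tissue_stiffness(mesh)
        sim = fem.SimulationConfig()
        obs, truth = mf.generate_supine_observation(
            mesh, mats, sim, noise_sd=0.0, seed=12, n_surface=100, n_chest=80,
            rigid_perturbation=True)
        R0, t0 = obs.meta["true_rigid"]
        R, t = reg.rigid_align_from_landmarks(obs.landmarks, mesh.landmarks)
        # the recovered transform inverts the perturbation
        assert np.max(np.abs(R @ R0 - np.eye(3))) < 1e-9
        assert np.max(np.abs(R @ t0 + t)) < 1e-8
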