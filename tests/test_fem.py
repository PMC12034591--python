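"""Linear tetrahedral elasticity: element matrices, assembly, loads, solve."""

import numpy as np
import pytest
import scipy.sparse as sp

import mammofem as mf
from mammofem import fem
from mammofem.mesh import LabeledTetMesh, structured_block, tet_volumes

from conftest import two_tet_mesh


def sympy_element_stiffness(coords, E, nu):
    """Independent oracle: V * B^T D B with the B matrix assembled from
    shape-function gradients computed symbolically."""
    import sympy as sy

    x, y, z = sy.symbols("x y z")
    c = [sy.Matrix(row) for row in np.asarray(coords, dtype=float)]
    # linear shape functions from the 4x4 vandermonde inverse
    M = sy.Matrix([[1, *ci] for ci in c])
    Minv = M.inv()
    shapes = [sum(Minv[j, i] * v for j, v in enumerate([1, x, y, z]))
              for i in range(4)]
    B = sy.zeros(6, 12)
    for i, N in enumerate(shapes):
        gx, gy, gz = sy.diff(N, x), sy.diff(N, y), sy.diff(N, z)
        col = 3 * i
        B[0, col] = gx
        B[1, col + 1] = gy
        B[2, col + 2] = gz
        B[3, col], B[3, col + 1] = gy, gx
        B[4, col + 1], B[4, col + 2] = gz, gy
        B[5, col], B[5, col + 2] = gz, gx
    Es, nus = sy.Rational(E) if E == int(E) else sy.Float(E), sy.Float(nu)
    fac = Es / ((1 + nus) * (1 - 2 * nus))
    D = sy.zeros(6, 6)
    for i in range(3):
        for j in range(3):
            D[i, j] = fac * (nus if i != j else 1 - nus)
        D[i + 3, i + 3] = fac * (1 - 2 * nus) / 2
    vol = abs(sy.Matrix.hstack(c[1] - c[0], c[2] - c[0], c[3] - c[0]).det()) / 6
    Ke = vol * B.T * D * B
    return np.array(Ke.evalf(), dtype=float)


UNIT_RIGHT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


class TestElementStiffness:
    def test_matches_symbolic_oracle(self):
        Ke = fem.element_stiffness(UNIT_RIGHT_TET, E=1.0, nu=0.0)
        Ko = sympy_element_stiffness(UNIT_RIGHT_TET, 1.0, 0.0)
        assert np.max(np.abs(Ke - Ko)) < 1e-12

    def test_matches_symbolic_oracle_general_tet(self):
        rng = np.random.default_rng(0)
        coords = UNIT_RIGHT_TET + 0.2 * rng.normal(size=(4, 3))
        Ke = fem.element_stiffness(coords, E=9.75, nu=0.45)
        Ko = sympy_element_stiffness(coords, 9.75, 0.45)
        assert np.max(np.abs(Ke - Ko)) < 1e-10 * np.max(np.abs(Ko))

    def test_symmetric_psd_with_six_rigid_modes(self):
        Ke = fem.element_stiffness(UNIT_RIGHT_TET, E=2.0, nu=0.3)
        assert np.max(np.abs(Ke - Ke.T)) < 1e-12
        w = np.linalg.eigvalsh(Ke)
        assert w[0] > -1e-12
        assert np.sum(np.abs(w) < 1e-10) == 6

    def test_rigid_translation_in_null_space(self):
        Ke = fem.element_stiffness(UNIT_RIGHT_TET, E=4.0, nu=0.495)
        for ax in range(3):
            t = np.zeros(12)
            t[ax::3] = 1.0
            assert np.max(np.abs(Ke @ t)) < 1e-10

    def test_linearity_in_youngs_modulus(self):
        K1 = fem.element_stiffness(UNIT_RIGHT_TET, E=1.3, nu=0.4)
        K2 = fem.element_stiffness(UNIT_RIGHT_TET, E=2.6, nu=0.4)
        assert np.allclose(K2, 2.0 * K1, rtol=0, atol=1e-13)

    def test_degenerate_tet_raises(self):
        flat = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 0]])
        with pytest.raises(fem.FEMError, match="degenerate"):
            fem.element_stiffness(flat, E=1.0, nu=0.3)


def _mesh_from(nodes, tets, fixed=None):
    from mammofem.mesh import extract_surface
    return LabeledTetMesh(
        nodes=nodes, tets=tets, labels=np.zeros(len(tets), dtype=int),
        surface_tris=extract_surface(nodes, tets),
        fixed_nodes=np.asarray(fixed if fixed is not None else [0]),
        chest_nodes=np.array([], dtype=int),
        endpoint_chain=np.array([], dtype=int))


class TestAssembly:
    def test_matches_dense_scatter_oracle(self):
        """Sparse vectorized assembly equals a naive dense per-element
        scatter built on the scalar element routine."""
        nodes, tets = two_tet_mesh()
        mesh = _mesh_from(nodes, tets)
        E = np.array([1.5, 3.25])
        mats = fem.MaterialField(E, poisson=0.3)
        K = fem.assemble_stiffness(mesh, mats).toarray()

        Kd = np.zeros_like(K)
        for e, tet in enumerate(tets):
            Ke = fem.element_stiffness(nodes[tet], E[e], 0.3)
            dof = np.array([3 * v + d for v in tet for d in range(3)])
            Kd[np.ix_(dof, dof)] += Ke
        assert np.max(np.abs(K - Kd)) < 1e-12 * max(np.max(np.abs(Kd)), 1)

    def test_exact_symmetry(self):
        nodes, tets = structured_block(2, 2, 2)
        mesh = _mesh_from(nodes, tets)
        K = fem.assemble_stiffness(mesh, fem.MaterialField(np.full(len(tets), 2.0)))
        assert (K - K.T).nnz == 0 or abs(K - K.T).max() == 0

    def test_translation_equilibrium(self):
        nodes, tets = structured_block(2, 3, 2)
        mesh = _mesh_from(nodes, tets)
        K = fem.assemble_stiffness(mesh, fem.MaterialField(np.full(len(tets), 5.0)))
        scale = abs(K).max()
        for ax in range(3):
            t = np.zeros(K.shape[0])
            t[ax::3] = 1.0
            assert np.max(np.abs(K @ t)) < 1e-9 * scale


class TestGravityLoad:
    def test_zero_density_zero_load(self, small_phantom):
        _, mesh = small_phantom
        F = fem.gravity_load(mesh, 0.0, (0, 0, -9.81))
        assert not F.any()

    def test_single_tet_equal_lumping(self):
        nodes, tets = two_tet_mesh()
        mesh = _mesh_from(nodes, tets[:1])
        rho, g = 1000.0, np.array([0.0, 0.0, -9.81])
        F = fem.gravity_load(mesh, rho, g).reshape(-1, 3)
        V = tet_volumes(nodes, tets[:1])[0]
        expected = rho * fem.GRAVITY_FORCE_SCALE * V * g / 4.0
        for node in tets[0]:
            assert np.allclose(F[node], expected, rtol=1e-14)

    def test_total_weight_conserved(self, small_phantom):
        _, mesh = small_phantom
        rho, g = 950.0, np.array([0.3, -0.1, -19.62])
        F = fem.gravity_load(mesh, rho, g).reshape(-1, 3)
        Vtot = tet_volumes(mesh.nodes, mesh.tets).sum()
        expected = rho * fem.GRAVITY_FORCE_SCALE * Vtot * g
        assert np.allclose(F.sum(axis=0), expected, rtol=1e-10)


class TestSolve:
    def test_zero_load_zero_displacement(self):
        nodes, tets = structured_block(2, 2, 2)
        mesh = _mesh_from(nodes, tets, fixed=[0, 1, 2])
        K = fem.assemble_stiffness(mesh, fem.MaterialField(np.full(len(tets), 1.0)))
        u = fem.solve_displacement(K, np.zeros(K.shape[0]), mesh.fixed_nodes)
        assert not u.any()

    def test_patch_test_linear_field_exact(self):
        """Constant-strain elements reproduce any linear displacement field
        imposed on the boundary exactly (the FEM patch test)."""
        nodes, tets = structured_block(3, 3, 3, 2.0, 1.5, 1.0)
        assert len(tets) >= 100
        A = np.array([[0.02, 0.01, -0.005],
                      [0.003, -0.015, 0.02],
                      [-0.01, 0.004, 0.012]])
        b = np.array([0.1, -0.2, 0.05])
        u_exact = nodes @ A.T + b

        from mammofem.mesh import extract_surface
        surf = np.unique(extract_surface(nodes, tets))
        mats = fem.MaterialField(np.full(len(tets), 9.75), poisson=0.495)
        mesh = _mesh_from(nodes, tets, fixed=surf)
        K = fem.assemble_stiffness(mesh, mats)

        # impose the linear field on the boundary via force bookkeeping:
        # K u = F with u known on the boundary -> solve interior block
        mask = np.ones(K.shape[0], dtype=bool)
        mask[(3 * surf[:, None] + np.arange(3)).ravel()] = False
        Kii = K[mask][:, mask]
        Kib = K[mask][:, ~mask]
        ub = u_exact.ravel()[~mask]
        ui = sp.linalg.spsolve(Kii.tocsc(), -Kib @ ub)
        err = np.abs(ui - u_exact.ravel()[mask]).max()
        assert err < 1e-8 * max(np.abs(u_exact).max(), 1.0)

    def test_doubling_stiffness_halves_displacement(self, small_phantom):
        _, mesh = small_phantom
        F = fem.gravity_load(mesh, 1000.0, (0, 0, -9.81))
        for scale, expect in ((1.0, None), (2.0, 0.5)):
            mats = fem.MaterialField(np.full(mesh.n_elements, 9.75 * scale))
            K = fem.assemble_stiffness(mesh, mats)
            u = fem.solve_displacement(K, F, mesh.fixed_nodes)
            if expect is None:
                u1 = u
            else:
                assert np.allclose(u, expect * u1, rtol=1e-9, atol=1e-12)

    def test_energy_positivity(self, small_phantom):
        _, mesh = small_phantom
        mats = fem.MaterialField(np.full(mesh.n_elements, 4.0))
        K = fem.assemble_stiffness(mesh, mats)
        rng = np.random.default_rng(1)
        u = rng.normal(size=K.shape[0])
        u[(3 * mesh.fixed_nodes[:, None] + np.arange(3)).ravel()] = 0.0
        assert u @ (K @ u) > 0

    def test_permutation_equivariance(self):
        """Relabeling the nodes permutes the solution accordingly."""
        nodes, tets = structured_block(2, 2, 2)
        fixed = np.array([0, 1, 2, 3])
        mesh = _mesh_from(nodes, tets, fixed=fixed)
        mats = fem.MaterialField(np.full(len(tets), 3.0))
        K = fem.assemble_stiffness(mesh, mats)
        F = fem.gravity_load(mesh, 1000.0, (0, 0, -9.81))
        u = fem.solve_displacement(K, F, fixed).reshape(-1, 3)

        rng = np.random.default_rng(7)
        perm = rng.permutation(len(nodes))  # perm[old] = new index
        inv = np.argsort(perm)
        mesh2 = _mesh_from(nodes[inv], perm[tets], fixed=perm[fixed])
        K2 = fem.assemble_stiffness(mesh2, mats)
        F2 = fem.gravity_load(mesh2, 1000.0, (0, 0, -9.81))
        u2 = fem.solve_displacement(K2, F2, perm[fixed]).reshape(-1, 3)
        assert np.allclose(u2[perm], u, rtol=1e-8, atol=1e-12)

    def test_empty_fixed_set_raises(self):
        nodes, tets = two_tet_mesh()
        mesh = _mesh_from(nodes, tets)
        K = fem.assemble_stiffness(mesh, fem.MaterialField(np.ones(len(tets))))
        with pytest.raises(fem.FEMError, match="fixed"):
            fem.solve_displacement(K, np.ones(K.shape[0]), np.array([], dtype=int))


class TestTissueStiffness:
    def test_label_to_modulus_mapping(self, small_phantom):
        _, mesh = small_phantom
        mats = fem.assign_tissue_stiffness(mesh, E_skin=4.0, E_gland=9.75,
                                           E_deep=0.83)
        lab = mesh.labels
        assert np.all(mats.E_per_element[lab == mf.TissueLabel.DEEP_ADIPOSE] == 0.83)
        assert np.all(mats.E_per_element[lab == mf.TissueLabel.SKIN] == 4.0)
        assert np.all(mats.E_per_element[lab == mf.TissueLabel.GLAND] == 9.75)
        # tumor and superficial adipose share the gland stiffness
        assert np.all(mats.E_per_element[lab == mf.TissueLabel.TUMOR] == 9.75)
        assert np.all(
            mats.E_per_element[lab == mf.TissueLabel.SUPERFICIAL_ADIPOSE] == 9.75)

    def test_zero_thickness_layer_is_empty(self, small_phantom):
        """With a zero-thickness deep layer every adipose element reverts
        to the gland modulus."""
        _, mesh = small_phantom
        mats = fem.assign_tissue_stiffness(mesh, deep_layer_thickness=0.0)
        adipose = np.isin(mesh.labels, [mf.TissueLabel.DEEP_ADIPOSE,
                                        mf.TissueLabel.SUPERFICIAL_ADIPOSE])
        assert np.all(mats.E_per_element[adipose] == 9.75)

    def test_unknown_label_rejected(self, small_phantom):
        _, mesh = small_phantom
        bad = LabeledTetMesh(nodes=mesh.nodes, tets=mesh.tets,
                             labels=np.full(mesh.n_elements, 99),
                             surface_tris=mesh.surface_tris,
                             fixed_nodes=mesh.fixed_nodes,
                             chest_nodes=mesh.chest_nodes,
                             endpoint_chain=mesh.endpoint_chain)
        with pytest.raises(ValueError, match="unknown tissue label"):
            fem.assign_tissue_stiffness(bad)
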