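"""FE core: assembly properties, analytic solutions, stress recovery."""

import numpy as np
import pytest

from flipperfea.fe import (
    BoundaryCondition,
    assemble,
    principal,
    solve_static,
    traction_loads,
)
from flipperfea.mesh import Material, TetMesh, to_quadratic
from flipperfea.synthetic import structured_box

from conftest import BONE, make_bar


def uniaxial_bc(mesh, lx=100.0):
    """Axial-only constraints at x = lx plus minimal rigid-body pins, so
    the exact uniaxial field (free lateral contraction) is admissible."""
    far = mesh.node_sets["x1_face"]
    comps = [(int(n), 0) for n in far]
    y0 = [int(n) for n in far if np.isclose(mesh.nodes[n, 1], 0.0)]
    z0 = [int(n) for n in far if np.isclose(mesh.nodes[n, 2], 0.0)]
    comps += [(y0[0], 1), (y0[1], 1), (z0[0], 2)]
    return comps


class TestAssembly:
    def test_single_tet_operator_symmetric(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]))
        op = assemble(mesh, BONE)
        dense = op.matrix.toarray()
        assert np.abs(dense - dense.T).max() == 0.0

    @pytest.mark.parametrize("quadratic", [False, True])
    def test_rigid_body_modes(self, quadratic):
        """One connected body has 6 zero-energy modes; two disconnected
        tets have 12."""
        nodes = np.array(
            [
                [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0],
                [5, 5, 5], [6, 5, 5], [5, 6, 5], [5, 5, 6.0],
            ]
        )
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3], [4, 5, 6, 7]]))
        if quadratic:
            mesh = to_quadratic(mesh)
        op = assemble(mesh, BONE)
        vals = np.linalg.eigvalsh(op.matrix.toarray())
        n_zero = int((np.abs(vals) < 1e-8 * vals.max()).sum())
        assert n_zero == 12

    def test_inverted_element_named(self):
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        mesh = TetMesh(nodes, np.array([[0, 2, 1, 3]]))
        with pytest.raises(ValueError, match="inverted element 0"):
            assemble(mesh, BONE)

    def test_missing_material_rejected(self):
        mesh = structured_box(1, 1, 1, 1, 1, 1)
        mesh.region[:] = "cartilage"
        with pytest.raises(ValueError, match="cartilage"):
            assemble(mesh, BONE)

    @pytest.mark.parametrize("quadratic", [False, True])
    def test_patch_test_constant_strain(self, quadratic):
        """An affine displacement imposed on the boundary is reproduced
        exactly in the interior, with constant recovered stress."""
        mesh = structured_box(2.0, 2.0, 2.0, 2, 2, 2)
        if quadratic:
            mesh = to_quadratic(mesh)
        op = assemble(mesh, BONE)
        grad = np.array([[1e-3, 2e-4, -1e-4], [0.0, -5e-4, 3e-4], [2e-4, 0.0, 4e-4]])
        u_exact = mesh.nodes @ grad.T
        surface = mesh.surface_nodes()
        boundary_dofs = np.sort(
            np.concatenate([3 * surface, 3 * surface + 1, 3 * surface + 2])
        )
        all_dofs = np.arange(3 * mesh.n_nodes)
        interior = np.setdiff1d(all_dofs, boundary_dofs)
        k = op.matrix
        u = u_exact.reshape(-1).copy()
        if len(interior):
            import scipy.sparse.linalg as spla

            rhs = -k[np.ix_(interior, boundary_dofs)] @ u[boundary_dofs]
            u[interior] = spla.spsolve(k[np.ix_(interior, interior)].tocsc(), rhs)
        np.testing.assert_allclose(u, u_exact.reshape(-1), atol=1e-12)
        stress = op.element_stress(u)
        spread = np.abs(stress - stress[0]).max()
        assert spread < 1e-8 * np.abs(stress).max()


class TestStaticSolve:
    @pytest.mark.parametrize("quadratic", [False, True])
    def test_uniaxial_bar_exact(self, quadratic):
        """100 mm bar, 10x10 section, E=12 GPa, 1200 N compression:
        sigma3 = -12 MPa everywhere, shortening FL/EA = 0.1 mm."""
        mesh = make_bar(quadratic=quadratic)
        op = assemble(mesh, BONE)
        bc = BoundaryCondition(
            fixed_components=uniaxial_bc(mesh),
            loads=traction_loads(mesh, "x0_face", np.array([12.0, 0.0, 0.0])),
        )
        sol = solve_static(op, bc)
        np.testing.assert_allclose(sol.sigma3, -12.0, rtol=1e-8)
        np.testing.assert_allclose(np.abs(sol.sigma1), 0.0, atol=1e-8)
        tip = sol.displacement[mesh.node_sets["x0_face"], 0]
        np.testing.assert_allclose(tip, 0.1, rtol=1e-8)

    def test_zero_load_zero_state(self):
        mesh = make_bar(nx=4)
        op = assemble(mesh, BONE)
        bc = BoundaryCondition(fixed_nodes=mesh.node_sets["x1_face"])
        sol = solve_static(op, bc)
        assert np.abs(sol.displacement).max() == 0.0
        assert np.abs(sol.sigma1).max() == 0.0

    def test_unconstrained_system_rejected(self):
        mesh = make_bar(nx=2)
        op = assemble(mesh, BONE)
        with pytest.raises(ValueError, match="fixed boundary"):
            solve_static(op, BoundaryCondition())

    def test_global_equilibrium(self):
        """Applied loads plus reactions sum to zero, per component."""
        mesh = make_bar(nx=6)
        op = assemble(mesh, BONE)
        loads = traction_loads(mesh, "x0_face", np.array([3.0, -2.0, 5.0]))
        bc = BoundaryCondition(fixed_nodes=mesh.node_sets["x1_face"], loads=loads)
        sol = solve_static(op, bc)
        total_applied = np.sum([v for _, v in loads], axis=0)
        residual = total_applied + sol.reactions.sum(axis=0)
        assert np.abs(residual).max() < 1e-6 * np.abs(total_applied).max()

    def test_cantilever_matches_beam_theory(self, cantilever_result):
        tip, euler, _, _ = cantilever_result
        assert tip == pytest.approx(euler, rel=0.10)

    def test_sparse_matches_dense_oracle(self):
        """On a small mesh the sparse path reproduces a dense direct solve."""
        mesh = make_bar(nx=3, ny=1, nz=1)  # 16 nodes, 48 dof
        assert 3 * mesh.n_nodes <= 300
        op = assemble(mesh, BONE)
        loads = traction_loads(mesh, "x0_face", np.array([1.0, 2.0, -1.0]))
        bc = BoundaryCondition(fixed_nodes=mesh.node_sets["x1_face"], loads=loads)
        sol = solve_static(op, bc)
        fixed = bc.fixed_dofs(mesh.n_nodes)
        free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed)
        k = op.matrix.toarray()
        f = bc.load_vector(mesh.n_nodes)
        u_dense = np.zeros(3 * mesh.n_nodes)
        u_dense[free] = np.linalg.solve(k[np.ix_(free, free)], f[free])
        np.testing.assert_allclose(
            sol.displacement.reshape(-1), u_dense, rtol=1e-8, atol=1e-15
        )

    def test_refinement_energy_monotone(self):
        """Displacement FEM underestimates compliance energy: the
        cantilever's strain energy is non-decreasing under refinement."""
        energies = []
        for n in (1, 2, 4):
            mesh = make_bar(nx=10 * n, ny=n, nz=n, lx=40.0)
            op = assemble(mesh, BONE)
            loads = traction_loads(mesh, "x0_face", np.array([0.0, 0.0, 1.0]))
            bc = BoundaryCondition(fixed_nodes=mesh.node_sets["x1_face"], loads=loads)
            sol = solve_static(op, bc)
            f = bc.load_vector(mesh.n_nodes)
            energies.append(0.5 * float(f @ sol.displacement.reshape(-1)))
        assert energies[0] <= energies[1] <= energies[2]


class TestPrincipal:
    def test_hydrostatic(self):
        s1, s2, s3, tau = principal(np.diag([-5.0, -5.0, -5.0]))
        assert (s1, s2, s3, tau) == (-5.0, -5.0, -5.0, 0.0)

    def test_pure_shear(self):
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = 3.0
        s1, s2, s3, tau = principal(t)
        assert s1 == pytest.approx(3.0)
        assert s2 == pytest.approx(0.0, abs=1e-12)
        assert s3 == pytest.approx(-3.0)
        assert tau == pytest.approx(3.0)

    def test_uniaxial_compression(self):
        s1, s2, s3, tau = principal(np.diag([0.0, 0.0, -12.0]))
        assert s1 == pytest.approx(0.0, abs=1e-15)
        assert s3 == pytest.approx(-12.0)
        assert tau == pytest.approx(6.0)

    def test_nonsymmetric_rejected(self):
        t = np.zeros((3, 3))
        t[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            principal(t)

    def test_rotation_invariance(self):
        """Principal values are invariant under rigid rotation."""
        rng = np.random.default_rng(42)
        a = rng.normal(size=(3, 3))
        t = 0.5 * (a + a.T)
        from scipy.spatial.transform import Rotation

        r = Rotation.from_euler("xyz", [31.0, -47.0, 118.0], degrees=True).as_matrix()
        rotated = r @ t @ r.T
        orig = principal(t)
        rot = principal(rotated)
        np.testing.assert_allclose(orig, rot, rtol=1e-8, atol=1e-12)
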