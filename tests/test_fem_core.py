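import numpy as np
import pytest

from septumfem.fem_core import (
    ElementError,
    Material,
    TipSpring,
    assemble_membrane,
    assemble_system,
    dkt_b_matrix,
    element_bending_mass,
    element_bending_stiffness,
    element_geometric_stiffness,
    element_membrane_mass,
    element_membrane_stiffness,
    tip_spring_from_cantilever,
)


@pytest.fixture
def random_triangle():
    rng = np.random.default_rng(7)
    c = rng.random((3, 2))
    if np.cross(c[1] - c[0], c[2] - c[0]) < 0:
        c = c[[0, 2, 1]]
    return c


class TestMaterial:
    def test_invalid_constants_rejected(self):
        with pytest.raises(ElementError):
            Material(E=-1.0)
        with pytest.raises(ElementError):
            Material(nu=0.5)
        with pytest.raises(ElementError):
            Material(rho=0.0)

    def test_default_bending_rigidity_value(self):
        # D = E t^3 / (12 (1 - nu^2)) at E = 5 MPa, t = 2 mm, nu = 0.32
        D = Material().bending_rigidity(2e-3)
        assert D == pytest.approx(3.7136e-3, rel=1e-3)


class TestTipSpring:
    def test_unit_inputs(self):
        assert tip_spring_from_cantilever(4.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_cubic_length_scaling(self):
        k1 = tip_spring_from_cantilever(5e6, 0.004, 0.01, 0.02)
        k2 = tip_spring_from_cantilever(5e6, 0.004, 0.01, 0.04)
        assert k1 / k2 == pytest.approx(8.0, rel=1e-12)

    def test_cartilage_beam_evaluates_to_625_newtons_per_metre(self):
        # 3EI/L^3 with I = w h^3 / 12: E=5 MPa, w=4 mm, h=10 mm, L=20 mm
        k = tip_spring_from_cantilever(5e6, 0.004, 0.01, 0.02)
        assert k == pytest.approx(625.0, rel=1e-12)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ElementError):
            tip_spring_from_cantilever(5e6, 0.0, 0.01, 0.02)
        with pytest.raises(ElementError):
            TipSpring(k=-1.0)


class TestMembraneElement:
    def test_symmetry_and_three_rigid_modes(self, random_triangle, material):
        K = element_membrane_stiffness(random_triangle, material, 2e-3)
        assert np.allclose(K, K.T, atol=1e-12 * np.abs(K).max())
        eigs = np.linalg.eigvalsh(K)
        scale = eigs[-1]
        assert np.all(np.abs(eigs[:3]) < 1e-10 * scale)  # 2 translations + 1 rotation
        assert np.all(eigs[3:] > 1e-10 * scale)

    def test_rigid_translation_gives_zero_force(self, random_triangle, material):
        K = element_membrane_stiffness(random_triangle, material, 2e-3)
        for vec in (np.tile([1.0, 0.0], 3), np.tile([0.0, 1.0], 3)):
            assert np.allclose(K @ vec, 0.0, atol=1e-12 * np.abs(K).max())

    def test_uniaxial_stretch_energy_matches_closed_form(self, material):
        # unit right triangle, u = eps*x: energy = 0.5 * E/(1-nu^2) * eps^2 * t * A
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        t, eps = 2e-3, 1e-3
        K = element_membrane_stiffness(tri, material, t)
        u = np.array([0.0, 0.0, eps, 0.0, 0.0, 0.0])  # u = eps*x at each node
        E_fem = 0.5 * u @ K @ u
        E_exact = 0.5 * material.E / (1 - material.nu**2) * eps**2 * t * 0.5
        assert E_fem == pytest.approx(E_exact, rel=1e-12)

    def test_zero_area_triangle_rejected(self, material):
        tri = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ElementError):
            element_membrane_stiffness(tri, material, 2e-3)


class TestBendingElement:
    def test_symmetry_and_three_rigid_modes(self, random_triangle, material):
        K = element_bending_stiffness(random_triangle, material, 2e-3)
        assert np.allclose(K, K.T, atol=1e-12 * np.abs(K).max())
        eigs = np.linalg.eigvalsh(K)
        scale = eigs[-1]
        assert np.sum(np.abs(eigs) < 1e-9 * scale) == 3

    def test_rigid_tilt_fields_carry_no_energy(self, random_triangle, material):
        K = element_bending_stiffness(random_triangle, material, 2e-3)
        c = random_triangle
        tilts = [
            np.array([1.0, 0.0, 0.0] * 3),                       # uniform translation
            np.concatenate([[y, 1.0, 0.0] for x, y in c]),       # tilt about x: w = y
            np.concatenate([[-x, 0.0, 1.0] for x, y in c]),      # tilt about y: w = -x
        ]
        for u in tilts:
            assert abs(u @ K @ u) < 1e-10 * np.abs(K).max()

    def test_constant_curvature_patch(self, material):
        """Two-element square patch reproduces a constant-curvature field exactly."""
        kx, ky, kxy = 0.3, -0.7, 0.45
        t = 2e-3

        def dofs(pts):
            out = []
            for x, y in pts:
                w = 0.5 * (kx * x * x + ky * y * y) + kxy * x * y
                out += [w, ky * y + kxy * x, -(kx * x + kxy * y)]  # thx=w,y thy=-w,x
            return np.array(out)

        tris = [
            np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]),
            np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
        ]
        E_fem = sum(
            0.5 * dofs(tr) @ element_bending_stiffness(tr, material, t) @ dofs(tr)
            for tr in tris
        )
        D = material.bending_rigidity(t)
        kap = np.array([kx, ky, 2 * kxy])
        Db = D * np.array(
            [[1, material.nu, 0], [material.nu, 1, 0], [0, 0, (1 - material.nu) / 2]]
        )
        assert E_fem == pytest.approx(0.5 * kap @ Db @ kap, rel=1e-10)

    def test_curvature_recovery_constant_field(self, material):
        kx, ky, kxy = 0.2, 0.5, -0.1
        tri = np.array([[0.1, 0.0], [1.2, 0.3], [0.4, 1.1]])
        u = []
        for x, y in tri:
            w = 0.5 * (kx * x * x + ky * y * y) + kxy * x * y
            u += [w, ky * y + kxy * x, -(kx * x + kxy * y)]
        B = dkt_b_matrix(tri, 1 / 3, 1 / 3)
        # B returns curvatures of beta = -grad w
        assert np.allclose(B @ np.array(u), -np.array([kx, ky, 2 * kxy]), rtol=1e-9)

    def test_mass_matrices_positive_definite(self, random_triangle, material):
        for M in (
            element_bending_mass(random_triangle, material, 2e-3),
            element_membrane_mass(random_triangle, material, 2e-3),
        ):
            assert np.all(np.linalg.eigvalsh(M) > 0)


class TestGeometricStiffnessElement:
    def test_hand_integrated_uniaxial_oracle(self):
        # unit right triangle, sigma = diag(s, 0), t: Kg_w = t*A*G^T s G with
        # grad N1 = (-1,-1), grad N2 = (1,0), grad N3 = (0,1)
        s, t = 1234.5, 2e-3
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        Kg = element_geometric_stiffness(tri, t, np.array([[s, 0.0], [0.0, 0.0]]))
        expect_w = t * 0.5 * s * np.array([[1, -1, 0], [-1, 1, 0], [0, 0, 0.0]])
        assert np.allclose(Kg[0::3, 0::3], expect_w, rtol=1e-12)
        assert np.count_nonzero(Kg[1::3, :]) == 0  # rotations unloaded
        assert np.count_nonzero(Kg[2::3, :]) == 0


class TestAssembly:
    def test_toy_assembly_matches_dense_brute_force(self, two_triangle_mesh, material):
        mesh = two_triangle_mesh
        Km, Mm = assemble_membrane(mesh, material)
        Kd = np.zeros((8, 8))
        for e, tri in enumerate(mesh.triangles):
            ke = element_membrane_stiffness(mesh.nodes[tri], material, mesh.thickness[e])
            dofs = np.concatenate([[2 * i, 2 * i + 1] for i in tri])
            for a in range(6):
                for b in range(6):
                    Kd[dofs[a], dofs[b]] += ke[a, b]
        assert np.allclose(Km.toarray(), Kd, rtol=1e-12)

    def test_spring_adds_exactly_k_to_tip_diagonals(self, two_triangle_mesh, material):
        k = 20e3
        s0 = assemble_system(two_triangle_mesh, material, None, fixed_labels=("ethmoid",))
        s1 = assemble_system(two_triangle_mesh, material, TipSpring(k), fixed_labels=("ethmoid",))
        tip = two_triangle_mesh.tip_node
        dKm = (s1.Km - s0.Km).toarray()
        dKb = (s1.Kb - s0.Kb).toarray()
        expect_m = np.zeros_like(dKm)
        expect_m[2 * tip, 2 * tip] = k
        expect_m[2 * tip + 1, 2 * tip + 1] = k
        expect_b = np.zeros_like(dKb)
        expect_b[3 * tip, 3 * tip] = k
        assert np.allclose(dKm, expect_m)
        assert np.allclose(dKb, expect_b)

    def test_zero_stiffness_spring_is_identity(self, two_triangle_mesh, material):
        s0 = assemble_system(two_triangle_mesh, material, None, fixed_labels=("ethmoid",))
        s1 = assemble_system(two_triangle_mesh, material, TipSpring(0.0), fixed_labels=("ethmoid",))
        assert (s0.Km != s1.Km).nnz == 0
        assert (s0.Kb != s1.Kb).nnz == 0

    def test_operators_symmetric_and_positive_definite(self, mesh, material):
        sys = assemble_system(mesh, material, TipSpring(20e3))
        for which in ("membrane", "bending"):
            K, M = sys.reduced(which)
            assert abs(K - K.T).max() == 0.0
            assert abs(M - M.T).max() == 0.0
            # smallest eigenvalues strictly positive (no rigid modes remain)
            from scipy.linalg import eigh

            lam_k = eigh(K.toarray(), eigvals_only=True, subset_by_index=[0, 0])
            lam_m = eigh(M.toarray(), eigvals_only=True, subset_by_index=[0, 0])
            assert lam_k[0] > 0
            assert lam_m[0] > 0

    def test_energy_nonnegative_for_random_vectors(self, mesh, material):
        sys = assemble_system(mesh, material, TipSpring(20e3))
        rng = np.random.default_rng(3)
        for which in ("membrane", "bending"):
            K, _ = sys.reduced(which)
            for _ in range(5):
                u = rng.standard_normal(K.shape[0])
                assert u @ (K @ u) >= 0

    def test_unknown_fixed_label_rejected(self, two_triangle_mesh, material):
        with pytest.raises(ValueError, match="unknown"):
            assemble_system(two_triangle_mesh, material, None, fixed_labels=("dorsal_free",))
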