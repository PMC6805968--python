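"""Laplacian operator/deformation and FEM stiffness/deformation."""

import numpy as np
import pytest
import scipy.sparse as sp

from meshreg.global_reg import ConvergencePolicy
from meshreg.local_reg import (FEMConfig, LaplacianConfig, build_laplacian,
                               fem_deform_step, fem_stiffness,
                               laplacian_deform_step, solve_laplacian_positions,
                               _rigid_basis, _tet_stiffness_matrix)
from meshreg.mesh_core import TriMesh, mean_bidirectional_distance, validate_mesh
from conftest import make_icosphere, make_tetrahedron


def bumped_sphere(radius=18.0, height=3.0):
    m = make_icosphere(2, radius)
    dirs = m.vertices / radius
    bump = np.exp(-((dirs - dirs[10]) ** 2).sum(axis=1) / 0.15)
    return m, m.with_vertices(m.vertices + dirs * (height * bump)[:, None])


# ----------------------------------------------------------------------
# Discrete Laplacian
# ----------------------------------------------------------------------

class TestBuildLaplacian:
    def test_tetrahedron_uniform_weights(self, tetra):
        L = build_laplacian(tetra, "uniform").toarray()
        expected = np.eye(4) - (1.0 - np.eye(4)) / 3.0
        np.testing.assert_allclose(L, expected, atol=1e-12)

    @pytest.mark.parametrize("weighting", ["uniform", "cotangent"])
    def test_constant_vector_in_null_space(self, weighting):
        m = make_icosphere(2, 10.0)
        L = build_laplacian(m, weighting)
        np.testing.assert_allclose(L @ np.ones(m.n_vertices), 0.0, atol=1e-10)

    def test_cotangent_on_flat_square_matches_hand_computation(self):
        # unit square split along the diagonal (0, 2) into two right
        # triangles: boundary edges see one 45-degree angle (cot = 1,
        # weight 1/2); the diagonal sees two 90-degree angles (weight 0)
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        f = np.array([[0, 1, 2], [0, 2, 3]])
        L = build_laplacian(TriMesh(v, f), "cotangent").toarray()
        expected = np.array([[1.0, -0.5, 0.0, -0.5],
                             [-0.5, 1.0, -0.5, 0.0],
                             [0.0, -0.5, 1.0, -0.5],
                             [-0.5, 0.0, -0.5, 1.0]])
        np.testing.assert_allclose(L, expected, atol=1e-12)

    def test_unknown_weighting_rejected(self, tetra):
        with pytest.raises(ValueError):
            build_laplacian(tetra, "mean-value")


class TestLaplacianSolve:
    def test_all_vertices_constrained_to_self_is_fixed_point(self):
        m = make_icosphere(2, 18.0)
        L = build_laplacian(m, "uniform")
        C = sp.identity(m.n_vertices, format="csr")
        out = solve_laplacian_positions(L, m.vertices, C, m.vertices, 1.0)
        np.testing.assert_allclose(out, m.vertices, atol=1e-9)

    def test_large_lambda_interpolates_arbitrary_target(self):
        m, tgt = bumped_sphere(height=1.0)
        L = build_laplacian(m, "uniform")
        C = sp.identity(m.n_vertices, format="csr")
        tgt_v = tgt.vertices + [2.0, -1.0, 0.5]
        out = solve_laplacian_positions(L, m.vertices, C, tgt_v, 1e6)
        assert np.abs(out - tgt_v).max() < 1e-6

    def test_no_constraints_zero_lambda_is_singular(self):
        m = make_icosphere(1, 5.0)
        L = build_laplacian(m, "uniform")
        C = sp.csr_matrix((0, m.n_vertices))
        with pytest.raises(ValueError):
            solve_laplacian_positions(L, m.vertices, C,
                                      np.empty((0, 3)), 0.0)


class TestLaplacianStep:
    def test_identity_pair_is_fixed_point(self):
        m = make_icosphere(2, 18.0)
        out, trace = laplacian_deform_step(m, m)
        assert np.abs(out.vertices - m.vertices).max() < 1e-9
        assert trace.final_objective < 1e-9

    def test_converges_onto_smooth_bump(self):
        m, tgt = bumped_sphere()
        out, trace = laplacian_deform_step(m, tgt)
        assert mean_bidirectional_distance(out, tgt) < 0.05
        assert validate_mesh(out) == []
        assert np.array_equal(out.faces, m.faces)

    def test_trace_monotone_non_increasing(self):
        m, tgt = bumped_sphere()
        _, trace = laplacian_deform_step(m, tgt)
        assert (np.diff(trace.objective_per_iteration) <= 1e-12).all()

    def test_partial_constraint_fraction_runs(self):
        m, tgt = bumped_sphere()
        cfg = LaplacianConfig(correspondence_fraction=0.5)
        out, _ = laplacian_deform_step(m, tgt, cfg)
        assert mean_bidirectional_distance(out, tgt) < 0.5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LaplacianConfig(constraint_weight=0.0)
        with pytest.raises(ValueError):
            LaplacianConfig(correspondence_fraction=0.0)
        with pytest.raises(ValueError):
            LaplacianConfig(weighting="nope")


# ----------------------------------------------------------------------
# FEM stiffness
# ----------------------------------------------------------------------

def independent_strain_energy(nodes, u, E, nu):
    """Independent oracle: elastic energy of a linear displacement field
    on one tetrahedron, from the continuum formula W = V/2 (lam tr(e)^2 +
    2 mu e:e) with the strain taken from the exact displacement gradient."""
    G = np.linalg.lstsq(
        np.hstack([nodes - nodes[0:1], np.ones((4, 1))]),
        u, rcond=None)[0][:3].T          # displacement gradient du/dx
    eps = 0.5 * (G + G.T)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    vol = abs(np.linalg.det(nodes[1:] - nodes[0])) / 6.0
    return vol * (0.5 * lam * np.trace(eps) ** 2 + mu * (eps * eps).sum())


class TestFemStiffness:
    @pytest.mark.parametrize("element", ["surface-membrane", "tetrahedral"])
    def test_symmetric_with_translation_null_space(self, element):
        m = make_icosphere(2, 10.0)
        K = fem_stiffness(m, FEMConfig(element_type=element))
        assert abs(K - K.T).max() < 1e-10 * abs(K).max()
        for k in range(3):
            t = np.zeros(3 * m.n_vertices)
            t[k::3] = 1.0
            assert np.abs(K @ t).max() < 1e-9

    def test_rigid_rotations_in_null_space(self):
        m = make_icosphere(2, 10.0)
        K = fem_stiffness(m, FEMConfig())
        R = _rigid_basis(m.vertices)
        assert np.abs(K @ R).max() < 1e-8

    def test_six_dimensional_null_space(self):
        m = make_icosphere(1, 5.0)
        K = fem_stiffness(m, FEMConfig()).toarray()
        w = np.linalg.eigvalsh(K)
        assert (np.abs(w[:6]) < 1e-8 * w[-1]).all()
        assert w[6] > 1e-6 * w[-1]

    def test_linear_in_youngs_modulus(self):
        m = make_icosphere(1, 5.0)
        K1 = fem_stiffness(m, FEMConfig(youngs_modulus=1.0))
        K2 = fem_stiffness(m, FEMConfig(youngs_modulus=2.0))
        assert abs(K2 - 2 * K1).max() < 1e-12

    @pytest.mark.parametrize("nu", [0.0, 0.3])
    def test_single_tet_matches_continuum_energy(self, nu):
        """u^T K u = 2 W(u) for linear fields on one element (independent
        continuum-mechanics oracle, no shared B-matrix code)."""
        tet = make_tetrahedron(5.0)
        K = fem_stiffness(tet, FEMConfig(youngs_modulus=1.0, poisson_ratio=nu,
                                         element_type="tetrahedral")).toarray()
        rng = np.random.default_rng(0)
        for _ in range(5):
            G = rng.normal(size=(3, 3)) * 0.1
            u = tet.vertices @ G.T          # linear displacement field
            quad = u.ravel() @ K @ u.ravel()
            energy = independent_strain_energy(tet.vertices, u, 1.0, nu)
            assert quad == pytest.approx(2 * energy, rel=1e-9)

    def test_explicit_degenerate_tet_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ValueError, match="volume"):
            _tet_stiffness_matrix(flat, 1.0, 0.3)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            FEMConfig(youngs_modulus=0.0)
        with pytest.raises(ValueError):
            FEMConfig(poisson_ratio=0.5)
        with pytest.raises(ValueError):
            FEMConfig(element_type="hexahedral")


class TestFemStep:
    def test_identity_pair_is_fixed_point(self):
        m = make_icosphere(2, 18.0)
        out, trace = fem_deform_step(m, m)
        assert np.abs(out.vertices - m.vertices).max() < 1e-9
        assert trace.final_objective < 1e-9

    def test_converges_onto_concentric_sphere(self):
        # uniform 10% expansion costs volumetric strain energy, so the
        # equilibrium accuracy is gain-dependent; a strong spring gain
        # lets the step reach the target closely
        m = make_icosphere(2, 18.0)
        tgt = m.with_vertices(m.vertices * 1.1)
        out, trace = fem_deform_step(m, tgt, FEMConfig(force_scale=100.0))
        assert mean_bidirectional_distance(out, tgt) < 0.1
        assert validate_mesh(out) == []

    def test_stiffer_poisson_coupling_fits_no_better(self):
        m, tgt = bumped_sphere()
        _, tr_soft = fem_deform_step(m, tgt, FEMConfig(poisson_ratio=0.0))
        _, tr_stiff = fem_deform_step(m, tgt, FEMConfig(poisson_ratio=0.49))
        assert tr_stiff.final_objective >= tr_soft.final_objective - 1e-9

    def test_trace_monotone_non_increasing(self):
        m, tgt = bumped_sphere()
        _, trace = fem_deform_step(m, tgt)
        assert (np.diff(trace.objective_per_iteration) <= 1e-12).all()

    def test_membrane_variant_runs(self):
        m, tgt = bumped_sphere()
        out, _ = fem_deform_step(m, tgt, FEMConfig(element_type="surface-membrane",
                                                   force_scale=1.0))
        assert mean_bidirectional_distance(out, tgt) < \
            mean_bidirectional_distance(m, tgt)
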