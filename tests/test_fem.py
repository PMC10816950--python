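"""Bogner-Fox-Schmidt element: shapes, assembly, interpolation, evaluation."""

import io

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy.io import mmread

from levelseg.domain import GridDomain, ScalarField
from levelseg.fem import (
    AssemblyError,
    FEMesh,
    MeshResolutionWarning,
    assemble_mass,
    assemble_weighted_stiffness,
    bfs_shape_eval,
    build_mesh,
    evaluate_fe,
    export_operator_mtx,
    hermite_basis_1d,
    hermite_interpolate,
    interpolant_from_callables,
    make_centroid_quadrature,
)


def unit_mesh(elements=(1, 1), pixels=(8, 8)):
    dom = GridDomain(shape=pixels, spacing=tuple(1 / p for p in pixels))
    return FEMesh(dom, elements)


def constant_interpolant(mesh, value=1.0):
    return hermite_interpolate(
        mesh,
        lambda pts, deriv: np.full(pts.shape[0], value) if sum(deriv) == 0
        else np.zeros(pts.shape[0]),
    )


# ---------------------------------------------------------------------------
# shape functions
# ---------------------------------------------------------------------------

class TestShapeFunctions:
    def test_kronecker_at_corner(self):
        mesh = unit_mesh()
        vals = bfs_shape_eval(mesh, (0.0, 0.0))
        expected = np.zeros(16)
        expected[0] = 1.0  # (corner 0, value-value) shape
        np.testing.assert_allclose(vals, expected, atol=1e-14)

    def test_value_shapes_partition_of_unity(self):
        # the four corner value-DOF shapes sum to 1 anywhere (tensor product
        # of H00 + H10 = 1 per axis)
        mesh = unit_mesh()
        corners, types = mesh._local_layout
        value_dofs = np.all(types == 0, axis=1)
        rng = np.random.default_rng(1)
        for s in rng.uniform(0, 1, size=(20, 2)):
            vals = bfs_shape_eval(mesh, s)
            assert abs(vals[value_dofs].sum() - 1.0) < 1e-12

    def test_slope_shape_unit_physical_derivative(self):
        mesh = unit_mesh(elements=(2, 2))  # element size 0.5
        d_vals = bfs_shape_eval(mesh, (0.0, 0.0), derivative_order=(1, 0))
        # local dof (corner (0,0), d/dx type) sits at index (0*2+1)*4 + 0
        assert abs(d_vals[4] - 1.0) < 1e-12
        vals = bfs_shape_eval(mesh, (0.0, 0.0))
        assert abs(vals[4]) < 1e-14

    def test_coords_outside_reference_raise(self):
        with pytest.raises(ValueError, match="outside"):
            bfs_shape_eval(unit_mesh(), (1.2, 0.5))

    def test_basis_1d_derivative_scaling(self):
        # d/dt of the slope shape at node 0 equals 1 for any element length
        for L in (0.25, 1.0, 3.0):
            B = hermite_basis_1d(np.array([0.0]), L, deriv=1)
            assert abs(B[0, 1] - 1.0) < 1e-13


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

class TestBuildMesh:
    def test_dof_counts(self):
        dom = GridDomain(shape=(200, 200), spacing=(1 / 200, 1 / 200))
        mesh = build_mesh(dom, (20, 20))
        assert mesh.n_nodes == 441
        assert mesh.n_dofs == 1764

    def test_single_element_has_16_dofs(self):
        dom = GridDomain(shape=(8, 8), spacing=(1 / 8, 1 / 8))
        mesh = build_mesh(dom, (1, 1))  # 64 px/element: no warning expected
        assert mesh.n_nodes == 4 and mesh.n_dofs == 16

    def test_warns_on_too_few_pixels_per_element(self):
        dom = GridDomain(shape=(20, 20), spacing=(0.05, 0.05))
        with pytest.warns(MeshResolutionWarning):
            build_mesh(dom, (10, 10))  # 4 px/element

    def test_no_warning_in_recommended_range(self, recwarn):
        dom = GridDomain(shape=(64, 64), spacing=(1 / 64, 1 / 64))
        build_mesh(dom, (8, 8))  # 64 px/element
        assert not any(isinstance(w.message, MeshResolutionWarning) for w in recwarn)

    def test_invalid_counts_raise(self):
        dom = GridDomain(shape=(8, 8), spacing=(1.0, 1.0))
        with pytest.raises(ValueError):
            FEMesh(dom, (0, 2))


# ---------------------------------------------------------------------------
# mass matrix
# ---------------------------------------------------------------------------

class TestMassMatrix:
    def test_unit_element_corner_entry(self):
        # symbolic: int_0^1 H00^2 = 13/35, tensorized -> (13/35)^2
        M = assemble_mass(unit_mesh()).toarray()
        assert abs(M[0, 0] - 169 / 1225) < 1e-10

    def test_reproduces_total_mass(self):
        mesh = unit_mesh(elements=(3, 3), pixels=(12, 12))
        M = assemble_mass(mesh)
        c = constant_interpolant(mesh).coefficients
        assert abs(c @ (M @ c) - 1.0) < 1e-12  # area of the unit square

    def test_element_size_scaling(self):
        # doubling the element size multiplies value-value entries by 4
        m1 = assemble_mass(unit_mesh()).toarray()
        dom2 = GridDomain(shape=(8, 8), spacing=(0.25, 0.25))
        m2 = assemble_mass(FEMesh(dom2, (1, 1))).toarray()
        assert abs(m2[0, 0] / m1[0, 0] - 4.0) < 1e-12

    def test_symmetric_positive_definite(self):
        mesh = unit_mesh(elements=(3, 3), pixels=(12, 12))
        M = assemble_mass(mesh).toarray()
        assert np.abs(M - M.T).max() < 1e-14
        assert np.linalg.eigvalsh(M).min() > 0


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------

class TestCentroidQuadrature:
    def test_midpoint_rule_weights(self):
        mesh = unit_mesh(elements=(2, 2), pixels=(10, 10))
        rule = make_centroid_quadrature(mesh, (0, 0), mesh.domain)
        assert rule.nodes.shape[0] == 25
        np.testing.assert_allclose(rule.weights, 0.01)
        assert abs(rule.weights.sum() - 0.25) < 1e-10

    def test_integrates_constants_exactly(self):
        mesh = unit_mesh(elements=(2, 2), pixels=(8, 8))
        rule = make_centroid_quadrature(mesh, (1, 1), mesh.domain)
        assert abs(np.sum(rule.weights * 3.0) - 3.0 * 0.25) < 1e-12

    def test_second_order_convergence_on_x_squared(self):
        # midpoint-rule error for int x^2 over one element drops ~p^-2
        errs = []
        for p in (8, 16, 32):
            mesh = unit_mesh(elements=(1, 1), pixels=(p, p))
            rule = make_centroid_quadrature(mesh, (0, 0), mesh.domain)
            approx = np.sum(rule.weights * rule.nodes[:, 0] ** 2)
            errs.append(abs(approx - 1.0 / 3.0))
        rates = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(rates > 1.9)

    def test_empty_element_raises(self):
        dom = GridDomain(shape=(4, 4), spacing=(0.25, 0.25))
        mesh = FEMesh(dom, (8, 8))  # more elements than pixels
        h = ScalarField(dom, np.ones((4, 4)))
        with pytest.raises(AssemblyError, match="coarser"):
            assemble_weighted_stiffness(mesh, h)


# ---------------------------------------------------------------------------
# weighted stiffness
# ---------------------------------------------------------------------------

def exact_unit_stiffness(mesh):
    """Oracle: exact Gauss assembly of 2*int(grad u . grad v) via the kron
    structure of the tensor-product basis (h identically 1)."""
    x, w = leggauss(6)
    mats = {}
    for a in range(2):
        L = mesh.element_size[a]
        s = 0.5 * (x + 1)
        ww = 0.5 * w * L
        B0 = hermite_basis_1d(s, L, 0)
        B1 = hermite_basis_1d(s, L, 1)
        mats[a] = (
            (B0 * ww[:, None]).T @ B0,
            (B1 * ww[:, None]).T @ B1,
        )
    (Mx, Kx), (My, Ky) = mats[0], mats[1]
    elem = 2.0 * (np.kron(Kx, My) + np.kron(Mx, Ky))
    n = mesh.n_dofs
    K = np.zeros((n, n))
    for e, dofs in enumerate(mesh.element_dof_indices):
        K[np.ix_(dofs, dofs)] += elem
    return K


class TestWeightedStiffness:
    def test_constants_in_kernel(self):
        mesh = unit_mesh(elements=(2, 2), pixels=(16, 16))
        h = ScalarField(mesh.domain, np.ones(mesh.domain.shape))
        K = assemble_weighted_stiffness(mesh, h)
        c = constant_interpolant(mesh).coefficients
        assert np.abs(K @ c).max() < 1e-10

    def test_matches_exact_gauss_oracle_for_unit_h(self):
        mesh = unit_mesh(elements=(4, 4), pixels=(128, 128))
        h = ScalarField(mesh.domain, np.ones(mesh.domain.shape))
        K = assemble_weighted_stiffness(mesh, h).toarray()
        K_exact = exact_unit_stiffness(mesh)
        scale = np.abs(K_exact).max()
        assert np.abs(K - K_exact).max() / scale < 1e-3

    def test_quadrature_convergence_to_exact_stiffness(self):
        errs = []
        for p in (32, 64, 128):
            mesh = unit_mesh(elements=(4, 4), pixels=(p, p))
            h = ScalarField(mesh.domain, np.ones(mesh.domain.shape))
            K = assemble_weighted_stiffness(mesh, h).toarray()
            K_exact = exact_unit_stiffness(mesh)
            errs.append(np.abs(K - K_exact).max() / np.abs(K_exact).max())
        rates = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(rates > 1.9)  # empirical order >= 2

    def test_symmetry_and_psd(self):
        rng = np.random.default_rng(7)
        mesh = unit_mesh(elements=(3, 3), pixels=(24, 24))
        h = ScalarField(mesh.domain, rng.uniform(0.1, 2.0, mesh.domain.shape))
        K = assemble_weighted_stiffness(mesh, h).toarray()
        assert np.abs(K - K.T).max() <= 1e-12 * np.abs(K).max()
        eig = np.linalg.eigvalsh(K)
        assert eig.min() > -1e-10 * eig.max()

    def test_kernel_is_exactly_the_constants(self):
        mesh = unit_mesh(elements=(2, 2), pixels=(16, 16))
        h = ScalarField(mesh.domain, np.full(mesh.domain.shape, 0.8))
        K = assemble_weighted_stiffness(mesh, h).toarray()
        eig = np.linalg.eigvalsh(K)
        tol = 1e-10 * eig.max()
        assert np.sum(eig < tol) == 1  # one zero eigenvalue: the constants


# ---------------------------------------------------------------------------
# evaluation and interpolation
# ---------------------------------------------------------------------------

class TestEvaluateAndInterpolate:
    def quad_fn(self, pts, deriv):
        x = pts[:, 0]
        if deriv == (0, 0):
            return x**2
        if deriv == (1, 0):
            return 2 * x
        return np.zeros(pts.shape[0])

    def test_reproduces_quadratic(self):
        mesh = unit_mesh(elements=(3, 3), pixels=(12, 12))
        c = hermite_interpolate(mesh, self.quad_fn)
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 1, (100, 2))
        np.testing.assert_allclose(evaluate_fe(mesh, c, pts), pts[:, 0] ** 2, atol=1e-12)
        np.testing.assert_allclose(
            evaluate_fe(mesh, c, pts, (1, 0)), 2 * pts[:, 0], atol=1e-11
        )

    def test_reproduces_random_bicubic(self):
        rng = np.random.default_rng(13)
        cx = rng.normal(size=4)
        cy = rng.normal(size=4)

        def poly(pts, deriv):
            px = np.polynomial.polynomial.polyder(cx, deriv[0]) if deriv[0] else cx
            py = np.polynomial.polynomial.polyder(cy, deriv[1]) if deriv[1] else cy
            return (np.polynomial.polynomial.polyval(pts[:, 0], px)
                    * np.polynomial.polynomial.polyval(pts[:, 1], py))

        mesh = unit_mesh(elements=(2, 2), pixels=(8, 8))
        c = hermite_interpolate(mesh, poly)
        pts = rng.uniform(0, 1, (100, 2))
        expected = poly(pts, (0, 0))
        np.testing.assert_allclose(evaluate_fe(mesh, c, pts), expected, atol=1e-12)

    def test_zero_function_gives_zero_vector(self):
        mesh = unit_mesh()
        c = hermite_interpolate(mesh, lambda p, d: np.zeros(p.shape[0]))
        assert np.all(c.coefficients == 0)

    def test_nodal_roundtrip(self):
        # interpolate then evaluate value/derivatives at the nodes: exact
        mesh = unit_mesh(elements=(2, 2), pixels=(8, 8))
        c = hermite_interpolate(mesh, self.quad_fn)
        nodes = mesh.node_coords()
        np.testing.assert_allclose(
            evaluate_fe(mesh, c, nodes), nodes[:, 0] ** 2, atol=1e-12
        )
        np.testing.assert_allclose(
            evaluate_fe(mesh, c, nodes, (1, 0)), 2 * nodes[:, 0], atol=1e-11
        )

    def test_c1_continuity_across_element_edges(self):
        mesh = unit_mesh(elements=(2, 2), pixels=(8, 8))

        def wave(p, d):
            fx = np.cos(p[:, 0]) if d[0] else np.sin(p[:, 0])
            fy = -np.sin(p[:, 1]) if d[1] else np.cos(p[:, 1])
            return fx * fy

        c = hermite_interpolate(mesh, wave)
        ys = np.linspace(0.05, 0.95, 9)
        eps = 1e-9
        for deriv in [(0, 0), (1, 0), (0, 1)]:
            left = evaluate_fe(mesh, c, np.column_stack([np.full(9, 0.5 - eps), ys]), deriv)
            right = evaluate_fe(mesh, c, np.column_stack([np.full(9, 0.5 + eps), ys]), deriv)
            np.testing.assert_allclose(left, right, atol=1e-6)

    def test_point_outside_domain_raises(self):
        mesh = unit_mesh()
        c = constant_interpolant(mesh)
        with pytest.raises(ValueError, match="outside"):
            evaluate_fe(mesh, c, np.array([[1.5, 0.5]]))

    def test_non_finite_nodal_data_raises(self):
        mesh = unit_mesh()
        with pytest.raises(ValueError, match="finite"):
            hermite_interpolate(mesh, lambda p, d: np.full(p.shape[0], np.nan))

    def test_interpolant_from_callables_defaults_cross_to_zero(self):
        mesh = unit_mesh(elements=(2, 2), pixels=(8, 8))
        fn = interpolant_from_callables(
            value=lambda p: p[:, 0] + p[:, 1],
            grad=lambda p: np.ones((p.shape[0], 2)),
        )
        c = hermite_interpolate(mesh, fn)
        pts = np.random.default_rng(0).uniform(0, 1, (20, 2))
        np.testing.assert_allclose(
            evaluate_fe(mesh, c, pts), pts.sum(axis=1), atol=1e-12
        )


class TestExport:
    def test_mtx_roundtrip(self, tmp_path):
        mesh = unit_mesh()
        M = assemble_mass(mesh)
        path = tmp_path / "mass.mtx"
        export_operator_mtx(M, path)
        back = mmread(path).toarray()
        np.testing.assert_allclose(back, M.toarray(), atol=1e-12)


# ---------------------------------------------------------------------------
# 3-D brick sanity
# ---------------------------------------------------------------------------

class TestBrickElement:
    def test_counts_and_constant_kernel(self):
        dom = GridDomain(shape=(8, 8, 8), spacing=(0.125,) * 3)
        mesh = FEMesh(dom, (2, 2, 2))
        assert mesh.dofs_per_node == 8 and mesh.local_dofs == 64
        assert mesh.n_dofs == 27 * 8
        h = ScalarField(dom, np.ones(dom.shape))
        K = assemble_weighted_stiffness(mesh, h)
        c = constant_interpolant(mesh).coefficients
        assert np.abs(K @ c).max() < 1e-10

    def test_trilinear_reproduction(self):
        dom = GridDomain(shape=(6, 6, 6), spacing=(1 / 6,) * 3)
        mesh = FEMesh(dom, (2, 2, 2))

        def fn(pts, deriv):
            vals = np.ones(pts.shape[0])
            for a in range(3):
                vals = vals * (1.0 if deriv[a] else pts[:, a])
            # derivative of x -> 1; so product over non-derived axes
            return vals

        c = hermite_interpolate(mesh, fn)
        pts = np.random.default_rng(4).uniform(0, 1, (50, 3))
        np.testing.assert_allclose(
            evaluate_fe(mesh, c, pts), pts.prod(axis=1), atol=1e-12
        )
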