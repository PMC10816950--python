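"""C1 Bogner-Fox-Schmidt rectangular finite elements.

The element is the tensor product of 1-D cubic Hermite bases: on each node a
2-D element carries 4 degrees of freedom (value, d/dx, d/dy, d2/dxdy; 16 per
element) and a 3-D brick carries 8 (64 per element).  The resulting space is
C1-conforming on uniform rectangular meshes, which is what keeps the zero
level set (and the approximated surface) smooth.

Two assembly routes are provided:

* ``assemble_mass`` integrates products of basis functions exactly with a
  Gauss-Legendre rule (the integrand is polynomial and involves no imaged
  field);
* ``assemble_weighted_stiffness`` integrates ``2 * h * grad(u) . grad(v)``
  with the voxel-centroid midpoint rule, because the diffusivity h is only
  known at pixel/voxel centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import sparse
from scipy.io import mmwrite

from .domain import GridDomain, ScalarField

__all__ = [
    "MeshResolutionWarning",
    "AssemblyError",
    "FEMesh",
    "DofVector",
    "QuadratureRule",
    "hermite_basis_1d",
    "bfs_shape_eval",
    "build_mesh",
    "assemble_mass",
    "assemble_weighted_stiffness",
    "make_centroid_quadrature",
    "evaluate_fe",
    "hermite_interpolate",
    "interpolant_from_callables",
    "export_operator_mtx",
]


class MeshResolutionWarning(UserWarning):
    """Pixels-per-element outside the recommended 25..100 range."""


class AssemblyError(RuntimeError):
    """Quadrature/assembly failure (e.g. an element without quadrature nodes)."""


# Reference cubic Hermite shape functions on [0, 1], ascending power
# coefficients; order: value@0, slope@0, value@1, slope@1.
_HERMITE_COEFFS = np.array(
    [
        [1.0, 0.0, -3.0, 2.0],  # H00: 1 - 3 s^2 + 2 s^3
        [0.0, 1.0, -2.0, 1.0],  # H01: s - 2 s^2 + s^3
        [0.0, 0.0, 3.0, -2.0],  # H10: 3 s^2 - 2 s^3
        [0.0, 0.0, -1.0, 1.0],  # H11: -s^2 + s^3
    ]
)


def hermite_basis_1d(s: np.ndarray, length: float, deriv: int = 0) -> np.ndarray:
    """Evaluate the four 1-D Hermite shapes (or a derivative) on one element.

    ``s`` is the reference coordinate in [0, 1]; ``length`` the physical
    element size.  Slope-DOF shapes are scaled by ``length`` so that the
    corresponding coefficient is the *physical* derivative at the node, and
    the requested derivative is taken with respect to the physical
    coordinate.  Returns an array of shape ``s.shape + (4,)``.
    """
    if deriv < 0 or deriv > 3:
        raise ValueError("derivative order must be in 0..3")
    s = np.asarray(s, dtype=float)
    coeffs = _HERMITE_COEFFS
    for _ in range(deriv):
        coeffs = coeffs[:, 1:] * np.arange(1, coeffs.shape[1])
    powers = s[..., None, None] ** np.arange(coeffs.shape[1])
    vals = np.sum(coeffs * powers, axis=-1)  # (..., 4)
    scale = np.array([1.0, length, 1.0, length]) * length ** (-deriv)
    return vals * scale


@dataclass
class QuadratureRule:
    """Nodes (physical points) and positive weights tiling a region."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("quadrature weights must be positive")


class FEMesh:
    """Uniform rectangular BFS mesh covering the physical extent of a domain.

    Nodes sit on the corners of the elements; each node carries
    ``2**ndim`` degrees of freedom (all mixed first-order partials).  The
    global DOF id of node ``n`` and derivative-type ``t`` is
    ``n * 2**ndim + t`` with ``t``'s bits ordered by axis.
    """

    def __init__(self, domain: GridDomain, elements_per_axis: Sequence[int]):
        elements = tuple(int(e) for e in elements_per_axis)
        if len(elements) != domain.ndim:
            raise ValueError("elements_per_axis must match the domain dimension")
        if any(e < 1 for e in elements):
            raise ValueError(f"element counts must be >= 1, got {elements}")
        self.domain = domain
        self.elements_per_axis = elements
        self.element_size = tuple(
            ext / e for ext, e in zip(domain.extent, elements)
        )
        self.node_counts = tuple(e + 1 for e in elements)

    # -- sizes ---------------------------------------------------------------
    @property
    def ndim(self) -> int:
        return self.domain.ndim

    @property
    def n_elements(self) -> int:
        return int(np.prod(self.elements_per_axis))

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.node_counts))

    @property
    def dofs_per_node(self) -> int:
        return 2**self.ndim

    @property
    def n_dofs(self) -> int:
        return self.n_nodes * self.dofs_per_node

    @property
    def local_dofs(self) -> int:
        return 4**self.ndim

    # -- geometry ------------------------------------------------------------
    def axis_nodes(self, axis: int) -> np.ndarray:
        return self.domain.origin[axis] + np.arange(self.node_counts[axis]) * self.element_size[axis]

    def node_coords(self) -> np.ndarray:
        mesh = np.meshgrid(*[self.axis_nodes(a) for a in range(self.ndim)], indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Element multi-index and local [0,1] coordinates for each point.

        Points exactly on an interior element edge are assigned to the
        lower-index element; points outside the closed extent raise.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.ndim:
            raise ValueError(f"points must be (n, {self.ndim})")
        eidx = np.empty(pts.shape, dtype=np.int64)
        local = np.empty(pts.shape)
        for a in range(self.ndim):
            x = pts[:, a] - self.domain.origin[a]
            ext = self.domain.extent[a]
            tol = 1e-12 * max(ext, 1.0)
            if np.any(x < -tol) or np.any(x > ext + tol):
                bad = pts[(x < -tol) | (x > ext + tol)][0]
                raise ValueError(f"point {tuple(bad)} lies outside the mesh domain")
            h = self.element_size[a]
            e = np.floor(x / h).astype(np.int64)
            # boundary ties toward the lower-index element
            on_edge = (x == e * h) & (e > 0)
            e[on_edge] -= 1
            e = np.clip(e, 0, self.elements_per_axis[a] - 1)
            eidx[:, a] = e
            local[:, a] = np.clip(x / h - e, 0.0, 1.0)
        return eidx, local

    # -- DOF maps ------------------------------------------------------------
    @cached_property
    def _local_layout(self) -> tuple[np.ndarray, np.ndarray]:
        """(corner offsets, derivative types), each (local_dofs, ndim) of 0/1.

        Local index l decomposes per axis into a base-4 digit
        ``2 * corner + deriv`` so that element matrices are Kronecker
        products of the 1-D 4x4 matrices.
        """
        d = self.ndim
        corners = np.empty((self.local_dofs, d), dtype=np.int64)
        types = np.empty((self.local_dofs, d), dtype=np.int64)
        for l in range(self.local_dofs):
            for a in range(d):
                digit = (l // 4 ** (d - 1 - a)) % 4
                corners[l, a] = digit // 2
                types[l, a] = digit % 2
        return corners, types

    @cached_property
    def element_dof_indices(self) -> np.ndarray:
        """Global DOF index for each (element, local dof), shape (n_elems, 4**ndim)."""
        d = self.ndim
        corners, types = self._local_layout
        emesh = np.indices(self.elements_per_axis).reshape(d, -1)  # (d, n_elems)
        out = np.empty((self.n_elements, self.local_dofs), dtype=np.int64)
        type_ids = np.array(
            [sum(types[l, a] << (d - 1 - a) for a in range(d)) for l in range(self.local_dofs)]
        )
        for l in range(self.local_dofs):
            node_multi = emesh + corners[l][:, None]
            node_id = np.ravel_multi_index(tuple(node_multi), self.node_counts)
            out[:, l] = node_id * self.dofs_per_node + type_ids[l]
        return out

    def dofs_for_points(self, eidx: np.ndarray) -> np.ndarray:
        elem_id = np.ravel_multi_index(tuple(eidx.T), self.elements_per_axis)
        return self.element_dof_indices[elem_id]

    def tensor_basis(self, local: np.ndarray, deriv: Sequence[int]) -> np.ndarray:
        """All ``4**ndim`` shape values (per requested mixed derivative) at the
        given local coordinates; shape (n_points, 4**ndim)."""
        n = local.shape[0]
        out = np.ones((n, 1))
        for a in range(self.ndim):
            B = hermite_basis_1d(local[:, a], self.element_size[a], deriv[a])  # (n,4)
            out = (out[:, :, None] * B[:, None, :]).reshape(n, -1)
        return out

    def summary(self) -> str:
        px = [s / e for s, e in zip(self.domain.shape, self.elements_per_axis)]
        return (
            f"BFS mesh: {self.elements_per_axis} elements, {self.n_nodes} nodes, "
            f"{self.dofs_per_node} DOFs/node, {self.n_dofs} DOFs total; "
            f"element size {tuple(round(h, 6) for h in self.element_size)}; "
            f"~{np.prod(px):.0f} pixels/element"
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<FEMesh {self.elements_per_axis} on {self.domain.shape}>"


@dataclass
class DofVector:
    """FE coefficient vector: nodal values and mixed partials."""

    mesh: FEMesh
    coefficients: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (self.mesh.n_dofs,):
            raise ValueError(
                f"coefficient vector has length {c.shape}, expected ({self.mesh.n_dofs},)"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("coefficient vector contains non-finite entries")
        self.coefficients = c

    def copy(self) -> "DofVector":
        return DofVector(self.mesh, self.coefficients.copy())


def build_mesh(domain: GridDomain, elements_per_axis: Sequence[int]) -> FEMesh:
    """Build a uniform BFS mesh; warn when pixels-per-element leave ~25..100.

    The recommended density (roughly 25 to 100 pixels per element) balances
    quadrature accuracy of the voxel-centroid rule against system size.
    """
    mesh = FEMesh(domain, elements_per_axis)
    px_per_elem = np.prod([s / e for s, e in zip(domain.shape, mesh.elements_per_axis)])
    if not (25.0 <= px_per_elem <= 100.0):
        warnings.warn(
            f"{px_per_elem:.1f} pixels per element is outside the recommended "
            "25..100 range; quadrature accuracy or system size may suffer",
            MeshResolutionWarning,
            stacklevel=2,
        )
    return mesh


def bfs_shape_eval(
    mesh: FEMesh, local_coords: Sequence[float], derivative_order: Sequence[int] | None = None
) -> np.ndarray:
    """Values of all element shape functions at one reference point.

    ``local_coords`` lies in the reference square/cube [0,1]**ndim; the
    shapes are mapped to the physical element via the mesh's element size, so
    the Kronecker property holds for physical derivatives at the corners.
    """
    lc = np.asarray(local_coords, dtype=float)
    if lc.shape != (mesh.ndim,):
        raise ValueError(f"local_coords must have length {mesh.ndim}")
    if np.any(lc < 0) or np.any(lc > 1):
        raise ValueError(f"local coords {tuple(lc)} outside the reference element")
    deriv = (0,) * mesh.ndim if derivative_order is None else tuple(derivative_order)
    if any(d_ < 0 or d_ > 2 for d_ in deriv):
        raise ValueError("derivative order must be <= 2 per axis")
    return mesh.tensor_basis(lc[None, :], deriv)[0]


def _gauss_mass_1d(length: float, npts: int = 4) -> np.ndarray:
    """Exact 4x4 one-dimensional Hermite mass matrix on an element of the
    given length (degree-6 integrand; 4 Gauss points are exact)."""
    x, w = leggauss(npts)
    s = 0.5 * (x + 1.0)
    w = 0.5 * w * length
    B = hermite_basis_1d(s, length, 0)  # (npts, 4)
    return (B * w[:, None]).T @ B


def assemble_mass(mesh: FEMesh) -> sparse.csr_matrix:
    """Mass matrix with entries ``int(phi_j phi_l)``, exact Gauss integration.

    Symmetric positive definite; its kron structure follows from the
    tensor-product basis on the uniform mesh.
    """
    elem = np.array([[1.0]])
    for a in range(mesh.ndim):
        elem = np.kron(elem, _gauss_mass_1d(mesh.element_size[a]))
    edofs = mesh.element_dof_indices
    n_loc = mesh.local_dofs
    rows = np.repeat(edofs, n_loc, axis=1).ravel()
    cols = np.tile(edofs, (1, n_loc)).ravel()
    data = np.tile(elem.ravel(), mesh.n_elements)
    M = sparse.coo_matrix((data, (rows, cols)), shape=(mesh.n_dofs, mesh.n_dofs))
    return M.tocsr()


def _bin_centroids(mesh: FEMesh, quad_domain: GridDomain):
    pts = quad_domain.centroids()
    eidx, local = mesh.locate(pts)
    elem_id = np.ravel_multi_index(tuple(eidx.T), mesh.elements_per_axis)
    counts = np.bincount(elem_id, minlength=mesh.n_elements)
    if np.any(counts == 0):
        empty = int(np.argmin(counts))
        raise AssemblyError(
            f"element {np.unravel_index(empty, mesh.elements_per_axis)} contains "
            "no pixel centroid; use a coarser mesh (fewer, larger elements)"
        )
    return pts, eidx, local, elem_id


def make_centroid_quadrature(
    mesh: FEMesh, element: Sequence[int], quad_domain: GridDomain
) -> QuadratureRule:
    """Voxel-centroid (midpoint) quadrature restricted to one element."""
    pts, eidx, _, elem_id = _bin_centroids(mesh, quad_domain)
    target = np.ravel_multi_index(tuple(int(e) for e in element), mesh.elements_per_axis)
    sel = elem_id == target
    return QuadratureRule(pts[sel], np.full(int(sel.sum()), quad_domain.cell_volume))


def assemble_weighted_stiffness(mesh: FEMesh, h: ScalarField) -> sparse.csr_matrix:
    """Weighted stiffness: ``2 * sum_i lambda_i h(x_i) grad(phi_j).grad(phi_l)``.

    Quadrature nodes are the centroids of ``h``'s grid cells (midpoint rule,
    weight = cell volume); the factor 2 of the bilinear form is included.
    Symmetric positive semidefinite with constants in its kernel.
    """
    _, eidx, local, _ = _bin_centroids(mesh, h.domain)
    gdofs = mesh.dofs_for_points(eidx)  # (N, local_dofs)
    N = gdofs.shape[0]
    w = 2.0 * h.domain.cell_volume * h.values.ravel(order="C")
    rows = np.repeat(np.arange(N), mesh.local_dofs)
    cols = gdofs.ravel()
    K = sparse.csr_matrix((mesh.n_dofs, mesh.n_dofs))
    for a in range(mesh.ndim):
        deriv = tuple(1 if b == a else 0 for b in range(mesh.ndim))
        Da = mesh.tensor_basis(local, deriv)  # (N, local_dofs)
        P = sparse.csr_matrix((Da.ravel(), (rows, cols)), shape=(N, mesh.n_dofs))
        K = K + P.T @ P.multiply(w[:, None]).tocsr()
    return K.tocsr()


def evaluate_fe(
    mesh: FEMesh,
    coeffs: DofVector,
    points: np.ndarray,
    derivative_order: Sequence[int] | None = None,
) -> np.ndarray:
    """Evaluate the piecewise-polynomial FE function (or a derivative) at
    arbitrary physical points inside the domain."""
    deriv = (0,) * mesh.ndim if derivative_order is None else tuple(derivative_order)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    eidx, local = mesh.locate(pts)
    B = mesh.tensor_basis(local, deriv)
    gdofs = mesh.dofs_for_points(eidx)
    return np.sum(B * coeffs.coefficients[gdofs], axis=1)


def hermite_interpolate(
    mesh: FEMesh,
    fn: Callable[[np.ndarray, tuple[int, ...]], np.ndarray],
) -> DofVector:
    """Interpolate a smooth function into the FE space.

    ``fn(points, deriv)`` must return the mixed partial derivative indicated
    by the 0/1 multi-index ``deriv`` at the given points; it is called once
    per DOF type on the full node set.  The resulting FE function matches the
    input's nodal values and derivatives exactly.
    """
    nodes = mesh.node_coords()
    coeffs = np.empty(mesh.n_dofs)
    d = mesh.ndim
    for t in range(mesh.dofs_per_node):
        deriv = tuple((t >> (d - 1 - a)) & 1 for a in range(d))
        vals = np.asarray(fn(nodes, deriv), dtype=float)
        if vals.shape != (mesh.n_nodes,):
            raise ValueError("interpolation callable returned a wrong-shaped array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite nodal data in interpolation")
        coeffs[t :: mesh.dofs_per_node] = vals
    return DofVector(mesh, coeffs)


def interpolant_from_callables(
    value: Callable[[np.ndarray], np.ndarray],
    grad: Callable[[np.ndarray], np.ndarray] | None = None,
) -> Callable[[np.ndarray, tuple[int, ...]], np.ndarray]:
    """Adapter for ``hermite_interpolate`` from value (+ optional gradient).

    Missing derivative data (including every cross derivative) defaults to 0,
    the standard BFS practice; this only affects O(h^2) interpolation error.
    """

    def fn(points: np.ndarray, deriv: tuple[int, ...]) -> np.ndarray:
        order = sum(deriv)
        if order == 0:
            return np.asarray(value(points), dtype=float)
        if order == 1 and grad is not None:
            axis = deriv.index(1)
            g = np.asarray(grad(points), dtype=float)
            return g[:, axis]
        return np.zeros(points.shape[0])

    return fn


def export_operator_mtx(op: sparse.spmatrix, path) -> None:
    """Write an assembled operator in MatrixMarket format (debugging aid)."""
    mmwrite(str(path), sparse.coo_matrix(op))
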