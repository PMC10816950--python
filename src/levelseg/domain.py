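"""Core containers: rectangular grids, scalar fields, constraint sets, weights.

Coordinate convention (used everywhere in this package): grids are
cell-centered with 0-based indices.  ``origin`` is the physical coordinate of
the *corner* of the domain, and the centroid of cell ``(i, j)`` sits at
``origin + (i + 0.5) * spacing`` per axis.  All constraint points and all
evaluation points are expressed in these physical coordinates, in array axis
order (for an image loaded from file: axis 0 = row, axis 1 = column).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridDomain",
    "ScalarField",
    "ConstraintSet",
    "ModelWeights",
]


@dataclass(frozen=True)
class GridDomain:
    """A rectangular pixel/voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of cells per axis; every extent must be >= 2.
    spacing : tuple of float
        Physical size of one cell per axis; strictly positive.
    origin : tuple of float, optional
        Physical coordinate of the domain corner (defaults to zero).
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        if any(n < 2 for n in shape):
            raise ValueError(f"all grid extents must be >= 2, got {shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != len(shape):
            raise ValueError("spacing and shape must have the same length")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        origin = self.origin
        if origin is None:
            origin = (0.0,) * len(shape)
        origin = tuple(float(o) for o in origin)
        if len(origin) != len(shape):
            raise ValueError("origin and shape must have the same length")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical side lengths, shape * spacing."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def upper(self) -> tuple[float, ...]:
        return tuple(o + e for o, e in zip(self.origin, self.extent))

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def diameter(self) -> float:
        """Length of the domain diagonal."""
        return float(np.sqrt(sum(e * e for e in self.extent)))

    def axis_centroids(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def centroid_mesh(self) -> list[np.ndarray]:
        """Cell-centroid coordinates as a dense ``meshgrid`` (``indexing='ij'``)."""
        axes = [self.axis_centroids(a) for a in range(self.ndim)]
        return list(np.meshgrid(*axes, indexing="ij"))

    def centroids(self) -> np.ndarray:
        """All cell centroids, ``(n_cells, ndim)``, C-order raveled."""
        mesh = self.centroid_mesh()
        return np.stack([m.ravel() for m in mesh], axis=1)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether each point lies in the *closed* physical extent."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.origin)
        hi = np.asarray(self.upper)
        return np.all((pts >= lo) & (pts <= hi), axis=1)


@dataclass
class ScalarField:
    """One scalar value per grid cell.

    Holds the image ``I``, the distance field ``d_D``, the edge potential
    ``g``, the diffusivity ``h``, and finite-difference gradient components.
    Values must be finite everywhere.
    """

    domain: GridDomain
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.domain.shape:
            raise ValueError(
                f"values shape {values.shape} does not match domain shape "
                f"{self.domain.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("scalar field contains non-finite values")
        self.values = values

    def with_values(self, values: np.ndarray) -> "ScalarField":
        return ScalarField(self.domain, values)

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())


@dataclass
class ConstraintSet:
    """The geometric dataset D: points the contour must approximate.

    Curve or patch constraints are handled by densely sampling them to a
    point set before construction; the distance field only ever needs points.
    """

    points: np.ndarray
    label: str = ""

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size and pts.ndim != 2:
            raise ValueError("constraint points must form an (n, ndim) array")
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("constraint points must be finite")
        self.points = pts

    def __len__(self) -> int:
        return 0 if self.points.size == 0 else self.points.shape[0]

    def validate_in(self, domain: GridDomain) -> None:
        if len(self) == 0:
            raise ValueError("constraint set is empty")
        if self.points.shape[1] != domain.ndim:
            raise ValueError(
                f"constraint points are {self.points.shape[1]}-D but the "
                f"domain is {domain.ndim}-D"
            )
        inside = domain.contains(self.points)
        if not np.all(inside):
            bad = self.points[~inside][0]
            raise ValueError(
                f"constraint point {tuple(bad)} lies outside the domain "
                f"extent {tuple(domain.origin)}..{tuple(domain.upper)}"
            )


@dataclass(frozen=True)
class ModelWeights:
    """Fidelity/edge trade-off of the energy.

    ``alpha`` weights the squared distance to the constraint set (fidelity to
    D), ``beta`` weights the squared edge potential (attraction to strong
    image gradients).  Both are nonnegative and at least one is positive.
    """

    alpha: float
    beta: float

    def __post_init__(self):
        a, b = float(self.alpha), float(self.beta)
        if a < 0 or b < 0:
            raise ValueError(f"alpha and beta must be >= 0, got {a}, {b}")
        if a + b <= 0:
            raise ValueError("alpha + beta must be > 0")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
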