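"""Implicit time discretization and the evolution loop.

The semi-discrete problem is the weighted diffusion

    eps * dPhi/dt = 2 div(h grad Phi),        h = alpha d_D^2 + beta g^2,

with natural (do-nothing) boundary conditions.  Backward Euler in time and
the BFS space in space give, per step, the constant SPD system

    R alpha^m = eps M alpha^(m-1),     R = eps M + dt K,

where M is the mass matrix and K the weighted stiffness.  R does not depend
on the step because h is time-independent, so it is factorized once.  The
scheme is unconditionally stable and dissipates the quadratic energy
``sum_i lambda_i h(x_i) |grad Phi(x_i)|^2`` monotonically for any dt.

Two modes are exposed:

* ``segmentation`` (alpha, beta >= 0, image required): the zero level set of
  Phi, started as a cone, migrates toward low diffusivity -- image edges and
  user constraint points -- and parks there;
* ``approximation`` (beta = 0, scattered points required): the same
  evolution smooths a surface fitted to a point cloud, with the diffusivity
  vanishing at the data so the fit stays pinned there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.sparse import csc_matrix, spmatrix
from scipy.sparse.linalg import splu

from . import fields
from .domain import ConstraintSet, GridDomain, ModelWeights, ScalarField
from .fem import (
    DofVector,
    FEMesh,
    assemble_mass,
    assemble_weighted_stiffness,
    build_mesh,
    evaluate_fe,
    hermite_interpolate,
)

__all__ = [
    "EvolutionConfig",
    "LevelSetState",
    "EvolutionSystem",
    "cone_initializer",
    "build_system",
    "step",
    "energy",
    "run",
    "segment",
    "approximate",
    "evolve",
    "SegmentationResult",
    "ApproximationResult",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """All tunables of one evolution run.

    Only the ratio ``dt / epsilon`` enters the discrete flow, so ``epsilon``
    sets the pace of the evolution relative to the time step.  The class
    defaults are the segmentation operating point on unit-normalized images:
    dt = 0.3 with epsilon = 1e4 gives an effective step of 3e-5 and a
    500-step horizon T/epsilon = 0.015, which sits inside the window where
    the zero level has settled onto edges/constraints but the field has not
    yet relaxed to its (uninformative) constant steady state.  Use
    :meth:`approximation_defaults` for the surface-fitting mode, whose
    horizon is the smoothing bandwidth and therefore much shorter.

    ``elements`` of ``None`` auto-sizes the mesh to ~64 pixels per element.
    """

    alpha: float = 1.0
    beta: float = 1.0
    epsilon: float = 1e4
    dt: float = 0.3
    max_steps: int = 500
    stop_tol: float = 1e-6
    seed: int = 0
    mode: str = "segmentation"
    sigma_px: float = 1.0
    grad_prescale: float = 1.0
    elements: tuple[int, ...] | None = None
    cone_center: tuple[float, ...] | None = None
    cone_radius: float | None = None
    # approximation-mode geometry: "heightfield" (2-D mesh carrying heights)
    # or "volume" (3-D level set over the cloud's bounding box)
    approx_geometry: str = "heightfield"
    quad_cells_per_element: int = 8
    z_pad: float = 0.25

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.stop_tol < 0:
            raise ValueError("stop_tol must be >= 0")
        if self.mode not in ("segmentation", "approximation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.approx_geometry not in ("heightfield", "volume"):
            raise ValueError(f"unknown approx_geometry {self.approx_geometry!r}")
        ModelWeights(self.alpha, self.beta)  # validates signs

    @property
    def weights(self) -> ModelWeights:
        return ModelWeights(self.alpha, self.beta)

    @classmethod
    def approximation_defaults(cls, **overrides) -> "EvolutionConfig":
        """Defaults for the data-approximation mode (beta = 0).

        The evolution horizon T = max_steps * dt acts as the smoothing
        bandwidth: the default T = 0.02 (20 steps of 1e-3, the recommended
        step magnitude) applies a diffusion length of about half the mean
        inter-point spacing of survey-scale clouds on the unit square --
        mild denoising without eroding resolved relief.  Raise the horizon
        for noisier data.
        """
        base = dict(
            mode="approximation", alpha=1.0, beta=0.0, epsilon=1.0,
            dt=1e-3, max_steps=20, stop_tol=1e-6,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class LevelSetState:
    """The evolving FE function: coefficients, step index, energy, history."""

    coeffs: DofVector
    step_index: int = 0
    energy: float = 0.0
    history: list[dict] = field(default_factory=list)


@dataclass
class EvolutionSystem:
    """R = eps M + dt K with a reusable sparse LU factorization."""

    R: csc_matrix
    mass: spmatrix
    stiffness: spmatrix
    config: EvolutionConfig
    _lu: object = None

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return self._lu.solve(rhs)


def build_system(mass: spmatrix, stiffness: spmatrix, config: EvolutionConfig) -> EvolutionSystem:
    """Assemble and factorize the per-step operator R = eps M + dt K."""
    if mass.shape != stiffness.shape:
        raise ValueError("mass and stiffness operators must share a dimension")
    R = (config.epsilon * mass + config.dt * stiffness).tocsc()
    try:
        lu = splu(R)
    except RuntimeError as exc:  # pragma: no cover - h >= h_min makes R SPD
        raise RuntimeError(
            f"factorization of R failed ({exc}); the system should be SPD "
            "whenever the diffusivity is floored at a positive value"
        ) from exc
    return EvolutionSystem(R=R, mass=mass, stiffness=stiffness, config=config, _lu=lu)


def energy(coeffs: DofVector | np.ndarray, stiffness: spmatrix) -> float:
    """Spatial energy ``0.5 c^T K c`` = ``sum_i lambda_i h(x_i)|grad Phi|^2``.

    The assembled K carries the bilinear form's factor 2, hence the 1/2 here.
    """
    c = coeffs.coefficients if isinstance(coeffs, DofVector) else np.asarray(coeffs)
    return float(0.5 * c @ (stiffness @ c))


def step(state: LevelSetState, system: EvolutionSystem) -> LevelSetState:
    """One backward-Euler step: solve ``R alpha^m = eps M alpha^(m-1)``."""
    cfg = system.config
    c_old = state.coeffs.coefficients
    rhs = cfg.epsilon * (system.mass @ c_old)
    c_new = system.solve(rhs)
    resid = np.linalg.norm(system.R @ c_new - rhs)
    if not np.isfinite(resid) or resid > 1e-8 * max(np.linalg.norm(rhs), 1e-300):
        raise RuntimeError(
            f"linear solve failed: relative residual "
            f"{resid / max(np.linalg.norm(rhs), 1e-300):.3e}"
        )
    denom = np.linalg.norm(c_old)
    rel = np.linalg.norm(c_new - c_old) / denom if denom > 0 else 0.0
    e = energy(c_new, system.stiffness)
    hist = state.history + [
        {"step": state.step_index + 1, "energy": e, "rel_change": rel}
    ]
    return LevelSetState(
        coeffs=DofVector(state.coeffs.mesh, c_new),
        step_index=state.step_index + 1,
        energy=e,
        history=hist,
    )


def run(
    state: LevelSetState,
    system: EvolutionSystem,
    callback: Callable[[LevelSetState], None] | None = None,
) -> LevelSetState:
    """March until the relative coefficient change drops below ``stop_tol``
    or ``max_steps`` is reached."""
    cfg = system.config
    state.energy = energy(state.coeffs, system.stiffness)
    for _ in range(cfg.max_steps):
        state = step(state, system)
        if callback is not None:
            callback(state)
        if state.history[-1]["rel_change"] < cfg.stop_tol:
            break
    return state


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def cone_initializer(
    center: Sequence[float], radius: float, mesh: FEMesh
) -> DofVector:
    """Hermite interpolant of the cone ``Phi0(x) = radius - |x - center|``.

    The zero level is the circle/sphere of the given radius; gradient DOFs
    come from the analytic cone gradient, with the apex gradient and all
    cross derivatives set to 0.
    """
    c = np.asarray(center, dtype=float)
    if c.shape != (mesh.ndim,):
        raise ValueError(f"center must have length {mesh.ndim}")
    if not bool(mesh.domain.contains(c[None, :])[0]):
        raise ValueError(f"cone center {tuple(c)} lies outside the domain")
    if radius <= 0:
        raise ValueError(f"cone radius must be > 0, got {radius}")

    def fn(points: np.ndarray, deriv: tuple[int, ...]) -> np.ndarray:
        diff = points - c
        rho = np.sqrt(np.sum(diff * diff, axis=1))
        order = sum(deriv)
        if order == 0:
            return radius - rho
        if order == 1:
            axis = deriv.index(1)
            with np.errstate(invalid="ignore", divide="ignore"):
                g = np.where(rho > 0, -diff[:, axis] / np.where(rho > 0, rho, 1.0), 0.0)
            return g
        return np.zeros(points.shape[0])

    return hermite_interpolate(mesh, fn)


def default_cone(
    domain: GridDomain,
    constraints: ConstraintSet | None,
    config: EvolutionConfig,
) -> tuple[np.ndarray, float]:
    """Default cone placement: centered on the constraint centroid (domain
    center without constraints), radius from the constraint spread.

    With >= 2 constraint points the radius is half the largest pairwise
    distance -- the scale of the structure the user marked -- which balances
    the cone's positive mass inside the target against its negative mass
    outside.  Otherwise, half the distance from the center to the nearest
    domain boundary.  Both are overridable through the config.
    """
    if config.cone_center is not None:
        center = np.asarray(config.cone_center, dtype=float)
    elif constraints is not None and len(constraints) > 0:
        center = constraints.points.mean(axis=0)
    else:
        center = np.asarray(
            [o + 0.5 * e for o, e in zip(domain.origin, domain.extent)]
        )
    if config.cone_radius is not None:
        radius = float(config.cone_radius)
    elif constraints is not None and len(constraints) >= 2:
        pts = constraints.points
        diff = pts[:, None, :] - pts[None, :, :]
        radius = 0.5 * float(np.sqrt((diff * diff).sum(axis=2)).max())
    else:
        dists = [center[a] - domain.origin[a] for a in range(domain.ndim)]
        dists += [domain.upper[a] - center[a] for a in range(domain.ndim)]
        radius = 0.5 * float(min(dists))
    if radius <= 0:
        raise ValueError("degenerate cone radius; pass cone_radius explicitly")
    return center, radius


# ---------------------------------------------------------------------------
# end-to-end drivers
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    state: LevelSetState
    mesh: FEMesh
    config: EvolutionConfig
    h: ScalarField
    g: ScalarField | None
    d: ScalarField | None
    smoothed: ScalarField

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        return evaluate_fe(self.mesh, self.state.coeffs, points)


@dataclass
class ApproximationResult:
    state: LevelSetState
    mesh: FEMesh
    config: EvolutionConfig
    h: ScalarField
    fit_points: np.ndarray

    def predict(self, xy: np.ndarray) -> np.ndarray:
        """Surface height at the given (x, y) locations.

        Queries outside the fitted extent are clamped onto its boundary
        (constant extrapolation of the boundary trace).
        """
        dom = self.mesh.domain
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        lo = np.asarray(dom.origin[:2])
        hi = np.asarray(dom.upper[:2])
        xy = np.clip(xy, lo, hi)
        if self.config.approx_geometry == "heightfield":
            return evaluate_fe(self.mesh, self.state.coeffs, xy)
        return _volume_surface_heights(self, xy)


def _auto_elements(shape: tuple[int, ...]) -> tuple[int, ...]:
    # ~64 pixels per element in 2-D, within the recommended 25..100 window
    return tuple(max(1, int(round(n / 8))) for n in shape)


def segment(
    image: ScalarField,
    constraints: ConstraintSet | None,
    config: EvolutionConfig | None = None,
) -> SegmentationResult:
    """Full segmentation pipeline: fields -> FE assembly -> evolution.

    ``alpha > 0`` requires a non-empty constraint set; ``alpha = 0`` is the
    unconstrained edge-only model and ignores any constraints passed.
    """
    cfg = config or EvolutionConfig()
    if cfg.mode != "segmentation":
        raise ValueError("segment() requires mode='segmentation'")
    w = cfg.weights
    has_constraints = constraints is not None and len(constraints) > 0
    if w.alpha > 0 and not has_constraints:
        raise ValueError(
            "segmentation with alpha > 0 requires a non-empty constraint set "
            "(alpha = 0, beta > 0 is the unconstrained segmentation mode)"
        )
    if w.alpha == 0 and has_constraints:
        warnings.warn(
            "alpha = 0: the constraint set is ignored (unconstrained "
            "segmentation mode)",
            UserWarning,
            stacklevel=2,
        )

    domain = image.domain
    smoothed = fields.rescale_intensity(image)
    sigma_phys = cfg.sigma_px * min(domain.spacing)
    if cfg.sigma_px > 0:
        smoothed = fields.gaussian_smooth(smoothed, sigma_phys)

    g = None
    if w.beta > 0:
        grad = fields.gradient_fd(smoothed)
        g = fields.edge_potential(grad, k=cfg.grad_prescale)
    d = None
    if w.alpha > 0:
        d = fields.distance_field(constraints, domain)
    h = fields.weight_field(d, g, w)

    elements = cfg.elements or _auto_elements(domain.shape)
    mesh = build_mesh(domain, elements)
    center, radius = default_cone(domain, constraints if has_constraints else None, cfg)
    coeffs0 = cone_initializer(center, radius, mesh)

    M = assemble_mass(mesh)
    K = assemble_weighted_stiffness(mesh, h)
    system = build_system(M, K, cfg)
    state = run(LevelSetState(coeffs=coeffs0), system)
    return SegmentationResult(
        state=state, mesh=mesh, config=cfg, h=h, g=g, d=d, smoothed=smoothed
    )


def _heightfield_initial_surface(xy: np.ndarray, z: np.ndarray):
    """Smooth scattered-data interpolant supplying the initial surface.

    A local thin-plate-spline RBF: smooth across the whole bounding box
    (including outside the data's convex hull, where mesh nodes can fall),
    so the finite-difference nodal derivatives feeding the Hermite
    interpolation stay well-behaved.
    """
    neighbors = min(32, xy.shape[0])
    return RBFInterpolator(xy, z, neighbors=neighbors, kernel="thin_plate_spline")


def approximate(
    cloud: np.ndarray,
    config: EvolutionConfig | None = None,
) -> ApproximationResult:
    """Surface approximation from scattered (x, y, z) points (beta = 0)."""
    cfg = config or EvolutionConfig.approximation_defaults()
    if cfg.mode != "approximation":
        cfg = replace(cfg, mode="approximation")
    if cfg.beta != 0:
        raise ValueError(
            "approximation mode requires beta = 0 (alpha > 0, beta = 0 is "
            "the data-approximation specialization of the model)"
        )
    pts = np.asarray(cloud, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("the point cloud must be an (n, 3) array")
    if pts.shape[0] == 0:
        raise ValueError("approximation mode requires a non-empty point cloud")
    if cfg.approx_geometry == "heightfield":
        return _approximate_heightfield(pts, cfg)
    return _approximate_volume(pts, cfg)


def _approximate_heightfield(pts: np.ndarray, cfg: EvolutionConfig) -> ApproximationResult:
    """Height-field reading: a 2-D FE function z = u(x, y) evolved by the
    weighted diffusion, with diffusivity alpha * d^2 to the (x, y) data
    projections.  The data supply the initial surface; the evolution relaxes
    it away from the data while the vanishing diffusivity pins it there."""
    xy, z = pts[:, :2], pts[:, 2]
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    # tiny relative pad so bbox-corner points stay inside after the
    # spacing = span / shape round-trip
    lo = lo - 1e-9 * span
    span = span * (1 + 2e-9)
    elements = cfg.elements or (20, 20)
    if len(elements) != 2:
        raise ValueError("heightfield approximation needs a 2-D element count")
    npx = tuple(e * cfg.quad_cells_per_element for e in elements)
    domain = GridDomain(
        shape=npx,
        spacing=tuple(span[a] / npx[a] for a in range(2)),
        origin=tuple(lo),
    )
    mesh = FEMesh(domain, elements)

    d = fields.distance_field(ConstraintSet(xy, label="xy projections"), domain)
    h = fields.weight_field(d, None, ModelWeights(cfg.alpha, 0.0))

    surf = _heightfield_initial_surface(xy, z)
    eps_fd = 1e-4 * float(span.min())

    def fn(points: np.ndarray, deriv: tuple[int, ...]) -> np.ndarray:
        order = sum(deriv)
        safe = np.clip(points, lo + eps_fd, hi - eps_fd)
        if order == 0:
            return surf(points)
        if order == 1:
            axis = deriv.index(1)
            step_v = np.zeros(2)
            step_v[axis] = eps_fd
            return (surf(safe + step_v) - surf(safe - step_v)) / (2 * eps_fd)
        return np.zeros(points.shape[0])

    coeffs0 = hermite_interpolate(mesh, fn)
    M = assemble_mass(mesh)
    K = assemble_weighted_stiffness(mesh, h)
    system = build_system(M, K, cfg)
    state = run(LevelSetState(coeffs=coeffs0), system)
    return ApproximationResult(state=state, mesh=mesh, config=cfg, h=h, fit_points=pts)


def _approximate_volume(pts: np.ndarray, cfg: EvolutionConfig) -> ApproximationResult:
    """Volumetric reading: a 3-D level-set function over the cloud's padded
    bounding box, diffusivity alpha * d^2 to the 3-D points; the zero level
    is the fitted surface.  Kept coarse (tensor-Hermite bricks are 64
    DOFs/element); intended for qualitative use."""
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    pad = np.array([0.0, 0.0, cfg.z_pad * span[2]])
    lo3, hi3 = lo - pad, hi + pad
    span3 = hi3 - lo3
    elements = cfg.elements or (8, 8, 8)
    if len(elements) != 3:
        raise ValueError("volume approximation needs a 3-D element count")
    if any(e > 20 for e in elements):
        raise ValueError("volume approximation is limited to <= 20 elements per axis")
    q = max(2, cfg.quad_cells_per_element // 2)
    npx = tuple(e * q for e in elements)
    domain = GridDomain(
        shape=npx,
        spacing=tuple(span3[a] / npx[a] for a in range(3)),
        origin=tuple(lo3),
    )
    mesh = FEMesh(domain, elements)
    d = fields.distance_field(ConstraintSet(pts, label="cloud"), domain)
    h = fields.weight_field(d, None, ModelWeights(cfg.alpha, 0.0))

    z_mid = float(pts[:, 2].mean())

    def fn(points: np.ndarray, deriv: tuple[int, ...]) -> np.ndarray:
        # plane initializer: Phi0 = z_mid - z (positive below the mid-plane)
        if sum(deriv) == 0:
            return z_mid - points[:, 2]
        if deriv == (0, 0, 1):
            return -np.ones(points.shape[0])
        return np.zeros(points.shape[0])

    coeffs0 = hermite_interpolate(mesh, fn)
    M = assemble_mass(mesh)
    K = assemble_weighted_stiffness(mesh, h)
    system = build_system(M, K, cfg)
    state = run(LevelSetState(coeffs=coeffs0), system)
    return ApproximationResult(state=state, mesh=mesh, config=cfg, h=h, fit_points=pts)


def _volume_surface_heights(result: ApproximationResult, xy: np.ndarray) -> np.ndarray:
    """Height of the zero level above each (x, y): scan Phi along z for the
    sign change and refine the crossing by linear interpolation."""
    dom = result.mesh.domain
    z0, z1 = dom.origin[2], dom.upper[2]
    nz = 4 * dom.shape[2]
    zs = np.linspace(z0 + 1e-9 * (z1 - z0), z1 - 1e-9 * (z1 - z0), nz)
    out = np.full(xy.shape[0], np.nan)
    for i, (x, y) in enumerate(xy):
        pts = np.column_stack([np.full(nz, x), np.full(nz, y), zs])
        phi = evaluate_fe(result.mesh, result.state.coeffs, pts)
        sign = np.sign(phi)
        crossings = np.nonzero(np.diff(sign) != 0)[0]
        if crossings.size == 0:
            continue
        j = int(crossings[0])
        a, b = phi[j], phi[j + 1]
        t = a / (a - b) if a != b else 0.5
        out[i] = zs[j] + t * (zs[j + 1] - zs[j])
    return out


def evolve(
    config: EvolutionConfig,
    image: ScalarField | None = None,
    constraints: ConstraintSet | None = None,
    cloud: np.ndarray | None = None,
):
    """Mode dispatcher: segmentation needs an image, approximation a cloud."""
    if config.mode == "segmentation":
        if image is None:
            raise ValueError("segmentation mode requires an image")
        return segment(image, constraints, config)
    if cloud is None:
        raise ValueError("approximation mode requires a point cloud")
    return approximate(cloud, config)
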