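"""Synthetic fixtures: test images with known ground truth, noise, and
analytic terrains with sampled point clouds.

Every generator is a pure function of its parameters and seed; randomness
goes through ``numpy.random.default_rng`` (PCG64), so identical seeds give
identical fixtures on any platform.  Noise is additive Gaussian with a
standard deviation expressed as a percentage of the clean image's dynamic
range -- "50% noise" means sigma = 0.5 * (max - min).

Images are generated on a unit-normalized physical domain (spacing
1 / max(shape)) so that the fidelity term alpha * d^2 and the edge term
beta * g^2 of the diffusivity live on comparable scales with alpha=beta=1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import erf

from .domain import ConstraintSet, GridDomain, ScalarField
from .geometry_metrics import SegMask

__all__ = [
    "FixtureSpec",
    "DEFAULT_CLOUD_N",
    "unit_domain",
    "make_disk_image",
    "make_two_blob_image",
    "make_ramp_image",
    "make_flat_image",
    "add_noise",
    "default_terrain",
    "make_terrain_cloud",
    "make_sphere_cloud",
    "make_fixture",
]

#: survey-scale preset for terrain clouds
DEFAULT_CLOUD_N = 8736


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request; the seed fully determines the output."""

    kind: str
    params: dict = field(default_factory=dict)
    noise_pct: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_pct < 0:
            raise ValueError("noise_pct must be >= 0")
        kinds = ("disk", "two_blob", "ramp", "flat", "terrain", "sphere_cloud")
        if self.kind not in kinds:
            raise ValueError(f"unknown fixture kind {self.kind!r}; use one of {kinds}")


def unit_domain(shape: tuple[int, int]) -> GridDomain:
    """Pixel grid with the longest side scaled to physical length 1."""
    s = 1.0 / max(shape)
    return GridDomain(shape=shape, spacing=(s,) * len(shape))


@dataclass
class DiskFixture:
    image: ScalarField
    truth: SegMask
    center: np.ndarray
    radius: float
    boundary_points: Callable[..., ConstraintSet]


def _soft_step(signed: np.ndarray, softness_phys: float) -> np.ndarray:
    """1 inside (signed < 0), 0 outside, erf-smoothed over the given width."""
    if softness_phys <= 0:
        return (signed < 0).astype(float)
    return 0.5 * (1.0 - erf(signed / (np.sqrt(2.0) * softness_phys)))


def make_disk_image(
    size: tuple[int, int] = (128, 128),
    center: tuple[float, float] | None = None,
    radius: float | None = None,
    fg: float = 1.0,
    bg: float = 0.0,
    edge_softness: float = 1.5,
    domain: GridDomain | None = None,
) -> DiskFixture:
    """Disk test image with ground truth and a boundary-point sampler.

    ``radius`` and ``center`` are physical; defaults put a disk of radius
    0.3 * min(extent) at the domain center.  ``edge_softness`` is the erf
    transition width in pixels (0 gives a binary image).  The sampler
    returns k points exactly on the true circle, emulating the two-to-three
    user clicks near the boundary of the structure of interest.
    """
    dom = domain or unit_domain(size)
    ext = dom.extent
    c = np.asarray(center if center is not None else
                   [dom.origin[a] + 0.5 * ext[a] for a in range(2)], dtype=float)
    r = float(radius) if radius is not None else 0.3 * min(ext)
    if r <= 0 or r >= 0.5 * min(ext):
        raise ValueError(
            f"disk radius {r} must be positive and below half the min extent "
            f"{0.5 * min(ext)}"
        )
    mesh = dom.centroid_mesh()
    rho = np.sqrt((mesh[0] - c[0]) ** 2 + (mesh[1] - c[1]) ** 2)
    signed = rho - r
    soft_phys = edge_softness * min(dom.spacing)
    img = bg + (fg - bg) * _soft_step(signed, soft_phys)
    truth = SegMask(dom, signed < 0)

    def boundary_points(k: int = 2, phase: float = 0.0) -> ConstraintSet:
        theta = phase + 2.0 * np.pi * np.arange(k) / k
        pts = c + r * np.column_stack([np.cos(theta), np.sin(theta)])
        return ConstraintSet(pts, label=f"{k} disk boundary points")

    return DiskFixture(
        image=ScalarField(dom, img), truth=truth, center=c, radius=r,
        boundary_points=boundary_points,
    )


def make_two_blob_image(
    size: tuple[int, int] = (128, 128),
    centers=((0.32, 0.32), (0.68, 0.68)),
    radii=(0.18, 0.14),
    fg: float = 1.0,
    bg: float = 0.0,
    edge_softness: float = 1.5,
):
    """Union of two soft disks (exercises the topology-free contour)."""
    dom = unit_domain(size)
    mesh = dom.centroid_mesh()
    soft_phys = edge_softness * min(dom.spacing)
    inside = np.full(dom.shape, -np.inf)
    for c, r in zip(centers, radii):
        rho = np.sqrt((mesh[0] - c[0]) ** 2 + (mesh[1] - c[1]) ** 2)
        inside = np.maximum(inside, r - rho)
    img = bg + (fg - bg) * _soft_step(-inside, soft_phys)
    return ScalarField(dom, img), SegMask(dom, inside > 0)


def make_ramp_image(size: tuple[int, int] = (64, 64), axis: int = 0) -> ScalarField:
    dom = unit_domain(size)
    mesh = dom.centroid_mesh()
    return ScalarField(dom, mesh[axis].copy())


def make_flat_image(size: tuple[int, int] = (64, 64), value: float = 0.5) -> ScalarField:
    dom = unit_domain(size)
    return ScalarField(dom, np.full(size, float(value)))


def add_noise(image: ScalarField, noise_pct: float, seed: int) -> ScalarField:
    """Additive Gaussian noise, sigma = (noise_pct / 100) * dynamic range."""
    if noise_pct < 0:
        raise ValueError("noise_pct must be >= 0")
    if noise_pct == 0:
        return image.with_values(image.values.copy())
    rng = np.random.default_rng(seed)
    sigma = (noise_pct / 100.0) * (image.max - image.min)
    return image.with_values(image.values + rng.normal(0.0, sigma, image.domain.shape))


# ---------------------------------------------------------------------------
# terrains and point clouds
# ---------------------------------------------------------------------------

def default_terrain(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two Gaussian hills with steep flanks on a raised base.

    The narrow widths (sigma 0.16 and 0.12 on the unit square) give the
    large, rapidly varying relief that stresses a surface-approximation
    scheme the way real bathymetry does.
    """
    h1 = 1.0 * np.exp(-(((x - 0.30) ** 2) + (y - 0.35) ** 2) / (2 * 0.16**2))
    h2 = 0.6 * np.exp(-(((x - 0.70) ** 2) + (y - 0.70) ** 2) / (2 * 0.12**2))
    return 0.3 + h1 + h2


def make_terrain_cloud(
    n_points: int,
    surface: Callable[[np.ndarray, np.ndarray], np.ndarray] = default_terrain,
    noise_pct: float = 0.0,
    seed: int = 0,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0)),
) -> tuple[np.ndarray, Callable[[np.ndarray, np.ndarray], np.ndarray]]:
    """Scattered (x, y, z) samples of an analytic height function.

    Returns the (n, 3) cloud and the truth function for held-out evaluation.
    With ``noise_pct = 0`` every sampled z equals the surface exactly.
    """
    if n_points < 10:
        raise ValueError("need at least 10 points")
    rng = np.random.default_rng(seed)
    (x0, x1), (y0, y1) = bounds
    x = rng.uniform(x0, x1, n_points)
    y = rng.uniform(y0, y1, n_points)
    z = surface(x, y)
    if noise_pct > 0:
        z = z + rng.normal(0.0, (noise_pct / 100.0) * (z.max() - z.min()), n_points)
    return np.column_stack([x, y, z]), surface


def make_sphere_cloud(
    n_points: int = 500,
    center: tuple[float, float, float] = (0.5, 0.5, 0.5),
    radius: float = 0.3,
    noise_pct: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Points on a sphere (3-D volumetric-mode fixture)."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_points, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * np.ones(n_points)
    if noise_pct > 0:
        r = r + rng.normal(0.0, (noise_pct / 100.0) * radius, n_points)
    return np.asarray(center) + v * r[:, None]


def make_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to the matching generator."""
    p = dict(spec.params)
    if spec.kind == "disk":
        fx = make_disk_image(**p)
        if spec.noise_pct > 0:
            fx.image = add_noise(fx.image, spec.noise_pct, spec.seed)
        return fx
    if spec.kind == "two_blob":
        img, truth = make_two_blob_image(**p)
        if spec.noise_pct > 0:
            img = add_noise(img, spec.noise_pct, spec.seed)
        return img, truth
    if spec.kind == "ramp":
        return make_ramp_image(**p)
    if spec.kind == "flat":
        return make_flat_image(**p)
    if spec.kind == "terrain":
        return make_terrain_cloud(noise_pct=spec.noise_pct, seed=spec.seed, **p)
    return make_sphere_cloud(noise_pct=spec.noise_pct, seed=spec.seed, **p)
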