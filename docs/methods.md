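# Methods

This note documents the model, its discretization, the default parameters
and why they are what they are, what the synthetic fixtures do and do not
emulate, and the known limitations.

## Model

The contour (2-D) or surface (3-D) of interest is the zero level set of a
scalar function Φ evolving by the weighted diffusion

    ε ∂Φ/∂t = 2 ∇·(h ∇Φ),     h = α·d_D² + β·g²,     g = 1/(1 + |∇I|²),

with natural (zero-flux) boundary conditions. `d_D` is the exact Euclidean
distance from a point to the finite constraint set D (curves or patches are
densely sampled to points first). The equation is the L² gradient flow of
the convex energy `E(Φ) = ∫ h |∇Φ|²`: variation of Φ is progressively
expelled from regions of large h and concentrates where h is small — on
image edges (g ≈ 0) and near the user's constraint points (d ≈ 0). The
formulation is topology-free: contours split and merge at no extra cost.

Three regimes of the weights:

* `α > 0, β > 0` — constrained segmentation (the default);
* `α = 0, β > 0` — unconstrained, edge-only segmentation;
* `α > 0, β = 0` — scattered-data surface approximation (no image at all).

An essential property, verified in the tests and worth stating bluntly: the
only steady states of this flow are constants. Segmentation quality is a
property of a **finite-horizon transient** — the zero level set settles
into the valleys of h quickly and stays pinned there for a long but finite
time, after which the field drains toward its (uninformative) spatial mean.
All time-scale defaults below are chosen to stop inside the pinned window.

## Discretization

**Space.** C1 Bogner–Fox–Schmidt rectangles: the tensor product of 1-D cubic
Hermite bases, with value, both first derivatives and the mixed second
derivative as nodal unknowns (16 DOFs/element in 2-D; the 3-D tensor-Hermite
brick with 64 DOFs/element sits behind the same interfaces). The C1
conformity gives a smooth evolving function and, in approximation mode, a
C1 fitted surface.

**Quadrature.** The mass matrix involves only polynomials and is integrated
exactly (4-point Gauss per axis, exact through degree 7 ≥ 6). The weighted
stiffness `ã(u,v) = 2 Σᵢ λᵢ h(xᵢ) ∇u·∇v(xᵢ)` uses the pixel/voxel centroids
as quadrature nodes with weight λᵢ = cell volume (midpoint rule), because h
is only known at pixel centers; its per-element error is O(p⁻²) in the
pixels-per-element count p, verified empirically. `build_mesh` warns outside
the recommended ~25–100 pixels per element. Elements need not divide the
pixel grid evenly; pixels are binned to elements by centroid, ties toward
the lower-index element, and an element left without any quadrature node is
an assembly error (the fix is a coarser mesh).

**Time.** Backward Euler. Per step, `(εM + δt·Ã) αᵐ = εM αᵐ⁻¹` with a
sparse LU factorization computed once (h, hence Ã and R, do not depend on
time). The scheme is unconditionally stable, non-expansive in the M-norm,
and dissipates the energy `½ αᵀÃα` monotonically for every δt — these are
the discrete counterparts of the well-posedness of the continuous problem,
and they are tested rather than proved here.

## Parameters, defaults, and the reasoning behind them

| parameter | default | meaning / rationale |
|---|---|---|
| α, β | 1, 1 | relative weight of constraint fidelity vs edge attraction; equal weights keep the method essentially parameter-free for users |
| spacing | 1/max(shape) | images live on a unit-normalized physical domain, so d² (≤ 2) and g² (≤ 1) are commensurate with α = β = 1 |
| δt | 0.3 (segmentation) | the experiment convention for the per-step budget |
| ε | 1e4 (segmentation) | only δt/ε enters the discrete flow; ε sets the pace of evolution against the step. Dimensional analysis (h ∝ α·d² scales with the squared domain size, cancelling the domain size in the diffusion time) puts every structural timescale of a unit-normalized image at ~0.03·ε, *independent of the spacing convention*; δt/ε = 3·10⁻⁵ resolves it. Effective steps of order 10⁻³ or below are the suitable magnitude; δt = 0.3 with ε = 1 would flatten any image in a handful of steps |
| max_steps | 500 (segmentation) | horizon T/ε = 0.015 ≈ half the constraint-leak time; inside the pinned window |
| stop_tol | 1e-6 | relative ℓ² coefficient change; a safety net for genuinely converged runs (constants), rarely triggered before max_steps by design |
| σ (Gaussian pre-smoothing) | 1 pixel | standard denoising regularization; in physical units σ = min(spacing) |
| k (gradient pre-scaling in g) | 1 | `g = 1/(1+(k·\|∇I\|)²)`; k = 1 is the plain potential, k is exposed because g is scale-sensitive |
| intensity rescale | always to [0,1] | makes g's dynamic range independent of 8-bit vs float input |
| h floor | 1e-8·(α·diam² + β) | keeps R SPD when β = 0 and a quadrature node hits a data point exactly |
| mesh | ~64 px/element | inside the recommended 25–100 window |
| cone center | constraint centroid | the clicks mark the target |
| cone radius | half the max pairwise click distance | the initial zero circle passes through (or near) the clicks. The flow reliably *refines and holds* a constraint-consistent initialization but cannot grow a badly misplaced one: migration into the h-valleys and the drain toward the constant share the same timescale. Initializing from the geometric conditions is therefore part of the method, not a convenience. Without constraints the fallback is half the distance from the center to the nearest image border |

**Approximation mode** (`EvolutionConfig.approximation_defaults()`):
α = 1, β = 0, δt = 10⁻³, ε = 1, 20 steps. Here the evolution is a
variational smoother whose horizon T = max_steps·δt is the smoothing
bandwidth: h = α·d² makes the diffusion slowest at the data, so the surface
is relaxed *between* samples while staying pinned near them. The default
T = 0.02 corresponds to a diffusion length of roughly half the mean
inter-point spacing of a few-thousand-point cloud on the unit square — mild
denoising that leaves resolved relief intact. With noisy data, a larger
horizon helps (measured on the terrain fixture: at 5 % noise the holdout
error improves by ~2× before the optimum, then worsens); with clean dense
data, any long horizon erodes sharp relief. The initial surface is a local
thin-plate-spline interpolant (32 neighbors) of the scattered data, Hermite-
interpolated into the FE space; the nodal cross-derivatives default to 0.

Two geometries are available for clouds: the default **height-field**
reading (2-D mesh carrying z as the FE function, diffusivity from the 2-D
distance to the data's (x, y) projections) and a **volumetric** reading
(3-D level set over the padded bounding box, diffusivity from the 3-D
distance, surface = zero level, initialized as the horizontal mid-plane).
The height-field path is quantitative — it is what the holdout error is
measured on; the volumetric path is kept coarse (≤ 20 elements per axis)
and is validated qualitatively (the zero level moves from the plane toward
the data). Which one a given published computation on a 2-D mesh of a 3-D
problem corresponds to is ambiguous; neither is claimed to be it.

## Synthetic fixtures: what they emulate, what they don't

All tests and the acceptance script run on generated data only:

* **disk / two-blob images** stand in for closed anatomical contours: a
  single round structure with a soft (erf) edge of ~1.5 px, foreground 1,
  background 0, with two antipodal boundary points as the "user clicks".
  Additive Gaussian noise with σ = (noise %/100)·dynamic-range models image
  degradation; the percentage convention is this package's (the term "x %
  noise" has no universal definition).
* **Gaussian-hill terrains** (two hills, σ = 0.16 and 0.12, ~1.2 total
  relief on the unit square) stand in for steep bathymetry/topography; the
  survey-scale preset of 8736 points with a 1500-point random holdout
  mirrors a realistic acquisition/evaluation split.

What passing these tests shows: the discretization is correct (exact where
exactness is claimed, second-order where claimed), the scheme is stable and
dissipative, and the *mechanism* — pinning of the zero level at edges and
constraints, noise-graceful degradation, data-pinned surface smoothing —
works. What it does not show: performance on real modalities (intensity
inhomogeneity, anisotropic voxels, textured backgrounds, registration
artifacts), behavior with misleading user clicks far from any edge, or
competitive accuracy against learned segmenters on labeled benchmarks.

## Numerical choices and degenerate inputs

* Distance fields are computed by exact chunked min-over-sites evaluation
  (no grid propagation), so they carry no discretization error and are
  1-Lipschitz by construction.
* Zero-level extraction is marching squares with linear interpolation on a
  sampling grid (pixel centroids by default); single-signed fields yield an
  empty contour with a warning, not an error.
* Dice of two empty masks is 1, empty vs non-empty is 0; mIoU averages the
  foreground and background IoU; Hausdorff distances are plain max–min
  between boundary point sets (no percentile variant), in physical units.
* The relative quadratic error for surface fits is `(Σ(ẑ−z)²/Σz²)^½` over
  any number of evaluation points; an identically-zero truth vector is
  reported as an explicit division error.
* A constant image rescales to 0 and yields g ≡ 1 (no edges).
* The backward-Euler solve enforces a 1e-8 relative residual bound and
  fails loudly otherwise; R is SPD by the h-floor.

## Limitations

* The segmentation result is a finite-horizon snapshot; pathological
  parameter choices (horizon ≫ pinned window) return a near-constant field
  and an empty or degenerate contour. The defaults avoid this; the energy
  history in `state.history` makes it diagnosable.
* The capture range of the constraint/edge valleys is local. The quality of
  the result depends on the clicks being near the true boundary — which is
  the intended use.
* h is time-independent by assumption (it is what makes R factorizable
  once); re-assembly hooks would be needed for evolving imagery.
* 3-D segmentation of volumetric images is out of scope; the 3-D brick
  element is exercised only by the volumetric approximation path.
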