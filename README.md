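# levelseg

Variational level-set image segmentation under **geometric point
constraints**, with a β = 0 specialization for **scattered-data surface
approximation**, discretized with C1 Bogner–Fox–Schmidt (BFS) finite
elements.

## The problem and the model

Fully supervised segmentation needs labeled data that many imaging settings
(clinical scans, geophysics) do not have. An alternative is to let a user
mark a handful of points near the boundary of the structure of interest and
let a variational model do the rest. `levelseg` represents the unknown
contour S as the zero level set of a function Φ and evolves Φ by the
weighted diffusion

    ε ∂Φ/∂t = 2 ∇·(h ∇Φ),        h(x) = α d_D(x)² + β g(|∇I|)²,

with natural boundary conditions, where

* `d_D` is the Euclidean distance to the user's point set D,
* `g = 1 / (1 + |∇I|²)` is the edge-stopping potential of the (smoothed,
  intensity-normalized) image I — close to 0 on strong edges, 1 in flat
  regions,
* `α` weights fidelity to the constraints and `β` the attraction to edges
  (`α = β = 1` by default).

This is the gradient flow of the quadratic energy `∫ h |∇Φ|²`: the level
sets of Φ migrate toward and park in the valleys of h — image edges and the
constraint points — while topology changes (splitting/merging contours) are
free. Time is discretized by unconditionally stable backward Euler; space by
C1 BFS rectangles (4 DOFs per node in 2-D: value, ∂x, ∂y, ∂xy). Each step
solves the constant SPD system `(εM + δt·Ã) αᵐ = εM αᵐ⁻¹`, factorized once;
`Ã` is assembled with a voxel-centroid quadrature because h is only known at
pixel centers.

Setting `β = 0` turns the same machinery into scattered-data surface
approximation: `h = α d²` vanishes near the data, so an initial surface
fitted through an (x, y, z) point cloud is relaxed everywhere except at the
points — a variational smoother for bathymetry/topography-style clouds.

## Worked example

Segment a synthetic soft-edged disk from two boundary "clicks":

```python
import numpy as np
from levelseg import EvolutionConfig, dice, extract_zero_level, rasterize, segment
from levelseg.geometry_metrics import constraint_distances
from levelseg.synthetic import make_disk_image

fixture = make_disk_image(size=(128, 128))       # soft-edged disk, unit domain
clicks = fixture.boundary_points(2)              # two "user clicks" on the boundary

result = segment(fixture.image, clicks, EvolutionConfig())
contour = extract_zero_level(result.state, result.mesh, fixture.image.domain)
mask = rasterize(result.state, result.mesh, fixture.image.domain)

px = min(fixture.image.domain.spacing)
print(f"steps run         : {result.state.step_index}")
print(f"final energy      : {result.state.energy:.6f}")
print(f"contour components: {len(contour)}")
print(f"click distances   : {np.round(constraint_distances(contour, clicks) / px, 2)} px")
print(f"Dice vs truth     : {dice(mask, fixture.truth):.4f}")
```

prints

```
steps run         : 500
final energy      : 0.079850
contour components: 1
click distances   : [0.59 0.59] px
Dice vs truth     : 0.9675
```

i.e. the recovered contour is a single closed curve passing within ~0.6
pixels of both constraint points, and the rasterized mask overlaps the
ground-truth disk with Dice 0.97.

The same is available from the shell:

```bash
levelseg fixtures --kind disk --out-dir fx
levelseg segment fx/disk.png --points-csv fx/disk_points.csv --truth fx/disk_truth.png
levelseg approx terrain.xyz --holdout 500 --elements 20
levelseg metrics mask_a.png mask_b.png
```

Every run writes a `run_record.json` (resolved config, input/output hashes,
version) that makes it byte-reproducible.

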