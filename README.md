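# hipposeg

Semi-automatic segmentation of small, low-contrast structures — the
motivating case is the hippocampus in 2-D T1-weighted MR slices — from a
single user-supplied seed point. The hippocampus is hard to delineate
automatically: it is small, its intensity barely differs from neighboring
gray matter, coil shading drifts the intensities across the image, and
parts of its boundary are blurred or simply absent at MR resolution.
`hipposeg` combines two classical ideas so that neither has to work alone:

1. **Adaptive seeded region growing** builds a rough, automatic
   initialization. A window (default 45×45 px) is cropped around the
   seed; pixels are accreted over 8-connected neighbors while
   `|I(x,y) − X̄| ≤ ξ·σ_Global`, where `X̄` is the running mean of the
   region grown so far and `σ_Global` the standard deviation of the
   window. The grown region's perimeter is replaced by its filled convex
   hull, which starts the contour outside local minima.
2. **Hybrid level-set evolution** refines the contour as the zero level
   of a field φ (inside = {φ < 0}), by gradient descent on

   F(φ) = μ·½∫(|∇φ|−1)² + λ∫g δ_ε(φ)|∇φ| + ν∫g H_ε(−φ)
        + τ∫[−log p₁(I)·H_ε(φ) − log p₂(I)·(1−H_ε(φ))]

   The first three terms are the distance-regularized edge-based model
   (penalty keeping φ a signed-distance function, geodesic contour
   length, and a balloon term, all weighted by the edge indicator
   g = 1/(1+|∇G_σ∗I|²)). The τ-term fits the two regions with global
   Gaussians p_i = N(u_i, σ_i²) whose means *and variances* are refit
   every iteration; its force, δ_ε(φ)(e₁−e₂) with
   e_i = log(√(2π)σ_i) + (I−u_i)²/(2σ_i²), closes the contour across
   boundary gaps and separates regions whose means agree but whose
   variances differ. The update is explicit: central differences in
   space, forward Euler in time (default Δt = 4, μ = 0.05, λ = 10,
   ν = 2, τ = 0.01, ε = 2, σ = 1, c0 = 2).

Evaluation is by the Dice similarity coefficient,
DSC = 2|S₁∩S₂|/(|S₁|+|S₂|).

Because clinical MR data cannot ship with the package, a phantom module
generates MR-like 2-D test images with known ground truth — Gaussian
foreground/background intensities, multiplicative low-order bias fields,
blurred boundaries, and contiguous boundary gaps — on which every stage
and the full pipeline are tested.

## Worked example

```python
from hipposeg import ModelParams, PhantomSpec, dsc, generate_phantom, segment

image, truth, seed = generate_phantom(PhantomSpec(rng_seed=0))
result = segment(image, seed, ModelParams())
print(result.segmentation.iterations, dsc(result.mask, truth))
```

Running `python examples/01_segment_phantom.py` prints:

```
phantom (157, 189), target 877 px, seed at (77, 94)
grown region: 803 px (threshold 22.99 intensity units)
convex-hull init: 838 px, Dice vs truth 0.977
evolution: 81 iterations, converged=True
final Dice vs truth: 0.993
```

The grown region captures most of the target (803 of 877 px) under the
adaptive threshold; the convex hull starts the level set at Dice 0.977;
81 evolution iterations refine it to 0.993 — an almost perfect overlap
with the known target. The other scripts in `examples/` demonstrate the
region-term ablation (edge-only vs hybrid on broken boundaries), the
seed-robustness protocol, and the command-line workflow.

## Command line

```sh
hipposeg phantom --preset easy-s0 --out img.png --truth truth.png
hipposeg segment --image img.png --seed 77,94 --out mask.png --log-csv iters.csv
hipposeg eval --pred mask.png --ref truth.png
hipposeg robustness --image img.png --seeds "77,94;72,88;82,100" --out rob.csv
```

Parameters come from a flat JSON file (`--params p.json`) and/or
repeated `--set KEY=VALUE` flags; flags win over the file, the file over
the defaults. `--debug-dir` dumps every intermediate stage (window,
grown region, perimeter, hull, initial and final mask) as PNG.

## Layout

- `src/hipposeg/region_growing.py` — window crop, adaptive growth, perimeter, convex hull, φ₀
- `src/hipposeg/level_set.py` — mollifiers, edge map, region statistics, curvature, evolution
- `src/hipposeg/phantom.py` — synthetic MR-like images with ground truth
- `src/hipposeg/metrics.py` — Dice similarity coefficient
- `src/hipposeg/io.py`, `src/hipposeg/params.py` — raster/config IO
- `src/hipposeg/pipeline.py`, `src/hipposeg/cli.py` — orchestration and CLI
- `docs/methods.md` — model, assumptions, numerical choices, limitations
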