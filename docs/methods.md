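# Methods

## Problem and approach

The target use case is delineating a small, low-contrast anatomical
structure (hippocampus-scale: a few hundred pixels) in a single 2-D MR
slice, starting from one operator-supplied seed point. Fully edge-driven
active contours fail here for three reasons: they are sensitive to where
the contour starts, noise creates spurious edges that trap them, and the
true boundary is partly absent. The pipeline addresses the first problem
with a data-driven initialization (seeded region growing + convex hull)
and the other two by adding a global Gaussian region term to an
edge-based level-set model.

## Stage 1 — seeded region growing

A `window × window` crop (default 45 px, odd so the seed can be
centered; clamped inside the image for border seeds) is taken around the
seed. Cropping matters statistically, not just computationally: all
"global" quantities below — the growth threshold and the two-Gaussian
region fit — are only meaningful when the domain contains essentially
the target and its immediate surroundings rather than the whole brain.

Growth accretes 8-connected pixels in FIFO order (neighbors enumerated
N, NE, E, SE, S, SW, W, NW for determinism). A candidate is admitted iff

    |I(x, y) − X̄| ≤ ξ · σ_Global

where `σ_Global` is the population standard deviation of the window and
`X̄` the running mean of all admitted pixels, updated after every
admission (a frozen-at-the-seed variant is available via
`adaptive_mean=False`). Each pixel is tested at most once, when first
reached. The grown region's inner perimeter (members with a non-member
4-neighbor, image border counting as exterior) is replaced by its filled
convex hull (pixel-center inclusion against the hull of the perimeter
pixel centers, edge ties included), and the initial level-set field is
the binary step φ₀ = −c0 inside the hull, +c0 outside. φ₀ is
deliberately not a signed-distance function; the evolution's penalty
term regularizes it into one.

**ξ (growth weight).** No canonical value exists; it is exposed in the
configuration and logged per run. The default ξ = 0.6 was calibrated
once against the phantom corpus with the rule that the grown region
should cover roughly 60–95 % of the true target: smaller values make
low-contrast growth under-cover (and, at ξ ≤ 0.5, occasionally collapse
outright), larger values make growth leak into high-variance
backgrounds, inflating the hull. The two failure modes pull in opposite
directions; 0.6 is the best single compromise, with the low-contrast
family sitting just below the coverage band (≈ 0.52–0.55) while
segmenting well after evolution.

**Known fragility.** The running mean starts at the seed pixel's value,
so a seed placed on a noise outlier can strangle growth when the
contrast-to-noise ratio is low. This mirrors the intended protocol —
seeds are chosen by a human who picks a representative interior point —
and is why the phantom generator emulates seeding the same way (below).

## Stage 2 — hybrid level-set evolution

Inside is {φ < 0}; region index 1 is {φ > 0} (background), matching
M₁ = H_ε(φ), M₂ = 1 − H_ε(φ). The energy is

    F(φ) = μ P(φ) + λ L_g(φ) + ν A_g(φ) + τ E_GDF(φ)

- `P = ½∫(|∇φ|−1)²` keeps φ near a signed-distance function, removing
  any need for reinitialization.
- `L_g = ∫ g δ_ε(φ)|∇φ|` is the geodesic length under the edge
  indicator `g = 1/(1+|∇G_σ∗I|²)` (Gaussian kernel std σ, truncated at
  4σ), computed once before the loop.
- `A_g = ∫ g H_ε(−φ)` is the balloon term; with the φ<0-inside
  convention, ν > 0 shrinks the contour from the (over-covering) convex
  hull toward the boundary.
- `E_GDF` scores each pixel under two global Gaussians N(u_i, σ_i²)
  whose parameters are the H_ε-weighted means/variances of the two
  regions, refit every iteration (they are the exact minimizers of F
  for fixed φ). Its force is −τ δ_ε(φ)(e₁−e₂) with
  e_i = log(√(2π)σ_i) + (I−u_i)²/(2σ_i²): pixels better explained by
  the object Gaussian are pushed inside even where g provides no edge —
  this is what closes broken boundaries and separates equal-mean /
  different-variance regions.

H_ε(x) = ½(1 + (2/π)arctan(x/ε)) and δ_ε(x) = (1/π)·ε/(ε²+x²) = H_ε′.
Note δ_ε is a Cauchy kernel: its tails decay only as 1/x², so region
memberships never saturate completely. With a small object in a large
frame the object-region statistics therefore carry a visible admixture
of background; the variance floor and the fact that forces only need
the *sign* of e₁−e₂ near the contour keep this benign in practice, but
it is the model's most delicate property (see Limitations).

### Discretization

All spatial derivatives are central differences on the unit pixel grid;
boundaries are reflective (mirror, zero normal derivative) for every
stencil including the Gaussian smoothing. Curvature is
k = Δ₀x(Δ₀xφ/|∇φ|) + Δ₀y(Δ₀yφ/|∇φ|) with η = 1e-8 added under the
square root of |∇φ| (0/0 guard on plateaus, far below discretization
error). Time stepping is forward Euler:

    φ^{n+1} = φ^n + Δt·[ μ(Δφ − k) + λ δ_ε(φ)(g·k + ∇g·∇φ/|∇φ|)
                         + ν g δ_ε(φ) − τ δ_ε(φ)(e₁ − e₂) ]

The default Δt = 4 exceeds the usual explicit CFL comfort zone but is
stabilized in practice by the small μ and the δ_ε localization of the
other forces; the engine checks every iterate for finiteness and raises
a divergence error (with the iteration index) rather than propagating
NaNs. With a genuinely small step (Δt ≈ 0.1) the update is an energy
descent step by step — but only after the binary-step initialization has
relaxed toward a signed-distance profile; at the discontinuous φ₀ the
central-difference update is too crude an approximation of the energy
gradient for monotonicity.

Variances are floored at 1e-6·(intensity range)² before entering
e₁/e₂, so a degenerate (constant) region cannot divide by zero. With
τ = 0 the model reduces exactly to the edge-only formulation, which the
ablation tests use as the baseline.

### Stopping

No canonical stopping rule exists for this family of models. The loop
stops at `max_iters` (default 1000, a safety cap) or when the area of
{φ < 0} changes by less than `tol` (default 1e-3, relative) over the
last `patience` (default 60) iterations. The horizon form matters: the
hard cases evolve at a slow, steady ~0.1 px/iteration while expelling
wrongly included background, which a per-iteration change test mistakes
for convergence. All three values are configuration-exposed. The
per-iteration log (iteration, total energy, inside area, u₁, u₂, σ₁²,
σ₂²) is returned with the result and can be written as CSV.

## Parameters

| name | meaning | default | units |
|------|---------|---------|-------|
| Δt (`dt`) | explicit time step | 4 | – |
| `c0` | initial step height of φ₀ | 2 | – |
| μ (`mu`) | distance-regularization weight | 0.05 | – |
| λ (`lam`) | geodesic length weight | 10 | – |
| ν (`nu`) | balloon weight (+ shrinks inside) | 2 | – |
| τ (`tau`) | Gaussian-region weight (0 disables) | 0.01 | – |
| ε (`epsilon`) | H/δ mollifier width | 2 | px |
| σ (`sigma`) | edge-map Gaussian kernel std | 1 | px |
| ξ (`xi`) | growth threshold weight | 0.6 | – |
| `window` | crop side, odd | 45 | px |
| `max_iters` / `tol` / `patience` | stopping rule | 1000 / 1e-3 / 60 | – |

The first eight are the model's standard operating point; intensities
are kept on their native scale (the growth rule and the Gaussian region
terms are covariant under affine intensity maps, and σ, ε are defined in
pixel units), so no [0,1] normalization is applied on load.

## Phantom generator

`phantom.generate_phantom` renders what makes the clinical problem hard,
with known ground truth: an elliptical (or crescent) target of a few
hundred pixels in a 157×189 frame; Gaussian intensity distributions for
target and background; smooth multiplicative shading
1 + a·P₂(x, y) with a fixed normalized second-order polynomial
(emulating coil inhomogeneity); partial-volume blur across a boundary
band; and optionally a contiguous angular fraction of the boundary
blended into background (broken boundary). Order matters and follows
acquisition physics: the *noiseless* anatomy is blurred first and
per-pixel noise is added afterwards — blurring noisy pixels instead
would manufacture a low-variance halo around the target that a
variance-sensitive region model latches onto. The returned seed
emulates manual seeding: the median-intensity target pixel of the 3×3
neighborhood at the target centroid, i.e. a representative interior
point rather than a possibly outlying single pixel. One
`numpy.random.Generator` seeded per phantom makes every image
bit-reproducible.

The fixed test corpus (`phantom_suite`) holds five families × three
noise replicates: easy (means 160/80, stds 10), low-contrast (120/100),
equal-means-different-vars (120/120, stds 8 vs 25), bias-field (easy +
20 % shading), broken-boundary (easy + 20 % boundary gap).

What the phantoms do *not* model: Rician noise statistics, k-space or
motion artifacts, partial-volume mixtures of more than two tissues, and
— most importantly — neighboring confounder structures with
target-like intensity. Passing the phantom benchmarks therefore shows
the pipeline implements its model correctly and behaves as designed
under the listed degradations; it does not certify clinical accuracy.

## Design choices

- Images, masks and φ are plain numpy arrays (float64 / bool) with
  (row, col) indexing, as in scikit-image; structured values
  (parameters, growth results, region statistics, segmentation results,
  phantom specs) are dataclasses.
- The convex hull is computed from the perimeter pixel centers
  (scipy.spatial) with an explicit half-space inclusion test so the
  rasterization semantics (pixel-center, hull-edge ties included) are
  exact and degenerate inputs (single pixel, collinear points) are
  handled.
- The evolution runs on the full image frame with φ₀ embedded at the
  window offset. Evolving on the window alone was evaluated and was
  consistently worse on the phantom corpus, despite its cleaner region
  statistics — the frame provides a stable far-field for the
  distance-regularizer.
- Configuration is flat JSON; unknown keys and invalid values are
  rejected with the offending key names listed.

## Limitations

- The Cauchy tails of the arctan Heaviside mix a few percent of the
  far background into the object-region statistics whenever the object
  is small relative to the frame; with equal region means the variance
  contrast is then systematically underestimated. This bounds
  achievable accuracy on the equal-means-different-vars family (~0.86
  Dice here vs ~0.99 on the easy family).
- The balloon term moves fastest exactly where the image is smooth
  (g ≈ 1), so a very homogeneous target with ill-defined edges is
  slowly eroded once the region force weakens; results depend on the
  stopping rule in that regime.
- Growth quality depends on the seed pixel being representative of the
  target's intensity; a deliberate outlier click can still defeat it.
- 2-D only; one structure at a time; no shape prior.
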