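# Methods

## Problem and overall design

`hepaseg` segments the liver and the tumors inside it from contrast-enhanced
abdominal CT, assuming portal-venous-phase acquisition in which liver
parenchyma is enhanced relative to lesions. The design is a two-stage
cascade, each stage pairing a learned coarse segmentation with a
model-based refinement:

1. **Liver stage.** Axial slices are windowed to the −50…250 HU diagnostic
   range, median-filtered (3×3, per slice), resized to the network input,
   and passed through a 2D U-Net that emits a per-pixel liver probability.
   The thresholded prediction (≥ 0.5) is reduced to its largest 3D
   connected component and each slice is refined by a localized
   region-based level set.
2. **Tumor stage.** The axis-aligned bounding box of the liver (5 px
   margin, background zeroed outside the liver mask) is cropped, enhanced
   with 3D edge-enhancing diffusion (EED), and passed through a second
   U-Net trained to find tumors inside the liver envelope. Its prediction
   is refined per slice by the same level set and intersected with the
   liver mask.

Evaluation is the Dice overlap per case, `2|A∩B| / (|A|+|B|)`, reported
separately for the network-only and the refined masks so the contribution
of the level set can be read off directly.

## Preprocessing

**HU window.** `(clip(I, −50, 250) + 50) / 300` maps the diagnostic range
onto [0, 1]. The window spans liver parenchyma (~120 HU) and hypodense
lesions (~45 HU) while saturating air, lung, fat below −50 and bone above
250. Monotone and idempotent once intensities are in range.

**Median filter.** 3×3 per-slice median with reflective borders, applied
after windowing, for the liver stage only. Its purpose is intensity
homogenisation, not denoising per se; the kernel is deliberately small so
boundary geometry is untouched.

**Edge-enhancing diffusion.** The tumor-stage volume is smoothed with
`u_t = div(D ∇u)` where `D` has eigenvalue `g(|∇u_σ|²)` across the
(σ-smoothed, ρ-averaged) gradient direction and 1 on the orthogonal
complement — written in closed form as `D = I + (g−1) ŵŵᵀ` for the unit
gradient direction `ŵ`, so no per-voxel eigendecomposition is needed. The
diffusivity is Weickert's `g(s) = 1 − exp(−C_m / (s/λ²)^m)` with `m = 4`,
`C_m = 3.31488`, which keeps `g(0) = 1` (free diffusion in flat regions)
and suppresses flux across strong edges. Defaults: `σ = 1 px`, `ρ = 2 px`,
`λ = 0.05` (windowed-intensity units, i.e. 15 HU), `τ = 0.1`,
10 explicit steps. `τ` is validated against the stability bound
`τ ≤ 1 / (2 Σ 1/h_i²)` for voxel sizes `h_i` before iterating.

Numerics: the update uses a conservative flux form — face fluxes are
averages of adjacent cell fluxes and vanish on the domain boundary — so
the volume mean is conserved exactly up to the limiter. Because full
anisotropic stencils do not satisfy a discrete extremum principle, every
update is clamped to the 3×3×3 neighbourhood range of the previous
iterate (a monotone limiter); this guarantees no new extrema at the cost
of a vanishingly small conservation error (measured drift ~1e−7
relative on the test fixtures, against a 0.1% tolerance).

## U-Net

Both stages use the same family: a contracting path of `depth` levels
with two 3×3 conv+ReLU layers per level and 2×2 max pooling (channels
doubling from `base_filters`), a two-conv bottleneck, and an expanding
path of 2×2 stride-2 transposed convolutions, skip concatenation, and a
single 3×3 fusion conv per level. Dropout (0.5) precedes the final 1×1
convolution whose sigmoid yields per-pixel probabilities. At the default
configuration (256×256 input, depth 4, base 32) the architecture counts
exactly 19 convolutional layers: 8 contracting + 2 bottleneck + 4
transposed + 4 fusion + 1 output.

The implementation is pure NumPy in channels-last layout: 3×3
convolutions are computed as nine shifted BLAS matmuls (no im2col
buffer), with hand-derived backward passes verified against central
finite differences to ~1e−7 relative error in float64. It trains small configurations on a
CPU in minutes; it is not meant for GPU-scale corpora.

**Loss.** Soft Dice per sample, `1 − (2Σpt + ε)/(Σp + Σt + ε)` with
`ε = 1`, averaged over the batch. On binary predictions with ε→0 this is
exactly `1 − Dice`, tying the training objective to the evaluation
metric.

**Slice selection.** Slices with an empty target mask are excluded from
training (so every batch contains foreground), and for the tumor stage
volumes without any tumor annotation are excluded entirely. An optional
`max_slices` uniformly subsamples the selected slices; the synthetic
experiment uses it to bound CPU time.

**Optimisation.** Adam at 0.001, reduced by ×0.1 when the monitored loss
fails to improve by more than `min_delta = 1e−4` for 5 consecutive
epochs (reduce-on-plateau), clamped at `min_lr = 1e−5` so long runs keep
learning. When a validation split exists its loss is monitored; without
one, the training loss is re-evaluated in inference mode (dropout off)
on a fixed subset, so plateau detection is not driven by dropout noise.
Defaults are 20 epochs at batch 32; one seed governs initialisation,
shuffling and dropout.

**Liver envelope closure.** Both the thresholded network output (after
its largest-component reduction) and the refined mask are closed by
per-slice hole filling. The liver *envelope* includes the lesions inside
it, which are darker than parenchyma; any intensity-driven step —
thresholding or the level set — carves them out, so the envelope is
restored by filling interior holes. This is the standard liver-mask
postprocessing and is required for the tumor stage, whose region of
interest must contain the lesions it is asked to find.

## Localized level set

The refinement embeds the coarse mask as a signed Euclidean distance
`φ` (negative inside, zero level between the boundary pixel rows via a
half-pixel offset, so `|∇φ| ≈ 1` across the front) and evolves

    φ ← φ + dt · δ_ε(φ) · [ (I − u_x)² − (I − v_x)² + μ·κ ]

on the narrow band `|φ| ≤ r`, where `u_x`, `v_x` are the interior and
exterior mean intensities within the radius-`r` ball at each point
(computed for all points at once by disk-kernel convolution), and `κ` is
the curvature of `φ` (central differences, clipped to ±1/px). Points
whose ball lacks one side get zero force. The bracketed force is
normalised to unit maximum on the band before the step, so the front
advances at most `dt = 0.45` px per iteration — without this the squared
windowed-intensity forces move the front ~0.01 px/iteration and no
practical iteration budget converges. `φ` is reinitialised to a signed
distance every 20 iterations. The evolution stops at `max_iters`
(defaults 200 liver / 100 tumor), when the mean applied `|Δφ|` on the
band falls below `tol = 1e−3`, or when the sign mask has not changed for
10 consecutive iterations (a pinned front).

Defaults: `r = 9 px` at network resolution, `μ = 0.2` (dimensionless
after force normalisation), `ε = 1.5 px` for the smoothed Heaviside/
Dirac pair. Components whose local interior and exterior means are
indistinguishable feel only the curvature force; small such components
(the spurious non-lesion blobs a network sometimes emits) shrink and
vanish, while genuine lesions are anchored by their contrast.

**Otsu gate.** The coupling between Otsu thresholding and the level set
is implemented as an intensity gate on the interior statistics: an Otsu
cut is computed over the initial mask's bounding box dilated by `2r`,
and pixels on the wrong side of it (below the cut for the bright liver,
above it for dark tumors) contribute to the exterior statistics only.
The gate is off by default in `evolve` and enabled by the pipeline
presets. The Otsu implementation bins into 256 equal-width bins and
maximises between-class variance with class means computed from raw
pixel value sums, so it agrees exactly with an exhaustive search over
the same cuts (ties take the lowest cut); a constant image is a
degenerate-input error.

The refinement runs at network resolution (per-slice, 2D) and the result
is mapped back to the native grid by nearest-neighbour inverse resize —
cheaper than refining at native resolution and consistent with the
network geometry. The global Chan-Vese energy (curve length times `μ`
plus the two region residuals with global means) is computed only as a
descent diagnostic.

## Synthetic phantoms

The generator emulates the intensity structure the cascade relies on —
not anatomy. Each case renders, on a 128×128×48 grid with 1.5×1.5×3 mm
spacing: an elliptic-cylinder soft-tissue body (40 HU) in air (−1000 HU)
with lateral bone arcs (500 HU); a liver as an ellipsoid whose implicit
surface is perturbed by a smooth random field (relative amplitude 0.15),
painted at 120 ± 15 HU with low-frequency texture; 0–4 spherical tumors
of radius 4–14 px painted at 45 ± 10 HU, planted where the liver's
distance transform leaves ≥ 2 px margin; and i.i.d. Gaussian noise
(8–12 HU sd across the corpus). All HU choices sit inside the −50…250
window with tumors darker than parenchyma and a liver/tumor separation
of ~75 HU ≳ 3× the noise sd — the portal-venous contrast regime the
method assumes. Corpus generation draws per-case parameters from stated
ranges under a master seed and records every draw in a manifest.

What phantoms do *not* model: anatomical shape variability, vessels,
partial-volume effects at thick slices, scanner noise spectra, contrast
timing variability, or lesions touching the liver surface. Passing the
synthetic experiment therefore demonstrates that the pipeline's
machinery — training, cascading, refinement, bookkeeping — behaves as
designed under the assumed contrast regime; it does not certify clinical
accuracy on real CT.

## The scaled experiment

The end-to-end experiment trains both stages on 40 phantoms and
evaluates on 10 held-out phantoms. Problem sizes are chosen so the whole
experiment runs on one CPU core in minutes: network input 128×128
(native phantom resolution, no resize loss), depth 3, 8 base filters,
batch 16, at most 320 liver / 240 tumor training slices, 12 epochs for
the liver stage and 30 for the tumor stage (small lesions need more
optimisation steps than the large, high-contrast liver).
The full-scale defaults (256×256, depth 4, base 32, 20 epochs) remain
the package defaults for real data; the experiment preset is a
configuration of the same family, not a different architecture.

## Known limitations

- The NumPy backend makes large-corpus training (tens of thousands of
  slices) impractical; the package targets method verification and
  small-corpus use.
- The level set force normalisation makes `μ` dimensionless but also
  image-dependent; energies are comparable within one slice only.
- The tumor stage inherits liver-stage errors by construction (tumors
  are sought only inside the predicted liver envelope).
- Slices are processed independently (strictly 2D); no through-plane
  regularisation beyond the 3D connected-component step.
- Tumor-stage specificity on tumor-free volumes is poor by construction:
  the slice-selection rule trains the tumor network exclusively on
  slices that contain tumor, so it has never seen a negative liver and
  tends to label the darkest texture patches of a healthy parenchyma as
  lesions (measured ~1.4e4 false-positive voxels on a tumor-free phantom,
  reduced but not removed by the level set). Cases with tumor-free truth
  are therefore reported separately and excluded from the tumor mean;
  deploying the cascade as a lesion *detector* would require negative
  examples or a count-calibrated threshold, which is out of scope here.
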