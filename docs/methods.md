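# Methods

## Problem and model

Microbiome count tables (samples × OTUs/ASVs) are compositional — only
relative abundances carry information — and zero-inflated, often with the
overwhelming majority of cells exactly zero. Log-ratio transforms (alr, clr,
ilr) are undefined at zero and force a replacement step that distorts the
data. This package takes the spherical route instead:

1. **Closure.** Each sample's counts are divided by their total, placing the
   sample on the closed simplex `S^{d-1}` (boundary zeros allowed — they are
   the point).
2. **Square-root transform.** `y_i = sqrt(x_i)` maps the simplex onto the
   nonnegative orthant of the unit hypersphere `C^{d-1}`: sum-to-one becomes
   unit Euclidean norm, and exact zeros map to exact zeros with no
   replacement.
3. **Tangent projection (PGA).** The Fréchet mean `p` — the minimizer of the
   summed squared geodesic (great-circle) distance — is found by the Karcher
   fixed-point iteration (initialized at the normalized extrinsic mean, step
   size 1, tolerance 1e-10, max 200 iterations; convergence is guaranteed in
   an open hemisphere, which contains all orthant data). A rotation `R` with
   `R p = (0,…,0,1)` acting only in `span{p, pole}` carries the data to the
   pole, where the Log map has the closed form
   `Log(x) = (θ/sin θ)(x₁,…,x_{d−1})`, `θ = arccos(x_d)`. Angles below 1e-6
   use the series `θ/sin θ ≈ 1 + θ²/6` (and `sin r / r ≈ 1 − r²/6` in the Exp
   map) to avoid 0/0 at the pole. The tangent rows are the flat Euclidean
   coordinates used downstream; tangent PCA (the classical tangent
   formulation of principal geodesic analysis) is available but applies no
   truncation by default — the tangent projection itself is the geometry
   step, and the imaging stage consumes all `d−1` coordinates.
4. **Image rendering (DeepInsight layout).** Features (tangent coordinates)
   are embedded in 2D by dimensionality reduction of the *transposed* data
   matrix (PCA default; kernel PCA and t-SNE behind flags, seeds required),
   cropped to the minimum-area bounding rectangle of their convex hull
   (rotating calipers: the optimum has a side collinear with a hull edge, so
   the edge-angle scan is exact), affinely mapped onto the pixel grid,
   rounded half-away-from-zero and clamped. Pixel collisions aggregate by
   arithmetic mean (max behind a flag). Values are normalized to `[0,1]`
   either per feature (independent min–max) or with one global training
   minimum and range (topology-preserving); both use training-subset
   statistics only, and test values clip to `[0,1]`.
5. **Segmentation offset.** After normalization, every *foreground* pixel
   (one owning at least one feature) is clamped up to `ε = 1/255`: a feature
   value of exactly zero then renders as ε rather than as background black.
   All sample images consequently share a single support equal to the
   foreground mask. ε = 1/255 is the smallest increment an 8-bit image
   consumer can see, the minimal offset that survives quantization. The
   clamp is applied after normalization because the rotation to the pole
   mixes coordinates and destroys exact zeros; clamping the rendered
   foreground realizes "all images share one shape" unambiguously.
   `segment=False` reproduces the original DeepInsight control arm, where
   zero-valued features are indistinguishable from background and supports
   fragment per sample.
6. **Classification.** Stratified k-fold cross-validation (stratification
   chosen because imbalanced cohorts can otherwise yield folds without
   positives). Within each fold, the layout and normalization statistics are
   refit on the training samples only; held-out images are rendered with the
   training fold's transforms, so no statistic leaks. The default classifier
   is a compact numpy CNN — two 3×3 convolution blocks (8 and 16 channels,
   ReLU, one 2×2 max pool), global average pooling, and a linear head —
   trained with AdamW on binary cross-entropy. It is sized for 32×32 grids
   and trains in seconds per fold on one CPU. The `resnet50` option names the
   full-scale 224×224 mode and requires a deep-learning framework; it is a
   documented extension point, not a default. AUC is the Mann-Whitney
   pair-counting probability (ties one half), computed via midranks.
   Hyperparameter search draws learning rate from `[1e-6, 1e-2]` and weight
   decay from `(1e-6, 1e-2)`, uniformly in log10, with a full trial log;
   selecting the max-over-trials AUC is supported but optimistically biased,
   and reports say which rule produced them.

## Synthetic data

`generate_dataset` draws, per sample, relative abundances from a Dirichlet
whose concentrations are multiplied by `effect_multiplier` at the signal taxa
in class 1 (multiplicative on concentrations so the signal survives closure),
imposes independent structural zeros by Bernoulli masking *before* sequencing
(truly absent taxa), renormalizes, and draws multinomial counts at the
sequencing depth (adding sampling zeros). The two zero mechanisms are thus
mechanistically distinct, mirroring structural vs sampling zeros in 16S data.

Presets (all parameters frozen; the zero-fraction targets are Monte-Carlo
calibrations over 50 replicates):

| preset | n | d | signal taxa | effect | mask p | conc. | depth | zero frac |
|---|---|---|---|---|---|---|---|---|
| `paper-regime` | 91 | 2000 | 50 | 3.0 | 0.6 | 0.05 | 5·10⁴ | 0.879 ± 0.001 |
| `desk-strong` | 200 | 500 | 40 | 6.0 | 0.4 | 0.3 | 2·10⁴ | 0.520 ± 0.002 |

`paper-regime` mirrors a small-cohort 16S study (91 samples, ~26% positives,
thousands of sparse taxa); its zero fraction sits below the ~98% of extreme
real tables because multinomial sampling at depth 5·10⁴ still covers many
surviving taxa at concentration 0.05 — the preset keeps those stated
parameters and owns its measured 0.879 rather than chasing a rounder number.
`desk-strong` is calibrated so an l2-logistic probe on the tangent
coordinates exceeds 0.9 AUC (measured ≈ 0.998): if the probe can read the
signal but the imaging+CNN pipeline cannot, the pipeline — not the data — is
at fault.

What the generator does *not* emulate: phylogenetic correlation between taxa,
overdispersion beyond the Dirichlet, batch effects, and compositional
outliers. Passing tests therefore certify the pipeline's mechanics and its
recovery of a planted, linearly accessible signal — not clinical performance
on real cohorts.

## Numerical choices and degenerate inputs

- Antipodal inputs to the rotation/Log map are errors, never silently fixed:
  they cannot arise from orthant data and indicate caller bugs.
- Collinear 2D layouts fall back to the segment direction with a zero-height
  rectangle; constant coordinate axes map features to the grid's center line.
- Constant features normalize to 0 under the independent scheme.
- All-zero count rows are rejected at table construction (closure undefined).
- `arccos` arguments are always clipped to `[-1, 1]`; self-distances are
  excluded from isometry assertions because `arccos` is ill-conditioned at 1.
- One master seed fans out to data generation, fold splitting, CNN
  initialization and shuffling, and search sampling; reports record it.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline on
`desk-strong` (n=200, d=500, 32×32 grid, 5-fold CV, 30 training epochs), the
label-permuted null at the same size, and a 10-replicate paired ablation of
the segmentation arms at 8 epochs; generator calibration uses 10 seeds of
`paper-regime`. These sizes complete in a few minutes on a single CPU while
leaving the strong-signal recovery margin (mean CV AUC ≈ 0.99 vs the 0.85
floor) wide enough that the checks are not knife-edge.

## Known limitations

- The numpy CNN is intentionally small; it is not a ResNet50 and makes no
  claim of matching full-scale deep-learning performance.
- Algorithm-level clustering/rearrangement of pixels after mapping is an
  extension hook, not implemented: no published procedure specifies it.
- The ε offset guarantees a common support but also erases the distinction
  between a zero and a value below ε after 8-bit quantization of a rendered
  image; float stacks (the training input) keep the distinction above ε
  exactly.
- The segmentation arm's AUC advantage on synthetic data is noisy at desk
  scale; the shipped ablation asserts non-inferiority plus the support
  invariant, not a strict win.
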