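# sphereinsight

Hypersphere-adapted DeepInsight for zero-inflated, high-dimensional
compositional count data — built for microbiome OTU/ASV tables where the
vast majority of cells are exactly zero and only relative abundance carries
meaning.

## The problem and the method

A sample of counts `c ∈ ℕ^d` is closed to a composition
`x = c / Σc ∈ S^{d-1}`. Log-ratio transforms, the classical route into
Euclidean space, are undefined at the boundary zeros that dominate 16S data
and force a zero-replacement step that distorts it. The square-root map

    y = T(x) = (√x₁, …, √x_d),   ‖y‖₂ = 1,

instead sends compositions onto the nonnegative orthant of the unit
hypersphere `C^{d-1}` while mapping exact zeros to exact zeros. Geometry is
then done intrinsically: the Fréchet mean `p = argmin Σ d_g(p, yᵢ)²` (with
`d_g = arccos⟨·,·⟩` the great-circle distance) is rotated to the pole, and
the Log map

    Log_p(y) = (θ / sin θ)(y₁, …, y_{d−1}),   θ = arccos(y_d)

flattens the data into the tangent space (principal geodesic analysis,
tangent formulation). The tangent coordinates feed a DeepInsight imaging
stage: features are positioned in 2D by dimensionality reduction of the
transposed matrix, cropped to the minimum-area rectangle of their convex
hull, snapped to a pixel grid, normalized to `[0,1]`, and each sample is
rendered as a grayscale image for a CNN.

The key modification for zero-inflated data is a **segmentation offset**:
every foreground pixel is clamped up to `ε = 1/255` after normalization, so
a "true zero" (a feature whose value is zero) remains distinguishable from a
"fake zero" (background pixel with no feature). All images then share one
support — without the offset, zero-heavy samples render with fragmented,
sample-specific silhouettes that a CNN wastes capacity learning.

Classification is stratified k-fold cross-validation of a compact CNN
(AdamW, binary cross-entropy), scored by Mann-Whitney AUC, with log-uniform
random search over learning rate `[1e-6, 1e-2]` and weight decay
`(1e-6, 1e-2)`. Layout and normalization statistics are refit inside each
training fold, so nothing about held-out samples leaks into the transforms.

## Worked example

A built-in generator produces zero-inflated Dirichlet-multinomial count
tables with a planted class signal (structural zeros by masking, sampling
zeros from finite depth):

```python
import sphereinsight as si
from sphereinsight.classification import ImagingConfig, TrainConfig, cross_validate
from sphereinsight.synthetic_data import preset_params
from sphereinsight.pipeline import tangent_features

table, labels, signal_taxa = si.generate_dataset(preset_params("desk-strong", seed=1))
print(f"zero fraction: {si.empirical_zero_fraction(table):.3f}")
features = tangent_features(table)           # closure -> sqrt -> tangent space
print(f"tangent coordinates: {features.shape}")
report = cross_validate(features, labels, imaging=ImagingConfig(),
                        train_config=TrainConfig(epochs=30, seed=1), k=5, seed=1)
print("fold AUCs:", [round(a, 3) for a in report.fold_aucs])
print(f"mean AUC: {report.mean_auc:.3f}")
```

prints

```
zero fraction: 0.521
tangent coordinates: (200, 499)
fold AUCs: [1.0, 1.0, 1.0, 0.988, 0.995]
mean AUC: 0.996
```

52% of the 200×500 count table is exactly zero; after the spherical
transform the 499 tangent coordinates are rendered as 32×32 images per CV
fold, and the CNN recovers the planted signal almost perfectly (a
label-permuted control at the same settings scores ≈ 0.5, chance). The same
pipeline runs from the shell:

```sh
sphereinsight simulate data/ --preset desk-strong --seed 1
sphereinsight cv data/counts.tsv data/labels.tsv --k 5 --seed 1
sphereinsight run --preset desk-strong --out-dir runs/demo --seed 1
```

Real tables enter as TSV (header of taxon ids, first column sample id) with
a two-column label file; every run writes a manifest with the config hash
and all seeds.

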