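# histoage

Histopathologic brain-age estimation from whole-slide images (WSIs) by
context-aware, attention-based multiple instance learning — and the
downstream "age acceleration" analyses neuropathologists actually run on
such a model.

## The problem

Chronological age can be estimated from biological inputs (epigenetic
clocks, MRI); the residual between estimated and actual age quantifies
accelerated or decelerated aging. Histology offers cellular-level
signal that neither modality sees, but a hippocampal WSI is gigapixel
scale with only a single slide-level label (age at death), and
neuroanatomical topography matters. This package implements a pipeline
for that setting:

1. **Slide prep** — Otsu thresholding of the HSV saturation channel
   separates stained tissue from glass; the slide is cut into
   non-overlapping 256 × 256 px tiles with exact top-left coordinate
   bookkeeping (`histoage.prep`).
2. **Tile encoding** — each tile becomes a feature vector `h ∈ R^1024`
   via a ResNet-50 truncated after its third residual stage with global
   average pooling, or a fast hand-crafted toy descriptor for
   desk-scale work (`histoage.encoder`, `histoage.resnet`).
3. **Slide graph** — tiles are nodes; edges join tiles whose top-left
   coordinates lie within `256·√2` px (the tile diagonal), i.e. the
   8-neighbourhood in slide space, built with a kd-tree radius query.
   Every row sum of the adjacency matrix `A` is in `[1, 8]` after the
   isolated-tile drop policy (`histoage.graph`).
4. **Model** — two GraphSAGE convolutions (ReLU, hidden width
   `d = 256`) give node representations `G′ ∈ R^{M×d}`; a
   pooling-by-multihead-attention block (one learnable seed query, 2
   heads, graph-convolutional key/value transforms) gives a slide
   representation `Z ∈ R^{1×d}`; a fully connected layer predicts age
   `Y′` in years, trained with MSE loss (`histoage.model`, implemented
   on an in-package reverse-mode autodiff engine, `histoage.autodiff`).
5. **Training/evaluation** — repeated random 90/10 cross-validation
   (50 folds by default), Adam (lr 5e-4, weight decay 0.01, dropout
   0.30, batch 8), MAE/RMSE/MSE per fold, plus the 2 × 2 ablation
   lattice replacing graph convolutions with per-node MLPs and
   attention with mean pooling (`histoage.train`).
6. **Acceleration statistics** — acceleration = residual of `Y′`
   regressed on `Y` (bias correction), then univariate (t, ANOVA F,
   Pearson r, Spearman ρ) and adjusted (logistic/OLS with sex and age
   as nuisance covariates) associations, a composite cognitive
   impairment label (CDR ≥ 0.5 or MMSE ≤ 24 or clinical diagnosis), and
   cross-correlation with methylation-clock accelerations
   (`histoage.stats`).
7. **Attention topography** — per-tile attention (mean of the two
   heads), blue→red heatmap overlays, median attention per annotated
   region (tissue type or hippocampal subfield) and one-way ANOVA with
   Tukey post-hoc across regions (`histoage.attention`).

Because autopsy WSI cohorts cannot be redistributed, `histoage.synthetic`
generates seeded cohorts with the statistical structure the pipeline
assumes — per-subject acceleration δ injected into tile features (or as
dark puncta in pseudo-stained images), spatially gated signal so that
graph context genuinely matters, and covariates with declared effect
sizes — so every stage is testable offline and recovery of the injected
truth is a measurable quantity.

## Worked example

Train on a synthetic feature cohort (200 subjects, injected acceleration
σ_δ = 5 y, unit feature noise, 10 × 10 tile grids, 64-d features), then
test whether the model's out-of-fold acceleration recovers the injected
truth:

```python
import numpy as np
from scipy import stats as sps
from histoage import (SimConfig, simulate_feature_cohort, graph_from_features,
                      ModelConfig, TrainConfig, cross_validate,
                      compute_acceleration, associate_univariate)

cfg = SimConfig(n_subjects=200, accel_sd=5.0, noise_sd=1.0, feature_dim=64, seed=1)
bags, record, truth = simulate_feature_cohort(cfg)
graphs = [graph_from_features(b.slide_id, b.X, b.coords, age=b.age) for b in bags]
ages = np.array([b.age for b in bags])

res = cross_validate(graphs, ages, TrainConfig(n_folds=5, epochs=30, seed=1),
                     ModelConfig(input_dim=64, hidden_dim=32))
print(res.summary().round(2))

accel = compute_acceleration(res.pooled_oof())
merged = accel.merge(truth.subjects[["id", "accel"]], left_on="slide_id",
                     right_on="id", suffixes=("_est", "_true"))
r, p = sps.pearsonr(merged["accel_est"], merged["accel_true"])
print(f"r(estimated accel, injected delta) = {r:.2f} (n={len(merged)})")
```

Output (≈2 min on one CPU):

```
       mae  rmse    mse
mean  5.33  6.58  44.77
std   1.09  1.34  19.22
r(estimated accel, injected delta) = 0.74 (n=82)
```

The cohort's ages are uniform over 51–108 y, so a mean-predictor
baseline sits near MAE ≈ 14 y; the model's 5.3 y shows it reads the age
signal out of the tiles, and `r = 0.74` shows the bias-corrected
residual tracks the *injected* per-subject acceleration, not just age.
Univariate association of that residual with the generator's binary
impairment covariate gives `T = 2.13, p = 0.037` — the generator plants
the effect and the statistics recover it.

The same pipeline is scriptable from the shell (`histoage simulate`,
`prep`, `encode`, `graph`, `train`, `predict`, `stats`, `attend`); run
`histoage --help` for the commands.

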