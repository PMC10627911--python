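# Methods

## Model

A whole-slide image is represented as a graph `G = (X, A)`: `X ∈ R^{M×F}`
stacks the feature vectors of the `M` retained 256-px tiles and
`A ∈ {0,1}^{M×M}` is the spatial 8-neighbourhood adjacency
(`A_ij = 1 ⇔ 0 < ‖c_i − c_j‖₂ ≤ 256·√2 + ε`, `ε = 1e-6` px, on top-left
tile coordinates). The kd-tree radius query used in practice is
contractually identical to all-pairs thresholding and is tested against
that oracle. Self-edges are excluded; any self-loop needs are the
convolution's self-path. Disconnected tissue fragments are allowed
(message passing is component-local); isolated tiles are dropped by
default so every adjacency row sum lies in `[1, 8]`, with a `keep`
policy available for auditing.

The regressor is:

* **Graph module.** Two GraphSAGE layers with mean aggregation and a
  separate self-path weight (`H ← ReLU(H W_self + D⁻¹A H W_nb + b)`),
  `F → d → d`, `d = 256` by default.
* **Attention pooling.** Pooling by multi-head attention with a single
  learnable seed query and 2 heads. Key and value projections are
  GraphSAGE transforms over the same adjacency, keeping the pooler
  topology-aware; per-head weights are softmax-normalised over the `M`
  nodes; head outputs are concatenated and linearly mixed into
  `Z ∈ R^{1×d}`. One block is used. All attention analyses use the
  post-softmax weights averaged over the two heads.
* **Head.** A single linear layer `d → 1` predicting age in years.
  Labels are never rescaled (MSE in years², MAE directly
  interpretable); instead the head bias is initialised to the
  training-set mean age, which removes the large constant offset from
  the optimisation without touching the labels.

Ablations: `ablate_graph` replaces every graph-convolutional transform
(including the pooler's) with per-node perceptron layers of identical
widths; `ablate_attention` replaces pooling with the unweighted node
mean. Together they span the 2 × 2 comparison lattice.

Training: Adam (lr 5e-4, β = (0.9, 0.999), L2-coupled weight decay
0.01 — the classical `Adam(weight_decay=…)` behaviour, not decoupled
AdamW), dropout 0.30 after each graph layer and before the head, batch
size 8, 100 epochs, final-epoch weights kept. Batches of variable-size
graphs are processed as gradient accumulation over single-graph
forwards with the loss averaged, which is mathematically identical to
disjoint-union batching for this architecture (per-graph pooling and a
mean-over-batch loss). "Fifty cross-fold validation with 9:1 splits" is
implemented as 50 repeated seeded random 90/10 splits — 50 disjoint
folds at that ratio are impossible — and fold metrics are aggregated as
mean ± SD across folds. The best fold is the argmin of validation MAE.
Out-of-fold predictions pooled across folds (per-subject mean) are the
default input to downstream statistics; single-best-fold predictions
are also available.

The network, its gradients and Adam are implemented on an in-package
reverse-mode autodiff engine over NumPy arrays; every operator's
vector-Jacobian product is unit-tested against central finite
differences, and whole-model properties (permutation invariance of
`Y′`, equivariance of `G′` and attention, attention normalisation,
eval-mode determinism) are asserted directly.

## Tile encoding

The deep encoder is a 50-layer residual network truncated after its
third residual stage (the 1024-channel stage) with global average
pooling — the only truncation consistent with a 1024-d output — run as
a pure NumPy forward pass (im2col convolutions, inference-mode batch
norm). Pretrained weights are a user-supplied `.npz`; nothing is
downloaded, and with seeded random initialisation the shape and
determinism contracts still hold, which is what the tests check. Tiles
are scaled to `[0, 1]`; whether the original pipeline applied channel
normalisation before encoding is unknown, so none is baked in. The toy
encoder (dark-pixel fraction, channel moments, HSV statistics, 8-bin
intensity histogram; 19 base features, zero-padded to the requested
width) exists so that desk-scale experiments and the image pathway are
fast and interpretable — its feature 0 directly tracks the puncta
density the synthetic images use to encode effective age.

## Synthetic cohorts

The generator emulates the statistical structure of an aged autopsy
cohort, not its visual appearance. Per subject: chronological age `Y`
uniform over the study range (default 51–108 y, chosen for even
coverage of the regression target), acceleration `δ ~ N(0, σ_δ)`
truncated so `Ỹ = Y + δ` stays within 10 y of the range (avoids
extrapolation artifacts), default `σ_δ = 5` y. Each slide is a
`rows × cols` tile grid (default 10 × 10) with randomly placed signal
(default 30% of tiles) and context (default 10%) regions. Signal tiles
carry mean `g(Ỹ) = 0.05·(Ỹ − 50)` on the first 4 feature dimensions
plus `N(0, noise_sd²)` noise (default 1.0); all other tiles are pure
noise; context tiles carry an indicator on dimension 4. With
`context_coupling` on, a signal tile expresses the full mean only if at
least one of its 8 grid neighbours is context-labelled (otherwise
attenuated ×0.1) — a task where message passing provably helps, since a
tile-wise model cannot distinguish a gated old subject from an ungated
young one. The sparse-signal variant (5% signal tiles) is the analogous
designed stress test for attention pooling versus mean pooling.
Covariates are drawn with declared effects per SD of δ: binary via
`logit p = β·δ/σ_δ`, continuous via `β·δ/σ_δ + N(0,1)`, ordinal via a
logistic latent cut at quartiles (defaults: impairment, NFT-like
density, Braak-like stage, each β = 0.5).

Image mode renders each subject as a white canvas with a
nested-ellipse pseudo-stained blob (leptomeningeal rim, pink gray
matter, blue white matter) and dark puncta in the white-matter core
with Poisson intensity `1.2e-5 px⁻¹ · Ỹ` — enough puncta to be
countable but sparse on an 8-px lattice so connected components never
merge and the count is exactly recoverable. Counts are drawn by inverse
transform from a shared uniform so they are monotone in `Ỹ` at fixed
seed. Everything is a pure function of the config seed.

What passing tests do **not** show about real data: no stain or scanner
variability, no texture, no section-position or hemisphere variance, no
tissue artifacts; the age signal is linear and low-dimensional by
construction. The synthetic results certify the machinery (recovery of
a planted signal under the pipeline's assumptions), not clinical
performance.

## Statistics

Acceleration is the residual of OLS `Y′ ~ 1 + Y`; by construction it is
mean-zero and uncorrelated with `Y` (asserted to 1e-8). Univariate
associations: two-sample pooled-variance t (Welch by flag; reported `T`
is mean(high level) − mean(low level) over the pooled SE), one-way
ANOVA F, Pearson r, Spearman ρ; complete cases per variable with `n`
reported; no multiple-testing correction in headline output. Adjusted
models: logistic (binary outcome) or OLS, always `outcome ~ accel + sex
+ age`, with acceleration standardised to unit variance by default so
odds ratios are per SD of acceleration (raw-years mode available); Wald
95% CIs; perfect separation is flagged with an unbounded CI rather than
failing silently. Clock comparison applies the same bias correction to
each clock-age column (complete cases per clock) and reports the
pairwise Pearson matrix; pairs with fewer than 3 complete cases are
missing. Region comparison of per-subject median attention uses one-way
ANOVA with Tukey HSD post-hoc; regions contributed by a single subject
are dropped with a record.

## Numerical choices and desk-scale profile

Tolerances: adjacency radius ε 1e-6 px; attention normalisation 1e-6;
permutation invariance 1e-4; residual orthogonality 1e-8. Tile-label
ties break to the smaller label id; tiles with > 50% unlabeled pixels
are unassigned. Heatmap normalisation is per-slide min–max for display
only. Graph archives are compressed `.npz` with COO adjacency and a
SHA-256 checksum verified on load.

Tests and examples run at a reduced profile chosen to finish in minutes
on one CPU — n = 200 subjects, 10 × 10 grids, F = 64, d = 32, 5
folds × 30 epochs (and n = 120, 8 × 8, 2 folds × 20 epochs for the
ablation orderings) — while the library defaults retain the full-scale
protocol (F = 1024, d = 256, 50 folds × 100 epochs). At the reduced
profile the recovery and ordering claims are stochastic; they are
asserted as medians over three generation seeds.

## Known limitations

No pyramidal-WSI reader is bundled (flat TIFF/PNG only; a pre-extracted
level array can be passed directly, and the plugin contract is
`open(path, level) → array`). No stain normalisation or artifact
detection. The NumPy implementation is single-CPU and desk-scale; it is
not intended for 689-slide, 1024-d production training runs. Pretrained
encoder weights are a contract, not shipped. Attention analyses assume
post-softmax weights; pre-softmax scores are not exposed.
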