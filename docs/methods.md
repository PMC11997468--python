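# Methods

This note documents the models and procedures the package implements, the
synthetic data they are exercised on, the numerical choices involved, and
what the test suite does and does not establish.

## The cold-start AL protocol

A run is parameterized by a budget schedule $B = N_0 + k N_1$ (defaults
$N_0 = 10$, $N_1 = 10$, $k = 4$, so checkpoints at budgets
10, 20, 30, 40, 50). The initialization stage selects $N_0$ samples with a
label-free strategy; each subsequent iteration queries $N_1$ more. After
every annotation batch the classifier is retrained **from scratch** on the
accumulated labeled set. Retraining from scratch (rather than continuing
from the previous parameters) is the default because it makes checkpoints
comparable across runs and exactly reproducible from one seed;
warm continuation is available via `run_al(..., retrain="continue")`.
Evaluation uses the held-out test set at every checkpoint; the test set is
never used for training, model selection, or stopping, and no validation
set exists anywhere in the protocol — the cold-start premise is that no
labels beyond those purchased exist.

Pool bookkeeping is explicit: `PoolState` maintains the disjoint
labeled/unlabeled partition, and the `Oracle` answers label queries from a
hidden table, counting distinct annotated ids. No id can be annotated
twice.

## Initialization strategies

**Diversity.** K-means (k-means++ initialization, 10 restarts, seeded;
50 restarts on pools of at most 64 points, where extra restarts are free
and make the partition reliably the global SSE optimum) with k = budget,
on embeddings standardized per dimension to zero mean and unit variance.
Standardization is on by default — without it, high-variance embedding
dimensions dominate the Euclidean metric — and can be disabled
(`standardize=False`). From each cluster the sample nearest the exact
cluster mean is queried (the fitted `cluster_centers_` of a K-means
implementation can differ from the member mean at convergence tolerance,
so the mean is recomputed). Empty clusters, which k-means++ makes rare,
trigger a reseeded retry (up to 5) before erroring.

**Proxy-task uncertainty.** The estimator $M_u$ shares the image
classifier's trunk with its output layer widened to the embedding
dimensionality, and is trained with MSE loss (learning rate $10^{-4}$) on
the (image, embedding) pairs of the *entire unlabeled pool* — the only
data available before any annotation. Uncertainty is the MC-dropout
inference variance: $T = 100$ stochastic forward passes with dropout
active at $P = 0.5$; per output dimension the **population** variance over
the $T$ outputs (normalized by $T$, not $T-1$, matching the defining
formula); aggregated across dimensions by the mean (default) or sum — the
two give identical rankings at fixed dimensionality, and the choice is
exposed because the defining formula is scalar while the output is a
vector.

**Hybrid.** The two-step composition: the diversity clustering, then the
highest-variance member of each cluster.

**Random.** 100 replicates by default. Each replicate draws a single
permutation of the pool and takes prefixes, so the budget-$b$ set is
nested inside every larger budget's set within that replicate — required
for paired comparisons across budgets.

All ties (equal distance, equal variance, equal $|p - 0.5|$) break toward
the smallest sample id, making every selection deterministic.

## Models and training

Three roles, all implemented on a small numpy network engine
(`nn.py`: dense and 3x3 same-convolution layers, 2x2 max-pooling, ReLU,
inverted dropout, softmax cross-entropy with class weights, MSE, SGD with
momentum):

- **Pixel classifier** — conv(1→8) / pool / conv(8→16) / pool /
  dropout(0.5) / dense(64) / dropout(0.5) / dense(2). A desk-scale
  stand-in for a deep backbone: the benchmark's findings concern query
  strategies, not backbone identity, and the architecture is selectable.
- **Embedding classifier (MLP-3)** — dense(512) / dense(256) / dense(2)
  over frozen embeddings.
- **Uncertainty estimator** — the CNN trunk with an
  `embedding_dim`-wide linear output head.

Training configuration (defaults): SGD, learning rate $10^{-3}$
(classifiers) or $10^{-4}$ (estimator), momentum 0.9, batch size 10,
up to 200 epochs. The learning rate is halved after 10 epochs without
improvement and training stops after 20 epochs without improvement, where
"improvement" means the epoch-mean training loss decreased by at least
$10^{-5}$; the monitored quantity is the *training* loss because the
protocol has no validation data. Cross-entropy is class-weighted with
$w_c = n_{\text{total}} / (2 n_c)$, the standard balanced rule. A labeled
set containing a single class — possible after a budget-10 cold start on
an 87%-positive pool — trains with uniform weights and emits a
`SingleClassWarning` instead of failing, since aborting would censor
exactly the runs that make the class-balance analysis interesting.
Training is bit-reproducible from the config seed (initialization, batch
order and dropout masks all come from one generator); inference disables
dropout, so predicted probabilities are deterministic and rows sum to 1.

## Synthetic data

The generator produces what the protocol needs from data, without
modeling radiograph appearance:

- **Latent structure**: per class, `clusters_per_class` Gaussian clusters
  (default 2) whose centers sit `cluster_separation` (default 4, in units
  of the within-cluster SD) apart — so diversity sampling has real
  structure to find. A K-means on the true latents recovers the planted
  clusters (adjusted agreement > 0.95), which gates the generator in the
  test suite.
- **Images**: a fixed smooth cosine-basis expansion of the latent vector,
  plus a class-specific Gaussian-blob template whose per-sample amplitude
  is log-normal with sigma `difficulty_spread` (default 1.0) — a graded
  easy-to-hard spectrum — plus pixel noise (`noise_sd`, default 0.3),
  squashed to [0, 1] by a logistic. Default resolution 32x32 (224x224 is
  configurable but not the default; nothing in the pipeline depends on
  resolution beyond cost).
- **Calibration**: the class-signal gain is fixed at 0.2, chosen so the
  pixel classifier's learning curve is informative at bench scale — on
  the 450-image preset, random initialization averages AUROC ≈ 0.4–0.7 at
  budget 10 and ≈ 0.98 at budget 50, below an all-samples bound of
  ≈ 0.99. With a much stronger signal every strategy saturates the metric
  by budget 20 and budget comparisons degenerate into ties.
- **Presets**: `guangzhou_like` (5856 images, 4273 positive; 80/20 split)
  and `pakistan_like` (450 images, 390 positive; 50/50 split — the larger
  test share stabilizes evaluation on the small cohort). The stratified
  split takes the **ceiling** of (class count x train fraction) per
  class; this is the only rounding rule consistent with the target counts
  4686/3419 at 80/20, and it is isolated in one function so it can be
  swapped. Preset scaling rounds half-up and preserves both classes.

Encoders are synthetic stand-ins behind the interface a real pretrained
backbone would use (`make_encoder` / `encode`): `oracle_informative`
mixes a linear map of the true latents with per-sample hash noise by an
`informativeness` fraction (1.0 = an invertible linear map of the
latents, 0.0 = no task information; linear-probe AUROC is monotone in the
knob); `generic_frozen` is a fixed random convolutional filter bank with
global average pooling; `degraded` adds the hash-noise mixing to the
filter bank. Hash noise is derived from the image bytes so encoding stays
row-wise pure and deterministic. Embedding dimensionality defaults to 32.

**What passing on this data does and does not show.** The synthetic
cohorts have exactly the structure the strategies assume: compact latent
clusters aligned with class, a known-informative encoder, and
conditionally independent pixel noise. Success here demonstrates that the
pipeline's machinery is correct and that each strategy exploits the
structure it claims to exploit; it does not predict effect sizes on real
radiographs, where encoder quality, cluster structure and label noise are
all unknown. The statistical analyses likewise reproduce the *protocol*
(pairings, alternatives, table structure), not any real-data p-values.

## Evaluation and statistics

AUROC is the rank (Mann-Whitney) probability that a positive outscores a
negative with ties counted half; AUPRC is step-wise average precision.
Both are verified in the tests against brute-force oracles (exhaustive
pair counting; the hand-evaluated step rule). Bootstrap SDs use 1000
resamples by default; resamples that lose a class are redrawn, keeping
the number of effective replicates fixed. Accuracy-type metrics are
deliberately not implemented: at 87% prevalence they are dominated by the
majority class.

The five analyses consume a tidy results table (one row per run x
checkpoint x metric). Paired comparisons (encoder arms; backbone arms;
one-shot vs full AL at equal total budget) pair matched cells — e.g.
(strategy x budget x backbone) within a dataset — with replicates
averaged inside each cell first; the pairing unit is a documented choice
and the grouping columns are explicit in the code. Correlation analyses
(initialization vs subsequent performance; minority-class share of the
initialization sample vs performance) use Pearson's r with the
t-approximation p-value. All directional hypotheses are one-sided as the
protocol states them (foundation arm superior; embedding classifier
inferior; correlations positive), with two-sided available by flag; raw
p-values are reported per cell with no multiple-testing correction.
Degenerate inputs (zero-variance differences, constant vectors, fewer
than 3 pairs) raise typed errors rather than returning NaN.

## Orchestration and reproducibility

`run_experiment` executes the grid (encoders x strategies x budgets x
backbones, plus nested random baselines, random-throughout AL, and the
all-samples bound) from a YAML-loadable config. Every component seed is
`sub_seed(master_seed, *tags)` — a BLAKE2 hash of the master seed and the
component's name tags, reduced below $2^{31}$ — so any single run can be
reproduced in isolation and reruns are byte-identical. Desk-scale
defaults (450-image preset, 10 random replicates, 2 AL replicates,
bootstrap 200) complete in roughly 15–30 minutes on one CPU; the paper
protocol's values (100 random replicates, bootstrap 1000) remain the
defaults of the underlying functions.

## Known limitations

- The numpy engine is single-threaded and desk-scale; it is not a
  framework replacement, and the CNN is far smaller than production
  backbones.
- PNG round-trips quantize pixels to 8 bits and drop latents (the NPZ
  bundle keeps them).
- One-sided p-values from the t approximation are exact only under
  normality of cell differences; with ~10–20 cells the analyses are
  directional instruments, not precision inference.
- `oracle_informative` requires generator latents and therefore cannot
  wrap real image datasets; `generic_frozen` / `degraded` can.
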