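# Methods

This note records the models, metrics, synthetic-data design and
numerical choices behind `milrel`, and what the synthetic experiments do
and do not establish.

## Problem setting

A slide is a bag `X = {x₁ … x_N}` of patch feature vectors
(`d = 1024` by default, matching ResNet50 features of 256 px patches at
20×) with grid coordinates, and a slide-level label `Y`. Every
aggregator first compresses instances through a shared affine map plus
ReLU (`1024 → D = 512`), pools the embeddings into a slide
representation, and predicts class logits. Besides logits, each
architecture (except plain mean pooling, which has no per-patch quantity)
emits one or more per-patch score sets tagged by channel:

| channel | meaning | constraint |
|---|---|---|
| `attention` | convex pooling weights | non-negative, sums to 1 |
| `patch_prob` | per-patch class probability | values in [0, 1] |
| `selection` | share of element-wise-max wins | values in [0, 1] |

Reliability is the concordance of these scores with patch labels derived
from region annotations.

## Patch labels from polygons

Patch footprints are half-open squares `[x, x+p) × [y, y+p)` in level-0
pixels. The default rule labels a patch positive when its center point
lies inside (or on the boundary of) any annotated polygon of any tumor
class; an `any_overlap` rule (positive-area intersection) is also
provided because published descriptions of this step are usually
ambiguous between "falls within" and "intersects". Center-in is the
common convention for 256 px grids and avoids sliver-overlap
ambiguities; `any_overlap` always labels a superset, which the tests
assert.

## Aggregators

* **mean_pool / max_pool** — element-wise mean / max of embeddings, then
  a linear classifier. Max pooling's `selection` score of instance `i`
  is the fraction of embedding dimensions whose maximum is attained at
  `i`, ties split equally. The "selected patch index" of a max-pooled
  model is inherently ambiguous under element-wise max; the
  argmax-fraction form was chosen because it spreads mass across all
  winning instances and degenerates toward uninformative scores whenever
  the classifier does not concentrate on few dimensions.
* **mean_pool_ins / max_pool_ins** — a linear classifier scores each
  embedded instance; instance probabilities are mean-pooled (bag
  probability = instance mean) or class logits max-pooled. The
  instance-level max variant emits both a `selection` channel (class-
  winning instances) and a `patch_prob` channel, evaluated separately.
* **abmil** — gated attention
  `aᵢ = softmax(w·(tanh(V hᵢ) ⊙ σ(U hᵢ)))` with `V, U : 512 → 256`
  (with biases) and scalar head `w`; the weighted embedding sum feeds the
  classifier. The gate width 256 is fixed by the published parameter
  counts (789 K for the binary model is reproduced exactly by this
  shape).
* **clam_lite** — abmil plus one instance-scoring head per class
  (`512 → C` each), trained with an auxiliary cross-entropy on the top-k
  and bottom-k attention patches (k = 8, weight 0.3; both
  config-exposed). The heads participate only in the training loss, so
  FLOPs equal abmil's.
* **madmil** — the embedding is split into `heads` contiguous slices;
  each head runs gated attention (gate width `256/heads`) on its slice,
  and the per-head weighted sums are concatenated. The reliability score
  is the head-mean attention, renormalized. These shapes reproduce the
  published multi-head sizes (658 K / 660 K for two heads, binary /
  7-class).
* **acmil_lite** — `heads` attention branches share `V, U` and own
  separate scoring vectors; the bag representation is the branch mean and
  training adds a branch-diversity penalty (mean pairwise cosine of
  branch attentions, weight 0.1). Reliability uses the branch-mean
  attention.
* **dtfd** — instances are partitioned into `M = 8` pseudo-bags; a
  shared tier-1 gated attention + classifier summarizes each pseudo-bag
  (pseudo-bag-level cross-entropy on the slide label), and a tier-2
  attention + classifier pools the pseudo-bag features into slide
  logits. The partition is a spatial round-robin over the canonical
  coordinate order — deterministic and permutation-equivariant, so the
  model keeps the permutation-invariance contract that a per-step random
  partition would break. The `patch_prob` channel is a
  gradient-times-input attribution of the tier-1 predicted-class logit
  with respect to each instance embedding (`aᵢ·(w_c·hᵢ)` for the linear
  head), min-max mapped to [0, 1].
* **additive variants** — for the attention models, the classifier is
  applied per instance to `aᵢ hᵢ` and the bag logit is the exact sum of
  instance contributions (asserted to 1e-5). Additive models emit the
  attention channel and a contribution-based `patch_prob` channel
  (instance contribution vector through a softmax).

For multi-class problems, probability channels report the bag's
predicted class; attention channels are class-agnostic.

### Accounting

Parameter counts enumerate trainable scalars. FLOPs are
multiply-accumulate counts of one inference forward pass: weight
multiplications only (no biases, nonlinearities, or
activation-activation products), instance-wise layers counted per
instance (120 per bag by convention), bag-level layers once. This
convention reproduces the published Size and FLOPs columns exactly for
the pooling and abmil/clam/madmil families; the two-tier model's
published FLOPs and its 7-class size are not derivable from any
composition we tried, so `milrel` reports its own analytic count there.

## Training

Adam (lr 1e-4), cross-entropy plus the architecture's auxiliary losses,
50 epochs, one bag per optimization step (bags have variable N, so no
stacking), no early stopping. Weight decay is selected from a small grid
by final validation loss, re-initializing the model per candidate;
selection is reproducible from the logged curves. Every run is
deterministic given the model seed, which controls both initialization
and epoch shuffling. Training runs in float32 on a small tape-based
autodiff engine over numpy (float64 is used in the test suite's
finite-difference gradient checks); Adam's bias correction is folded
into scalar coefficients and updates are performed in place.

Classification metrics: AUC on the positive-class probability (macro
one-vs-rest for multi-class) and macro F1 of the argmax prediction.

## Reliability metrics

MI uses the plug-in estimator on quantile-binned scores (2 bins at the
median by default; probability channels binned at 0.5), natural log.
The bin count is exposed because absolute plug-in MI levels depend on
it; conclusions should rest on comparisons under a fixed binning, and
with ~50-patch slides the estimator's upward bias for independent
scores is about `1/(2N) ≈ 0.01` nats. Spearman is the Pearson
correlation of mid-ranks (average-rank ties), 0 with a warning when
either ranking is constant. AUPRC is average precision over
descending-score thresholds; slides whose labels are single-class after
ROI filtering are undefined and handled explicitly. All three metrics
are invariant to strictly increasing score transforms. Score sets with
>99% of mass on <1% of patches are flagged degenerate but evaluated
identically.

ROI-free slides are excluded before aggregation. The default
aggregation computes each metric within each retained slide and
averages (`per_slide_mean`); `pooled` concatenates patches first. The
per-slide default weights every annotated slide equally regardless of
size; published descriptions do not state the pooling level, so both are
implemented.

## Synthetic data

Each bag lives on a `grid_side²` lattice of 256 px cells. Background
instances are drawn from N(0, σ²I); a positive bag of class `c` plants
`round(ρ·N)` key instances from N(μ_c, σ²I) with `‖μ_c‖ = δ` (distinct
axes per tumor class), occupying a compact rectangular block of the
lattice; the emitted polygon covers exactly that block, so
annotation-derived labels reproduce the planted ones (asserted). A
`scattered` mode breaks spatial contiguity for stress tests. Defaults:
δ = 6, ρ = 0.2, σ = 1, d = 1024, N ∈ [32, 64], 200 bags per class with a
seeded, stratified 60/15/25 split. The bag count emulates the
few-hundred-slide training sets of the public WSI benchmarks so the
fixed 50-epoch protocol performs a comparable number of optimizer steps
(~12k); the bag size is kept below real-slide patch counts to make
repeated multi-seed training tractable on one CPU core. At δ = 6 the
instance-level Bayes error is Φ(−3) ≈ 0.13%, i.e. keys are nearly
separable given converged weights.

What the generator deliberately does not model: staining and scanner
artifacts, spatially correlated background texture, class-correlated
but non-ROI tissue (e.g. lymphoid background), or pixel-level images.
Passing synthetic tests therefore demonstrates the correctness of the
pipeline and the *attainability* of reliable localization under clean
conditions — not performance on real slides.

One consequence is worth stating explicitly. On this clean generator the
only class-discriminative feature direction is the planted key shift, so
any max-pooling classifier that reaches high slide AUC must align its
weights with that direction — and its selection channel then becomes
partially informative (five-seed means at the defaults: MI ≈ 0.05,
AUPRC ≈ 0.57 at prevalence 0.20, versus 0.15 / 0.91 for instance-level
mean pooling). The *relative* contrast — instance-level mean pooling far
more reliable than max pooling — reproduces robustly, but the *absolute*
unreliability of max pooling reported on real data (MI ≈ 0) does not: on
real slides max pooling can exploit artifact-like features that this
generator excludes by design. At smaller training scales (≤6k steps)
max pooling's selection channel does stay at chance level (MI ≤ 0.01),
but there the instance-level model is undertrained; no training scale
satisfies both extremes simultaneously on this generator.

## Cross-dataset reporting

Overall tables average each model family's per-dataset means with equal
dataset weight, rounding half-up to two decimals (nearest unit for the
K/M columns) — this reproduces the published overall cells checked in
the tests. Reliability rankings sum the selected metrics across datasets
with equal weight; scores tied after rounding to two decimals are
reported as ties. Excluding one metric perturbs only the totals, never
the per-dataset cells. A transcription of the published per-dataset
means ships as `milrel/data/published_means.csv` so this arithmetic is
testable without training. A generic one-way repeated-measures ANOVA
(models as the within factor, datasets as subjects) is provided for
model comparison, cross-checked against `pingouin`; degenerate inputs
(zero error sum of squares) raise rather than report an undefined F.

## Known limitations

* The CLAM / ACMIL / DTFD variants implement the published architectural
  ideas in simplified form (auxiliary-loss weights and schedules beyond
  the shared protocol are not reverse-engineered); they are labeled
  `*_lite` accordingly where applicable.
* Absolute plug-in MI values depend on the binning choice and are not
  comparable across estimators.
* CPU-only; bags with many thousands of instances will train slowly.
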