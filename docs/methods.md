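# Methods

This note records the models implemented, the parameter choices that
matter, the numerical conventions, and what the synthetic fixtures do
and do not demonstrate.

## Equilibrium Optimizer

`histovote.eo` implements EO as a generic bounded **maximizer**
(minimize by negating the objective). Each generation evaluates the
population, builds the equilibrium pool — the four fittest candidates
plus their coordinate-wise mean, ties broken by lower candidate index
for reproducibility — and updates every candidate toward a uniformly
drawn pool member:

```
C_new = Ceq + (C - Ceq) * F + G / (lam * V) * (1 - F)
t     = (1 - it/T) ** (a2 * it/T)
F     = a1 * sign(r - 0.5) * (exp(-lam * t) - 1)
G     = GCP * (Ceq - lam * C) * F,   GCP = 0.5 * r1 if r2 >= GP else 0
```

with `lam` and `r` fresh uniform(0,1) draws **per coordinate** and
`r1, r2` uniform scalars per candidate. Defaults follow the canonical
EO formulation: `a1 = 2`, `a2 = 1`, `GP = 0.5`, `V = 1`, population 30,
1000 iterations. Numerical conventions:

* `lam` is floored at 1e-12 so the `G/(lam V)` term never divides by zero;
* positions leaving the box are **clamped** (weights must stay in
  [0, 1]; reflection or resampling would serve equally, clamping is the
  simplest deterministic rule);
* the best candidate ever seen is tracked outside the population
  (elitism), so the per-iteration best-so-far trace is monotone
  non-decreasing and a lucky evaluation is never lost;
* an objective that raises is re-raised with the offending position
  attached.

Per-coordinate (rather than per-particle) randomness in `lam`/`r`
follows common vectorized EO practice; nothing in the package depends on
that choice beyond reproducibility of seeded runs.

## Ensemble weight search

Weighted soft voting fuses per-model probability matrices as a convex
combination and takes the per-row argmax, ties broken by lowest class
index everywhere. The EO fitness is plain accuracy of the fused argmax
against ground truth. The raw search space is the box `[0,1]^M` with
post-hoc normalization onto the simplex — matching EO's box-bounded
formulation — rather than a constrained simplex walk; an all-zero raw
vector is scored as the uniform weighting.

The initial population is warm-started with the `M` degenerate
one-model vectors plus the uniform vector. These are ordinary feasible
points, so EO's dynamics are unchanged, but combined with elitism they
guarantee the returned fitness never falls below any single model's
accuracy or plain average voting — the property a weight search must
have for its result to be meaningful.

Which predictions feed the fitness is deliberately the caller's choice:
optimizing weights on the final test set would leak, so the library
takes an explicit fitness set and the CLI is pointed at whatever
prediction CSVs the user supplies (validation-set predictions in the
intended workflow).

Weights are reported rounded to two decimals in logs and at full
precision in files.

## The custom CNN family

`histovote.nn` describes models declaratively (`BlockSpec`,
`StageSpec`, `ModelSpec`) and builds them into graphs with a NumPy
inference engine: forward pass, structural summary, and exact
trainable-parameter count. There is deliberately no gradient training
in this package — no deep-learning framework is a dependency — the
builders exist to make the architecture family concrete, checkable, and
countable. The CLI's `train` command instead fits a compact
scikit-learn multinomial logistic baseline on standardized pixels
(using the inverse-frequency class weights), which is enough to drive
the full simulate → split → train → predict → ensemble-fit → evaluate
composition on fixtures.

Structural conventions, chosen where the family's description is open:

* A block is `[1x1 conv + BN + ReLU]` (when a pointwise bottleneck is
  specified) → `3x3 conv, same padding + BN + ReLU` → channel attention
  → spatial attention. Stage-1 blocks (Block A) have no pointwise stage
  and are single-convolution blocks.
* Max pooling (2×2, stride 2) sits after each **stage**, not after each
  block instance — six stages of halving take 224 px down to 7 px,
  which is the only reading compatible with the family's depth.
* Concatenation links (when `residual_concat` is on) act **within a
  stage, from the second stage onward**: block *k* receives
  `concat(output_{k-1}, input_{k-1})` along channels, and the links
  reset at each pooling boundary, where shapes would otherwise clash.
  Only the two deepest presets (C19, C20/MultiHisNet) and the residual
  models C8–C10 switch this on.
* Attention follows the CBAM formulation: the channel branch is a
  shared two-layer bottleneck (reduction ratio 16, clipped to the
  channel count) applied to global-average- and global-max-pooled
  descriptors, summed and squashed with a sigmoid; the spatial branch
  is a 7×7 convolution over the stacked channel-wise average and max
  maps. Channel first, then spatial, inside every block instance.
* Heads: global average pooling (flatten for C1) → dense stack with
  ReLU, dropout after the first dense layer → softmax. The
  transfer-learning head is dense 512 → dense 256 → dropout 0.2 →
  softmax 8. Batch normalization and dropout run in inference mode;
  parameter counts include each BN layer's scale and shift.
* One structural ambiguity is worth flagging: the family's prose
  describes blocks as two-convolution units, which cannot hold for
  stage 1 under any reading consistent with the per-stage filter grid;
  the single-convolution Block A with two instances is our resolution,
  and it reproduces the 28-block census (2+2+4+4+10+6) of the deepest
  preset.

MultiHisNet (preset id C20) builds with ~31 M trainable parameters; a
batch-2 forward pass at 224 px takes a few seconds on one CPU, and the
structural tests run it once.

## Data pipeline

* Fixed category order `(A, DC, F, LC, MC, PC, PT, TA)`; directory
  names may be short codes or full tumor names, and the nested
  `<class>/<patient>/<magnification>/` layout is parsed with
  magnification tags kept. All magnifications are pooled
  (magnification-independent setting).
* Splits are stratified per class at the **image** level: exactly
  `round_half_away_from_zero(fraction × N_class)` records go to
  training, the rest to test; the validation carve-out applies the same
  per-class rule to the training records. Image-level splitting matches
  the reference protocol; it does not prevent patient-level leakage,
  which a leakage-aware user should handle by grouping on the parsed
  patient tags.
* Class weights use training counts (the weights act on the training
  loss; whole-dataset counts give the same two-decimal values on the
  reference census).
* Evaluation: confusion matrix with rows = true labels, columns =
  predicted; precision/recall per class with 0/0 defined as 0; macro
  averaging so rare subtypes count equally; F1 is the per-class
  harmonic mean before averaging.
* Augmentation is independent 50 % horizontal and vertical flips,
  training only; standardization is bilinear resize to 224 px and
  scaling to [0, 1].

## Synthetic fixtures

The image generator renders procedurally simple textures (class-specific
base color, stripe orientation/frequency, dark blobs, Gaussian noise)
into the directory layout the pipeline indexes, with per-class counts
defaulting to the BreakHis census scaled by 0.02 (9, 69, 20, 13, 16,
11, 9, 11). Each class has a distinct base color, so the fixtures are
learnable by construction — a nearest-centroid color rule beats chance
— but they carry none of the stain variation, patient structure, or
intra-class similarity of real histopathology. Tests passing on them
validate the machinery (indexing, splitting, weighting, fusion,
optimization), not clinical performance.

The prediction generator draws truth labels from the archive's
test-partition proportions (so imbalance exercises the macro metrics),
emits each model's label correctly with a per-class probability, and
builds probability rows by placing a Beta-distributed mass (support
(1/K, 1), sharpness set by the profile's confidence for the *emitted*
class) on the emitted label, spreading the rest with a flat Dirichlet
draw rescaled so the emitted label stays the argmax — hence empirical
accuracies converge exactly to the profiles. Confidence may vary per
class, which is how the `complementary_trio` preset encodes a
well-calibrated specialist (diffuse off its specialty) next to two
overconfident models: under equal weights the overconfident models
override the specialist, so uniform averaging is strictly suboptimal
and the weight search has a real optimum to find. The
`planted_dominant` preset places one near-perfect model beside two
label-noise models, making the optimal weights near-degenerate; weight
recovery to ≥ 0.9 mass on the dominant model is the package's
parameter-recovery check.

## Problem sizes and scope

Test and demonstration runs use 200–500-sample fitness sets, EO runs of
60–300 iterations (population 30), and 1001-point or step-0.01 simplex
grid oracles; these sizes make every check exhaustive or replicable on
one CPU in seconds while remaining well inside the regime where EO at
the full published settings (population 30, 1000 iterations) behaves
identically. Fitting the CNN family to the real BreakHis archive — and
therefore its published per-model and ensemble test accuracies and the
specific fitted weight triple — requires the external dataset and
GPU-scale training and is explicitly out of scope; the grid-oracle,
baseline-domination, structural-census, and parameter-recovery checks
above are the desk-scale substitutes.
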