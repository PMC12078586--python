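# Methods

## Continuous GGO

The optimizer maintains `n` agents in a bounded box and minimizes the
objective. State per iteration `t` (0-based, `t_max` iterations):

- `a(t) = a_start + (a_end − a_start)·t/t_max`, default 2 → 0, linear.
- `z(t) = 1 − (t/t_max)²`, the exploration decay weight.
- `r1_sched(t) = c·(1 − t/t_max)` is kept as an exported diagnostic
  schedule; the `r1` inside `A = 2a·r1 − a` is an independent uniform
  draw per dimension on every update. Both quantities exist in the
  method's lineage under the same name; they are deliberately separate
  here, with the scheduled one used only for traces.

Group dynamics: the population starts split evenly
(`n1 = ⌊n/2⌋`). Each iteration one agent moves from exploration to
exploitation (floor `min_group_size = 1`); when the leader's fitness
has not improved for `stagnation_threshold = 3` consecutive
iterations the move reverses and the counter resets. Group membership
is reshuffled uniformly after every resize, so the group sizes — not
fixed agent identities — carry the exploration/exploitation balance.

Strategy gates (the method's prose names the strategies but not their
precedence; these gates are this implementation's documented choice):

- Exploration, per agent: draw `r3 ∈ [0,1]`; if `r3 ≥ 0.5` use the
  spiral update; else if the mean of `|A|` is ≥ 1 use the
  three-paddling blend (the classic large-`|A|` diversification
  switch); else encircle the leader.
- Exploitation, per agent: fair coin between the sentry update and the
  flock local search.
- Sentries are the three best solutions by current fitness with the
  elitist leader included as a candidate; each sentry gets fresh
  `A_i = 2a·r1 − a`, `C_i = 2·r2` draws and the three candidate
  positions are combined by arithmetic mean (the standard three-leader
  aggregation).
- The flock reference is the best exploitation-group agent other than
  the one being updated (falling back to the leader when the group has
  no other member). The step factor `D` is an independent uniform
  [0, 1] draw per dimension, giving a bounded, dimensionally consistent
  local step.

Elitism and mutation: the best-ever solution is archived as the leader
and can only be replaced by a strictly better one, so the best-so-far
trace is non-increasing by construction. After its strategy move each
agent (except the current best) has each component redrawn uniformly
within bounds with probability `mutation_rate = 0.05`. Positions are
clipped to the box after every move. All draws come from one seeded
`numpy` generator in a fixed order, so a run is bit-reproducible from
`(objective, config)`.

Fitness ties are broken by lowest agent index (`argmin` order).

## Binary GGO and the wrapper fitness

Feature selection searches `[0,1]^D` with the continuous machinery;
before every evaluation a position is binarized by the steep sigmoid
`1/(1 + e^{−10(m−0.5)})` thresholded at 0.5 (equivalently `m ≥ 0.5`,
boundary inclusive). The mask fitness is
`α·Err + (1 − α)·|s|/D` with `α = 0.99`: the error term must dominate
for classification-driven selection, while the small size term breaks
ties toward compact subsets. An all-zero mask is assigned the
worst-case error (`Err = 1`) instead of raising, keeping the search
total. Mask fitnesses are memoized within a run — binarization maps
many positions onto few masks, so repeated masks cost nothing.

`Err` is the error of a 1-nearest-neighbour classifier (Euclidean
distance on the selected, z-scored columns). When no explicit
partition is supplied, a stratified 80/20 train/validation split
seeded by the run seed is created; z-scoring uses training-split
statistics only. The 1-NN inside the wrapper is computed directly from
a distance matrix; a test cross-checks it against scikit-learn's
1-NN classifier.

Repeated-run statistics (M runs, default 10): average error at the
best mask, average relative subset size `|s|/D`, and best (min), worst
(max), mean and sample standard deviation (denominator M − 1) of the
run fitnesses.

## Image preparation

All stages act on 8-bit grayscale in [0, 255] (L = 256 levels) and are
deterministic. The chain order is: resize → frequency-domain
high-pass → histogram equalization → unsharp sharpening. Resizing
first makes every later stage operate at the model input size, so
stage outputs are comparable and cheap.

- Resize: bilinear to `side × side` (default 224); a same-size input
  passes through unchanged.
- High-pass: Gaussian transfer `H(u,v) = 1 − exp(−D²/(2·D0²))` in the
  2-D FFT domain with `D0 = cutoff·side`, default cutoff 0.05, output
  rescaled linearly to [0, 255]. This emphasizes trabecular-bone-like
  texture; a constant image (no AC energy) stays constant.
- Equalization: `s_k = round((L−1)·CDF(k))` with rounding
  `floor(x + 0.5)`. The mapping is monotone and idempotent up to one
  intensity level.
- Sharpening: unsharp mask `clip(in + λ·(in − blur(in)))` with a 3×3
  Gaussian blur (σ = 1) and λ = 1.
- Color inputs are converted by luminance weights 0.299/0.587/0.114.

Rebalancing: within each split independently, every image of the
minority class is duplicated once as its horizontal mirror; the
majority class is untouched and nothing is deleted. Starting from the
published per-split counts (train 810/1540, validation 210/430, test
569/276, total 3835) this reproduces 1620 train-normal, 420
validation-normal and 552 test-osteoarthritis images. The computed
post-augmentation totals are 2609 normal and 2522 osteoarthritis
(grand total 5131); the source tables print 2523 and 5132 for the last
two — their own split sums give 2522/5131, so the implementation
reports the computed sums. Random equal-subsampling is available as an
optional alternative but is not the default.

Texture descriptor (a deliberately simple, deterministic stand-in for
large pretrained feature extractors, which are out of scope): the
image is tiled into `grid × grid` blocks (default 4, so 48 features)
and the vector concatenates all block means, then block standard
deviations, then block mean gradient magnitudes (gradient computed on
the full image). Block means are shift-equivariant; SD and gradient
features are shift-invariant.

## Classification and tuning

Learners: 1-NN, a decision tree, and a small MLP (one hidden layer,
default 16 units), all via scikit-learn with seeded initialization.
Metrics from the confusion counts with osteoarthritis as the positive
class by default: accuracy, sensitivity TP/(TP+FN), specificity
TN/(TN+FP), PPV, NPV, F1 = 2TP/(2TP+FP+FN). Specificity is computed
from the negatives — a widely circulated table typo repeats the
sensitivity formula for it, which is not followed here. Zero-denominator
metrics are reported as NaN with a warning, never silently as 0.

Hyperparameter tuning encodes each parameter on [0, 1] (linear map for
continuous, rounded for integer, index-snapped for categorical) and
minimizes validation error with the continuous optimizer. The deep-CNN
path is represented by the MLP at desk scale; the classifier interface
takes any hyperparameter assignment, so an external model can be wired
in without changing the module.

## Synthetic data

Feature tables: two balanced classes, `k` informative columns with
class-conditional means `∓/± effect/2` in units of the noise SD, all
other columns class-independent noise. `effect = 6` (the default used
in the oracle studies) makes a single informative column essentially
fully separating, so the expected global optimum is a 1-column mask;
`effect = 0` yields chance-level 1-NN error. The generator returns the
ground-truth mask.

Knee images: two bright granular bands (mean 170, texture grain SD 20)
separated by a dark gap (mean 40) whose width is drawn from
`Normal(gap_mean, gap_sd)`; `gap_mean` defaults to 0.14·side for the
normal class and 0.06·side for osteoarthritis (`gap_sd = 0.02·side`),
with a small vertical jitter. The measured gap is defined
operationally as the longest run of pixels darker than 100 in the
centre column. These images emulate exactly one discriminative
property — joint-space narrowing plus texture — and none of the
anatomy, projection geometry, exposure variation or label noise of
real radiographs; passing tests show the pipeline recovers a planted
signal, not that it grades real knees.

## Pipeline

`run_pipeline` chains synthesize/ingest → preprocess → rebalance →
extract → select → classify and reports a before/after-selection
metric block on the held-out test split. The global seed fans out to
stages by fixed offsets so stages can be rerun in isolation; the run
is a pure function of (config, seed). The wrapper's validation set is
the pipeline's own validation split (standardized by training-split
statistics): wrapper selection over ~50 features needs an adequately
sized independent validation set, and re-splitting the training data
would both shrink it and correlate it with training. The default
synthetic study uses 160 train / 52 validation / 100 test images at
side 64 with a 12-agent, 30-iteration selection budget — small enough
to run in seconds, large enough that accuracy is estimated on a
percent grid. Timings and library versions go to a separate metadata
file so the data outputs are byte-stable.

## Known limitations

- The exploration/exploitation gates, the sentry aggregation, the
  flock step factor `D`, the mutation operator and the group-resize
  rate are documented implementation choices where the method's
  description is silent or ambiguous; other choices would yield a
  different (still valid) member of the same algorithm family.
- The wrapper's 80/20 single split makes the selected mask noisy on
  small tables; cross-validated error estimation would be steadier but
  is not part of the specified estimator.
- The texture descriptor is far weaker than learned deep features; the
  pipeline's absolute accuracies on synthetic images say nothing about
  accuracy on clinical data.
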