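# Methods

## Model

The classifier is a dropout-regularised convolutional network with two
output heads. The trunk is a compact residual CNN: a 3×3 stem convolution
with batch normalisation and ReLU, followed by one stride-2 residual block
per additional width entry (each block: conv–BN–ReLU–conv–BN plus a 1×1
projected skip, then ReLU), ending in global average pooling. The pooled
features feed two parallel fully connected layers of 32 units, each with
dropout at rate 0.5, into an *auxiliary* and a *final* M-way softmax. The
trunk width/depth is configurable (`ModelConfig.filters`); the default
input resolution is 128×128×3, the only resolution meaningful for
segmentation tiles, with bilinear resizing applied to tiles of any other
size. The implementation is pure NumPy — im2col convolution, hand-written
backward passes, Adam — so everything the package does is inspectable and
dependency-light.

Training minimises the weighted categorical cross-entropy
0.9·CE(final) + 0.1·CE(aux) in nats, with probabilities clamped at 1e-12
so losses stay finite. The auxiliary head acts purely as a training
regulariser; all predictions come from the final head. Optimisation uses
Adam (initial rate 1e-3, exposed in `TrainConfig`), training batches of 32
and evaluation batches of 128. A stratified validation split (fraction 0.1
by default, 0.3 in active-learning mode where the labelled set starts very
small) monitors accuracy; whenever it fails to improve for `lr_patience`
(default 5) consecutive epochs, the learning rate is multiplied by 0.1.
The patience value and initial rate are conventional defaults, deliberately
configurable because no canonical value exists for them.

## Uncertainty

At prediction time batch-norm statistics are frozen and dropout masks on
the two 32-unit layers are the only stochastic element. T stochastic
passes (default 50) give a T×M row-stochastic matrix; its row average
approximates the predictive distribution. Entropy H is the Shannon entropy
of that average (0·ln 0 := 0); BALD is H minus the mean per-pass entropy,
clipped at zero because floating-point cancellation can leave a ~−1e−16
residue on a provably non-negative mutual information. Both are reported
in nats, along with H/ln M, since rules of thumb like "H below 0.2 is very
certain" are otherwise scale-ambiguous. Because the trunk is deterministic
in prediction mode, its features are computed once per tile and only the
heads are resampled T times — an exact optimisation that makes MC scoring
cheap. Each tile draws its masks from its own seeded substream, so scores
are independent of batch composition. Ties in the argmax classification go
to the lowest class index.

## Active learning

The loop starts from a stratified seed of `seed_per_class` tiles per class
(default 40), trains, scores the remaining pool, moves the `step_size`
(default 160) highest-uncertainty tiles (descending H or BALD; uniform
random as baseline; ties by lexicographic id) into the labelled set, and
retrains from the same fresh initialisation seed — no fine-tuning, so each
step is an independent training on a grown set. Steps are 0-indexed with
step 0 the seed training; the labelled size at step s is
min(M·seed_per_class + s·step_size, pool); the last step may be partial
(an 8-class pool of 4496 yields 28 steps, 0..27, ending 320 + 26·160 + 16).
The harness pairs strategies: the same splits and the same
pre-initialisation seeds are reused for every strategy, and per-step
accuracies are averaged over `n_splits` × `n_inits` runs. The summary
statistic is the area under the accuracy-vs-size curve normalised by the
size span (the schedule-mean accuracy).

## Mislabel detection

Given the expected mislabelled percentage p_m, the detector computes for
each assigned class c the p_m-th percentile of that class's empirical H
values — linear interpolation between closest ranks with inclusive
endpoints (`numpy.percentile(method="linear")`), a choice fixed and
oracle-tested because several percentile conventions exist — and flags
every tile misclassified with H strictly below its class threshold
("below" read literally; a tile exactly at the class maximum is excluded
even at p_m = 100). The candidate set is the union over classes; it nests
monotonically as p_m grows. The benchmark plants noise by relabelling
round(p_m/100·N) tiles uniformly to one of the other M−1 classes (the
label always actually changes) and scores the detector with
sensitivity = |planted ∩ candidates|/|candidates| and
specificity = |clean ∩ non-candidates|/|non-candidates|. This
"sensitivity" is a precision; the definition is kept for comparability
with the protocol it mirrors, and standard recall is reported alongside.
In the benchmark the same p_m drives planting and detection; in normal use
the detector takes a user-supplied p_m.

## Segmentation

A slide is cut into non-overlapping square tiles in row-major order,
half-open pixel boxes [r·t,(r+1)·t)×[c·t,(c+1)·t); partial edge tiles are
dropped rather than padded (the 5000/50 reference geometry divides
exactly, so the edge case is unconstrained — dropping avoids fabricating
border content). Each tile is bilinearly upscaled to the model input and
classified by the argmax of its T-sample predictive mean; per-tile H is
recorded but never consulted for the class decision, and the class grid is
bit-identical with uncertainty computation on or off. Rendering paints
each tile its catalog colour and applies a per-channel Gaussian blur,
sigma defaulting to tile_size/4 — a cosmetic choice: class surface-area
percentages are always computed from the unblurred grid, sum to 100 by
construction, and report 0 for absent classes.

## Evaluation

Error rate is the misclassified fraction. Multi-class scores are evaluated
one-vs-all: class c's probability column against the indicator truth = c,
ROC AUC by trapezoidal integration and precision-recall area by the
step-wise (non-interpolated) convention, i.e. average precision; the
convention is recorded in the result metadata because interpolated PR
areas are systematically higher. Mean AUCs are unweighted over classes;
classes absent from the truth are skipped with a warning. These standard
curve computations delegate to scikit-learn; the test suite checks ROC AUC
against an independent Mann–Whitney pair-counting oracle.
`cross_validate` trains and evaluates on k seeded stratified holdout
splits. Per-class test counts use ceiling rounding, ⌈n_c/k⌉ — with 625
tiles per class and k = 10 this reproduces the canonical 504/4496 (and,
restricted to two classes, 126/1124) divisions — and repeated "folds" are
independent seeded draws rather than a strict partition, since a strict
partition is incompatible with those printed test sizes.

## Synthetic data

The generator stands in for stained-tissue tiles everywhere in the tests.
Each class renders an oriented sinusoidal grating (frequency 3 + 1.5·c
cycles/tile, orientation 180°·c/M) interpolating two class-specific
colours, plus a smooth Gaussian blob field and per-pixel noise (sd 10 of
255 by default) — cheap, learnable by tiny CNNs, with tunable difficulty.
A *confusability* dial blends the generative parameters of a designated
pair toward their midpoint, shrinking the pair's parameter separation by
the factor (1 − confusability): at 1 the two distributions coincide and
the residual uncertainty is purely aleatoric, emulating intrinsically
ambiguous tissue pairs. One master seed spawns an independent substream
per patch, so generation is order-independent; ids encode class, seed and
index. Composite slides are rectangular-region layouts validated to tile
the canvas exactly, each region filled with its class texture over a known
pixel mask.

What the generator does *not* emulate: stain variation, nuclear
morphology, spatial correlation between neighbouring tiles, class
imbalance, and annotation ambiguity beyond the single confusable pair.
Passing the reduced-scale benchmarks therefore demonstrates that the
machinery — training, MC uncertainty, acquisition, detection, segmentation
— behaves as specified, not that the headline accuracies on real stained
tissue are reproduced.

## Reduced-scale study conditions

All stochastic benchmarks (test suite and `scripts/acceptance.py`) run at
a scale chosen so every training finishes in seconds on one CPU, while
keeping the full pipeline intact: 16×16 px tiles, M = 4 classes, trunk
widths (8, 16, 32) (~21k parameters), T = 16 MC samples.

* Convergence / mislabel benchmark: 80 tiles per class for training, 30
  per class held out, 25 epochs; noise rates p_m ∈ {0, 10, 30, 50};
  3 seeds.
* Active learning: pool of 75 tiles per class with the (2,3) pair at
  confusability 0.95 (the regime with real learning-curve headroom),
  seed 10/class, step 50, 18 epochs per step, 2 initialisations × 1 split,
  3 dataset seeds, paired between strategies.
* Segmentation: 256×256 checkerboard slides at 64 px tiles with a
  mean-colour oracle classifier for exact area recovery, and trained
  models on 160×160 slides for end-to-end checks.

## Known limitations

The exact reference network topology is not public; the trunk here is the
package's own compact residual design preserving the stated structural
properties (batch norm, residual connections, dropout 0.5 on two 32-unit
FC layers, dual heads). Pure-NumPy training is single-threaded BLAS-bound
and not meant for 150×150 tiles at full dataset scale. BALD acquisition is
implemented and tested for correctness, but the reduced-scale benchmark
only asserts the entropy-vs-random ordering, the one robust at this scale.
Pyramidal WSI formats, stain normalisation and sub-tile segmentation are
out of scope.
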