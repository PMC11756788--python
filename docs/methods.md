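# Methods

This note documents the models and procedures `irdhs` implements, the
assumptions behind them, the synthetic data used to exercise them, and the
numerical and design choices a maintainer would want written down.

## Problem and data model

The unit of analysis is a DNase I hypersensitive site (DHS): a 600 bp window
of open chromatin lying inside a gene. A DHS is labeled **IR** when it
overlaps an intron subject to intron retention, **non-IR** otherwise.
Coordinates follow the BED convention (0-based, half-open); the overlap of
[a, b) and [c, d) is max(0, min(b, d) − max(a, c)).

Two labeling phases mirror how such datasets are assembled. Introns called
retained in genome annotations label a DHS IR on *any* overlap
(`min_overlap=1`; the annotation is positional truth, and a 1 bp rule is the
most permissive reading of "overlaps" — the threshold is a config key, so
stricter choices are one argument away). Retained introns detected in
RNA-seq are noisier, so a negative flips to IR only when the overlap reaches
**500 bp**, and new DHSs enter under the same rule. Relabeling never flips
IR back to non-IR, and the event bookkeeping (`DatasetSummary`) makes the
arithmetic auditable: totals are annotation events plus RNA-seq additions,
relabels conserve the total, and reverse-complement augmentation doubles
every count.

Redundancy control: sequences are clustered greedily at **80% identity** —
longest first (ties lexicographic, for determinism), each sequence joining
the first cluster whose founder it matches. Identity is the best ungapped
alignment of the shorter sequence at any offset inside the longer, on either
strand, scored as matches / length(shorter). This reproduces the threshold
semantics of the word-filter clustering tools used on real data without an
external binary; a precomputed cluster assignment can be passed straight to
`split_dataset` if an external tool is preferred. Whole clusters are
assigned to train/validation/test (80/10/10 target fractions, seeded cluster
shuffle, largest-deficit-first assignment), so no test sequence has a
≥80%-identical relative in training — verified by brute force in the tests.

Augmentation doubles the dataset with reverse complements, originals first.
The default augments whatever it is given; augmenting only the training
portion (by calling it on that split alone) avoids evaluating on mirror
images of test sequences, which is what the worked example and the test
suite do.

One-hot encoding is a 4 × N matrix, rows A, C, G, T; `N` bases give an
all-zero column, chosen so ambiguous positions contribute nothing to
convolution activations and are never eligible as attribution hot spots.

## Models

All sequence models consume (batch, 4, length) arrays and output a
probability; all are built on the package's own numpy layer engine with
hand-written backpropagation (finite-difference checked to ~1e-10), because
the interpretation stage needs exact gradients with respect to the input
one-hot matrix.

**BassetClassifier** — three convolution → batch-norm → ReLU → max-pool
stages, then three dense layers ending in a sigmoid unit. Desk-scale
defaults: 64/32/32 filters, kernels 15/6/6, pooling 3/1/global (a pool size
of −1 pools whatever length remains; a pool size of 1 is skipped). The wide
first layer and the late, global max-pool are deliberate: at a few thousand
training sequences, gradient signal must reach the first-layer filters
before the dense head can memorise, and heavy intermediate pooling was
observed to prevent exactly that.

**BasenjiClassifier** — a linear convolutional stem; six conv blocks
(defaults; the count is a parameter), each a **dual-path** unit summing a
linear convolution with a batch-normalised GELU convolution of the same
input, with optional max-pooling per block; three residual dilated
convolution blocks whose dilation doubles per block (2, 4, 8); then the
fine-tuning head. The dual-path form gives every block a direct gradient
route from output to stem, which is what makes the tower trainable at small
sample sizes.

**FinetunedSequenceClassifier** — a convolutional backbone behind a small
contract (`build()` returning a module mapping one-hot input to a feature
map, plus `out_channels`/`downsample`/`receptive_field` metadata) with a
binary head on top. `head='block'` appends the fine-tuning block:
convolution → attention pooling → dense → sigmoid. Attention pooling scores
each position with a learned linear map, softmaxes over positions, and
returns the attention-weighted average feature vector; on
position-constant features it reduces to mean pooling (tested).
`head='linear'` merely replaces the classification layer (mean-pool →
one sigmoid unit). `freeze_backbone=True` makes backbone parameters
non-trainable *and* pins its batch-norm statistics, so frozen means
bit-identical. The default backbone is a two-conv miniature; a full
pre-trained chromatin model slots in behind the same contract but is not
shipped.

**LogisticTargetsClassifier** — logistic regression over an
(n_samples × n_targets) matrix of chromatin-state target scores in [0, 1],
with per-target metadata assigning each target to TF / histone-mark /
accessibility groups (`subset_targets` selects a group; counts always come
from the metadata, never from constants, because published group totals
disagree by small amounts between sources). Trained with the package
protocol — BCE, AdamW whose decoupled decay doubles as the weak L2
(default 1e-4) that stabilises the weights used for ranking, warmup+cosine
schedule, early stopping, and the class-balanced sampler, since IR labels
are ~1:3 imbalanced in the motivating data. `coef_` feeds
`rank_lr_targets`, which ranks targets by signed weight; because one protein
is often assayed as several targets, the table keeps protein identity so
the top-k ∩ bottom-k protein intersection can be reported.

**GBDTTargetsClassifier** — LightGBM at the reference settings
(1000 trees, unbounded depth, 50 leaves, bagging_freq 1, imbalanced mode);
`feature_importances_` provides the alternative target ranking.

## Training protocol

Mean binary cross-entropy with probabilities clipped at 1e-7. The learning
rate rises linearly from `warmup_begin_lr` to `max_lr` over `warmup_steps`
*optimizer steps* (step, not epoch, granularity — the parameter names imply
it), then follows a cosine to `final_lr` at `total_steps`. Early stopping
halts after `patience` epochs without a strict validation-loss improvement
(`min_delta` 0 by default; ties do not count), and the best epoch's
parameters **and batch-norm statistics** are restored on exit — restoring
only parameters silently pairs old weights with late running statistics,
which was a real bug caught during development. The class-balanced sampler
draws indices with replacement, per-class probability inversely proportional
to class frequency, giving a 50/50 expected batch mix. Gradients are clipped
to a global L2 norm of 5 before each step; with momentum 0.95 and batch
norm, unclipped steps occasionally collapsed a network irrecoverably.
Divergence (NaN loss) aborts with a diagnostic rather than continuing.
Every source of randomness — batch order, sampler, initialisation — derives
from the seed, so a fit is reproducible run-to-run.

Optimizer defaults: AdamW at max_lr 5e-3 (the from-scratch setting), with
SGD + momentum 0.95 — the classical fine-tuning choice — available as
`optimizer="sgd_momentum"`. Two further choices matter at desk scale: the
final dense layer is initialised near zero so training starts at chance loss
(max-pooled normalised features carry a large common offset that would
otherwise start the sigmoid saturated), and Table-style budgets
(max 100 epochs / patience 10 for sequence models, 1000 / 50 for the
logistic model) are the defaults while tests and the acceptance script use
explicit smaller epoch counts.

## Evaluation

AUROC integrates the ROC curve by the trapezoidal rule with tied scores
grouped, which equals the Mann-Whitney pair statistic (wins + half-ties) —
asserted against exhaustive pair enumeration in the tests. AUPRC uses the
step-wise right-continuous rule (the average-precision estimator);
trapezoidal interpolation in PR space is biased upward and is deliberately
not used. Constant scores give AUPRC equal to prevalence; both areas are
invariant under strictly monotone score transforms; flipping labels maps
AUROC to 1 − AUROC. Curve construction is delegated to scikit-learn's
threshold sweeps.

## Interpretation

Integrated Gradients with an all-zeros baseline (the conventional
"no sequence" reference for one-hot inputs) and a right-Riemann
approximation over `m` steps, evaluated in one batched forward/backward
pass; the completeness axiom |ΣIG − (f(x) − f(baseline))| is verified to
shrink with `m` and to be <1% of the output gap at 200 steps on a trained
CNN. On a linear model the implementation equals w ⊙ (x − baseline) exactly.

Sequences enter interpretation only when the model predicts their true class
with probability above 0.7 (symmetric: non-IR kept when 1 − p > 0.7). Hot
spots are positions whose attribution *at the observed base* exceeds 70% of
the per-sequence maximum. Signed attributions are the default — the rule is
applied exactly as stated, so a sequence whose attributions are all
non-positive yields no hot spots — with `use_abs=True` available for
magnitude-based selection. N positions are never hot spots.

A hot spot carries a motif when *any* window of the motif's length covering
the position, on either strand, has log-odds score ≥ 80% of that motif's
maximum achievable score (the most permissive window reading; windows
crossing the sequence boundary are skipped). PWMs come from JASPAR count
files via biopython with a pseudocount of 0.01 per cell and a uniform
background by default. Per motif, the enrichment score is the fraction of IR
hot spots carrying it minus the fraction of non-IR hot spots carrying it
(range [−1, 1]); ranking is by score, ties broken by motif id. Significance
is a one-sided permutation test shuffling hot-spot class labels, with the
+1 correction, whose null is centred at zero (tested).

## Synthetic data: what it does and does not show

Three generators replace the genome-scale inputs, each with a fixed RNG
stream derived from the seed (`SeedSequence(seed, spawn_key=(k,))`, k = 0
annotation / 1 sequences / 2 targets), so identical configs give
byte-identical files and arrays.

`simulate_annotation` builds one chromosome of intronic intervals with one
600 bp DHS per intron; introns hosting the first n_ir DHSs (in shuffled
order) are marked retained. It exercises interval arithmetic, labeling
rules, and FASTA/BED round-trips, not gene-structure realism: there are no
exons, splice sites, or nested introns, and retained/non-retained introns
are disjoint by construction.

`plant_motif_sequences` draws i.i.d.-base backgrounds at a configurable GC
content (default 0.41, the human genome-wide value) and plants motif
instances sampled from each PWM with class-conditional probabilities, at
uniformly random non-overlapping offsets and random strand, logging every
placement. i.i.d. background is the model under which PWM log-odds is
well defined; planted motifs never overlap so hot-spot ground truth is
unambiguous. Packing that cannot satisfy non-overlap raises rather than
silently overlapping. Synthetic PWMs (`random_pwm`) default to one dominant
base per column at probability 0.95 over 12 columns — the information
content of a strong, sharp TF motif. This is a deliberate condition: at
sharpness 0.9 even an oracle scanning with the true PWM tops out near AUROC
0.91 over 600 bp (sampled instances stray too far from the consensus), so
fixtures meant to be separable would not be; at 0.95 the oracle reaches
0.99 and "separable by construction" is true. What passing tests show is
that the pipeline recovers strong planted signals; they do not show
performance on degenerate, low-information, or co-occurring real motifs,
nor on real chromatin backgrounds with repeat structure.

`simulate_targets` draws target scores uniform in [0, 1], picks `n_active`
weights of magnitude `weight_scale` (default 4) with alternating signs,
centres the intercept at −½Σw so neither class degenerates, and draws labels
Bernoulli(sigmoid(w·x + b + noise)). Group metadata follows the canonical
TF/HM/accessibility proportions, with each protein appearing as two targets
to emulate multi-cell-line assays. Recovery tests show the estimator finds
strong sparse signals in independent features; they say nothing about the
heavy correlation structure of real chromatin-state profiles.

## Problem sizes

The test suite and acceptance script run at sizes chosen to keep a full run
in minutes on one CPU while staying at the stated study conditions where
those exist: 600 bp sequences, n = 2000 with planting probabilities 0.9/0.05
and 10 decoy motifs for pipeline recovery; n = 2000, 50 targets, 5 active
for weight recovery; n ≤ 12 / n ≤ 8 / n ≤ 50 for the exhaustive oracle and
hygiene checks; 240 × 200 bp sequences for fast attribution unit tests.
Sequence-model fits in tests use 8–18 epochs with the reverse-complement
augmented training split.

## Known limitations

- The layer engine is CPU numpy: fine at desk scale, not for genome-scale
  training; there is no dropout, no multi-GPU, no mixed precision.
- The pre-trained chromatin backbone and DNA language models are contract
  slots, not shipped weights; the fine-tuning machinery is exercised with
  the miniature backbone only.
- Greedy identity clustering is O(n²) in sequence comparisons and exact
  ungapped only — appropriate for fixture scales, not millions of
  sequences.
- The enrichment statistic treats hot spots as exchangeable under the
  permutation null; spatial clustering of hot spots within a sequence is
  not modelled.
- `GBDTConfig.bagging_freq=1` is kept for fidelity to the reference
  settings although it has no effect without a bagging fraction below 1.
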