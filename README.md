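# irdhs — intron retention from open-chromatin sequence

Intron retention (IR) — an intron surviving splicing into the mature
transcript — is regulated co-transcriptionally, and chromatin state leaves a
readable signature of it. `irdhs` implements a complete, desk-scale pipeline
for studying that signature in regions of open chromatin: DNase I
hypersensitive sites (DHSs, 600 bp windows) are labeled *IR* when they
overlap a retained intron and *non-IR* otherwise, sequence models and
chromatin-target classifiers are trained to tell the two apart, and the
trained models are mined for transcription-factor signal with Integrated
Gradients and position-weight-matrix (PWM) enrichment.

The package is aimed at computational biologists who want a tested, fully
reproducible implementation of every stage — dataset construction, model
training, evaluation, and interpretation — with a synthetic-data module that
replaces the original genome-scale inputs so the whole pipeline runs in
minutes on one CPU with known ground truth.

## What is inside

- **`irdhs.dataset`** — BED-convention interval labeling (IR iff overlap with
  a retained intron ≥ a threshold; 1 bp for annotation-derived introns,
  500 bp for RNA-seq-derived ones), RNA-seq relabeling with event
  bookkeeping, reverse-complement augmentation, greedy sequence clustering at
  80% ungapped identity, and cluster-aware 80/10/10 splitting so no test
  sequence has a near-duplicate in training.
- **`irdhs.models`** — scikit-learn-style estimators:
  `BassetClassifier` (three conv/batch-norm/max-pool layers, three dense),
  `BasenjiClassifier` (conv stem, dual-path conv blocks, residual dilated
  convolutions with doubling dilation, attention-pooled head),
  `FinetunedSequenceClassifier` (a pre-trained backbone behind a contract,
  plus a fine-tuning block; freezable), `LogisticTargetsClassifier` and
  `GBDTTargetsClassifier` over a chromatin-targets matrix with TF /
  histone-mark / accessibility group metadata.
- **`irdhs.nn`** — the numpy layer engine behind the sequence models:
  convolution (with dilation), batch norm, GELU/ReLU, max/mean/attention
  pooling, residual and dual-path blocks, SGD-momentum and AdamW, all with
  hand-written backpropagation that is finite-difference checked in the test
  suite. Input gradients flow to the one-hot sequence, which is what
  Integrated Gradients needs.
- **`irdhs.training`** — binary cross-entropy, a warmup + cosine learning-rate
  schedule, validation-loss early stopping with best-weights restoration, and
  a class-balanced sampler for imbalanced labels.
- **`irdhs.evaluation`** — ROC and precision-recall curves, AUROC
  (trapezoidal / Mann-Whitney) and AUPRC (step-wise rule).
- **`irdhs.interpretation`** — Integrated Gradients, confident-sequence
  selection (correct prediction with probability > 0.7), hot spots
  (positions above 70% of the per-sequence attribution maximum), JASPAR PWM
  scanning (log-odds ≥ 80% of the motif maximum, both strands), the
  enrichment statistic *f*<sub>IR</sub> − *f*<sub>nonIR</sub> with a
  permutation null, and logistic-weight target ranking.
- **`irdhs.simulate`** — generators with known ground truth: a toy genome
  with retained-intron structure, two-class sequences with class-conditionally
  planted PWM motifs, and a targets matrix whose labels come from a known
  sparse logistic model.

## The core statistic

For a trained sequence classifier *f* and input one-hot sequence *x*, the
attribution of position *i* is the Integrated Gradient

IG<sub>i</sub>(x) = (x<sub>i</sub> − x̄<sub>i</sub>) · (1/m) Σ<sub>k=1..m</sub>
∂f(x̄ + (k/m)(x − x̄)) / ∂x<sub>i</sub>

against an all-zeros baseline x̄. Positions whose attribution at the observed
base exceeds 70% of the sequence maximum are *hot spots*; a hot spot carries a
motif when any PWM window covering it scores at least 80% of that motif's
maximum log-odds on either strand. Each motif is then ranked by

score(motif) = (fraction of IR hot spots carrying it) − (fraction of non-IR
hot spots carrying it),

with significance from shuffling hot-spot class labels.

## Worked example

Train a Basset-style CNN on sequences in which one motif of eleven is
planted in 90% of IR and 5% of non-IR sequences, then recover that motif:

```python
import numpy as np
from irdhs import (SimulationConfig, plant_motif_sequences, random_pwm,
                   one_hot_batch, revcomp, BassetClassifier, roc_auc,
                   interpret_sequences, InterpretConfig)

rng = np.random.default_rng(1)
pwms = [random_pwm(f"MA{i:04d}.1", 12, rng, name=f"TF{i}") for i in range(11)]
causal = pwms[3]
cfg = SimulationConfig(n_ir=1000, n_nonir=1000, seq_len=600, seed=3,
                       plant_prob_ir={causal.id: 0.9},
                       plant_prob_nonir={causal.id: 0.05})
seqs, labels, _ = plant_motif_sequences(cfg, pwms)
X = one_hot_batch(seqs)
order = np.random.default_rng(4).permutation(len(X))
tr, te = order[:1600], order[1600:]
Xtr = np.concatenate([X[tr], one_hot_batch([revcomp(seqs[i]) for i in tr])])
ytr = np.concatenate([labels[tr], labels[tr]])      # RC augmentation

clf = BassetClassifier(max_epochs=8, patience=8, seed=1).fit(Xtr, ytr)
print("test AUROC:", round(roc_auc(clf.predict_proba(X[te])[:, 1],
                                   labels[te]).auc, 3))

enrichment, hotspots = interpret_sequences(
    clf, X, labels, pwms, InterpretConfig(ig_steps=32),
    max_per_class=150, n_perm=1000, seed=1)
print(enrichment.head(3)[["motif_id", "f_ir", "f_nonir", "score", "p_perm"]])
```

Output (one CPU, about three minutes):

```
test AUROC: 0.906
   motif_id      f_ir  f_nonir     score    p_perm
0  MA0003.1  0.571599      0.0  0.571599  0.000999
1  MA0000.1  0.000000      0.0  0.000000  1.000000
2  MA0001.1  0.000000      0.0  0.000000  1.000000
```

The held-out AUROC of 0.906 sits near the ceiling this planting noise
allows, and the planted motif `MA0003.1` is the only one enriched in IR hot
spots: 57% of IR hot spots carry it versus 0% of non-IR hot spots
(permutation p ≈ 0.001 at 1000 shuffles).

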