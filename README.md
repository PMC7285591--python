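# aptapred

Sequence-based prediction of **aptamers** and **protein–aptamer
interactions**.

Aptamers are short single-stranded DNA or RNA oligonucleotides that fold
into stable three-dimensional structures and bind protein targets with
high affinity.  Discovering them experimentally (SELEX) is slow and
expensive, so a classifier that screens candidate sequences — *is this
sequence an aptamer?* and *does this aptamer bind this protein?* — is a
useful triage tool for aptamer researchers.  `aptapred` is a library plus
CLI implementing both tasks from sequence alone.

## Method

**Features.**  Proteins are encoded by five physicochemical descriptors:
amino-acid composition (AAC, 20), Chou's type-1 pseudo amino-acid
composition (PseAAC, 20 + λ with λ = 30, weight w = 0.05), grouped
amino-acid composition over five physicochemical groups (GAAC, 5), the
composition part of the C/T/D descriptors for seven attributes (CTDC, 21),
and sequence-order-coupling numbers under two amino-acid distance matrices
(SOCN, 2λ with λ = 30) — 156 components in total.  Nucleotide sequences are
encoded by nucleotide composition (NAC, 4), pseudo k-tuple nucleotide
composition (PseKNC, 4ᵏ + λ with k = 2, λ = 10, w = 0.05) and the
normalized Moreau–Broto autocorrelation of 11 dinucleotide physicochemical
properties (NMBAC, 11 × 10 lags) — 140 components, with separate DNA and
RNA property tables.  A protein–aptamer pair is the 296-component
concatenation.

**Class balance.**  Interaction data is heavily skewed toward
non-interacting pairs, so the minority class of the *training partition
only* is oversampled with SMOTE (`x_new = x + u·(x_nn − x)`,
u ~ U(0,1), k = 5 neighbors) up to full balance.  Test partitions always
consist solely of real samples; the API enforces this.

**Classifier.**  A discrete AdaBoost loop whose weak learners are small
random forests (10 trees, max depth 150; T = 300 rounds, learning rate
0.75).  Each round fits a forest on a weighted bootstrap, computes the
weighted error ε_t and the learner weight α_t = lr · ½ ln((1 − ε_t)/ε_t),
and re-weights the samples; the final score is the α-weighted mean of the
forests' positive-class probabilities.  A pair is called interacting when
its score ≥ 0.44; a sequence is called an aptamer when its score ≥ 0.48
(both thresholds configurable).

**Negative aptamers by structure screening.**  Negative examples for the
aptamer task are length- and composition-matched random sequences that
*fail* an aptamer-likeness screen computed from a secondary-structure
fold: energy density, unpaired-base fraction, hairpin count and longest
stem, parsed from dot-bracket structures.  Structures come from any
RNAfold-style engine (parsed from its text output) or from the built-in
maximum-base-pairing (Nussinov) folder.

**Evaluation.**  Sn, Sp, Acc, Precision, F1, MCC, ROC/AUC (tie-aware
Mann–Whitney), and DeLong's paired test for comparing correlated AUCs.

## Worked example

```python
import numpy as np
from aptapred import pipeline as pl
from aptapred import synthetic, seqio
from aptapred.evaluation import auc_score

# a planted-signal fixture bundle (400 pairs + 80 aptamers)
sizes = synthetic.FixtureSizes(train_pos=100, train_neg=200,
                               test_pos=40, test_neg=60,
                               aptamer_pos=40, aptamer_neg=40)
bundle = synthetic.make_fixtures(seed=707, sizes=sizes)
train, _ = seqio.filter_pair_dataset(bundle.pairs_train)
test, _ = seqio.filter_pair_dataset(bundle.pairs_test)

model, log = pl.train_pairs(train, pl.PipelineConfig(seed=3))
print(log["counts_before_balancing"], "->", log["counts_after_balancing"])
ds = pl.encode_pairs(test, pl.PipelineConfig(seed=3))
print("held-out AUC:", round(auc_score(ds.labels, model.predict_score(ds.features)), 3))
```

prints

```
{0: 200, 1: 100} -> {0: 200, 1: 200}
held-out AUC: 1.0
```

i.e. SMOTE brought the 100 interacting training pairs up to the 200
non-interacting ones, and on the held-out pairs the ensemble separates the
two planted classes perfectly (the fixture's composition shift is
deliberately strong; see `docs/methods.md`).

The same workflows are available from the shell:

```
aptapred make-fixtures --seed 7 --outdir fixtures --scale 0.1
aptapred train-pairs fixtures/pairs_train.tsv --model-out model.joblib
aptapred predict-pairs model.joblib proteins.fasta aptamers.fasta --out predictions.tsv
aptapred gen-negatives positives.fasta -n 100 --out negatives.fasta
```

Prediction tables have the columns `aptamer`, `protein`, `result`
(`yes`/`no`) and `score` (pair mode), or `name`, `result`, `score`
(aptamer mode).

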