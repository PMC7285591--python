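# Methods

This note documents the models and procedures implemented in `aptapred`,
the defaults and where they come from, what the synthetic-data generator
does and does not emulate, and the numerical and design choices that were
genuinely open.

## Sequence validation and the problematic-sequence filter

Sequences are typed as protein (20 canonical residues), DNA (ACGT) or RNA
(ACGU) and validated before encoding; letters outside the alphabet raise
rather than being silently skipped, because skipping changes the sequence
length N and corrupts every frequency-based feature.  Nucleotide records
are additionally screened by the problematic-sequence filter: a record is
discarded if it contains B, contains N, or contains both U and T (an
ambiguous DNA/RNA mixture).  The filter applies to nucleotide records
only; B is an ambiguity code only in extended protein alphabets and the
U/T clause is meaningless for proteins.  A flag extends it to proteins for
users who want symmetric behavior.  Sequences are stored as given (RNA
keeps U); encoders canonicalize U to the fourth base slot internally so
DNA and RNA share a 4-letter index while using molecule-specific property
tables.

## Protein encoders

* **AAC** — residue frequencies, 20 components summing to 1.
* **GAAC** — frequencies of five physicochemical groups (aliphatic
  GAVLMI, aromatic FYW, positively charged KRH, negatively charged DE,
  uncharged STCPNQ).
* **PseAAC** (Chou type 1) — the 20 residue frequencies plus λ
  sequence-order correlation factors θ_j, where θ_j averages the mean
  squared difference of three property scales (hydrophobicity,
  hydrophilicity, side-chain mass; standardized to zero mean / unit
  population variance over the 20 residues) between residues j apart; the
  20 + λ components are jointly normalized to sum to 1 with pseudo-weight
  w.  Defaults λ = 30, w = 0.05 — the conventional reference-implementation
  defaults, since no value is fixed by the task itself.  Requires N > λ.
* **CTDC** — for each of seven attributes (hydrophobicity, normalized van
  der Waals volume, polarity, polarizability, charge, secondary structure,
  solvent accessibility), the frequencies of its three residue classes.
  The class tables follow the iFeature conventions and ship as a
  plain-text resource (`data/protein_groups.tsv`) so results are
  bit-for-bit reproducible.  "Solubility" in informal descriptions of the
  seven attributes maps to the standard solvent-accessibility attribute.
  Only the Composition part of C/T/D enters the default feature set;
  Transition and Distribution are deliberately out of scope.
* **SOCN** — sequence-order-coupling numbers f_d = Σ_i d(R_i, R_{i+d})²
  for d = 1..λ (default 30) under two 20×20 amino-acid distance matrices,
  physicochemical block first, Grantham block second.  Requires N > λ.

**Distance matrices.**  The Grantham matrix is recomputed from Grantham's
published formula (composition / polarity / volume, α = 1.833, β = 0.1018,
γ = 0.000399, scaled so the mean pairwise distance is 100); the
recomputation reproduces the printed landmark values (L–I 5, W–C 215,
S–R 110) within rounding.  The second matrix,
`data/physchem_distance_synthetic.tsv`, is a **synthetic** constructed
stand-in for the classical Schneider–Wrede physicochemical distance
matrix, which is not redistributable here: Euclidean distance in the
standardized (hydrophobicity, hydrophilicity, side-chain mass) space,
rescaled to [0, 1].  It has the same structural properties (non-negative,
zero diagonal) and plays the same role in SOCN; users with the original
matrix can drop it in as a TSV.

## Nucleotide encoders

* **NAC** — four base frequencies, U counted in the T/U slot.
* **PseKNC** — normalized k-tuple frequencies plus λ correlation factors
  from the mean squared difference of 11 standardized dinucleotide
  properties, jointly normalized with weight w.  Defaults k = 2, λ = 10,
  w = 0.05 (configurable); requires L ≥ k and L − 1 > λ.
* **NMBAC** — for each property p and lag d = 1..max_lag (default 10),
  the average product of the standardized property profile with its
  d-shifted self over the L − 1 dinucleotide positions.  Sequences shorter
  than max_lag + 2 raise a per-sequence error rather than being padded —
  padding would fabricate autocorrelation signal.

**Dinucleotide property tables.**  Eleven properties per molecule type:
shift, slide, rise, tilt, roll, twist, stacking energy, enthalpy, entropy,
free energy, hydrophilicity.  (Informal listings of this property set
sometimes print "twist" twice; the eleventh property here is enthalpy,
the standard companion of entropy and free energy in nearest-neighbor
thermodynamics.)  DNA and RNA tables are separate plain-text resources
compiled from published B-DNA/A-RNA base-step parameters, the unified
(DNA) and Turner/Xia (RNA) nearest-neighbor thermodynamic sets, and the
published dinucleotide hydrophilicity scale; the file headers state the
provenance per column group.  Every property is standardized to zero mean
and unit population variance across the 16 dinucleotides *per table*
before entering any encoder (the convention of the autocorrelation
method), so results depend only on the relative spacing of the values,
not on units or affine differences between published compilations.

## SMOTE balancing

Synthetic minority samples interpolate between a real minority point and
one of its k = 5 nearest minority neighbors (Euclidean distance on the raw
feature scale — the encoders already produce comparable-magnitude
components).  The default target is the majority count, i.e. full balance;
the historical report of one-short-of-balance (1681 vs 1682) in the
original interaction study is a discrepancy we do not reproduce.  Real
rows pass through bitwise untouched and every row carries a provenance
flag; evaluation helpers refuse datasets containing synthetic rows, and
the configuration validates that test-partition balancing is never
requested.  SMOTE requires a minority class of at least 2 samples.

## Boosted random-forest ensemble

Discrete AdaBoost with random-forest weak learners.  Per round t:

1. draw a weighted bootstrap of the training set (sampling proportional to
   the current boosting weights) and fit a forest h_t (10 trees, max depth
   150) — resampling keeps the weak-learner contract independent of any
   particular library's `sample_weight` semantics;
2. compute the weighted training error ε_t of h_t on the original set;
3. set α_t = learning_rate · ½ ln((1 − ε_t)/ε_t); the learning-rate
   multiplier sits outside the ½ ln term;
4. multiply misclassified sample weights by e^{α_t}, correct ones by
   e^{−α_t}, renormalize.

Early stopping: ε_t = 0 caps α_t at ln(10¹⁰) (finite arithmetic in place
of the formula's infinity), keeps the round and stops; ε_t ≥ 0.5 stops the
loop, retaining the round only when it is the first (so the model always
has T ≥ 1 learners; at ε = 0.5 exactly the formula gives α = 0).
Defaults: T = 300 rounds, learning rate 0.75.

Scoring aggregates the forests' positive-class probabilities as
Σ α_t p_t / Σ α_t ∈ [0, 1] (falling back to the unweighted mean when all
α are 0); the classical hard-vote rule sign(Σ α_t h_t) is exposed
separately and coincides with thresholding the probability aggregate at ½
when the base outputs are hard votes.  Decisions are threshold-inclusive:
"yes" iff score ≥ threshold, with defaults 0.44 (pair interaction) and
0.48 (aptamer); both were tuned choices in the original study and both are
configurable, with a Youden-J grid-search utility (`tune_threshold`)
provided for re-tuning on a validation split — the original
threshold-selection simulation is under-specified, so an explicit
validation-split search replaces it.  Models serialize to a versioned
joblib archive that stores the feature-name signature and refuses inputs
whose columns differ in names or order.

## Structure screening and negative-set construction

Dot-bracket structures are stack-parsed into pair tables (crossing or
unbalanced brackets are rejected — nested structures only, so pseudoknots
are out of scope, a known limitation shared with the standard folding
engines' text output).  Loops enclosed by a pair are classified by their
directly nested pairs: none → hairpin; one, flush on both sides → stacked
pair (stems are maximal runs of these); one with a one-sided gap → bulge;
one with two-sided gaps → internal loop; several → multiloop.  Derived
statistics: pair count, hairpin/bulge/internal/multiloop counts, stem
count, longest stem, unpaired fraction, energy density (energy/length).

The internal fallback folder is a maximum-base-pairing (Nussinov) dynamic
program with hairpin loops of at least 3 unpaired bases and pairs A–U/T,
G–C and the G–U wobble (DNA is folded with T ≡ U).  Its pseudo-energy is
−(pair count) — a structural score, **not** a thermodynamic minimum free
energy.  An external engine's RNAfold-style text output (name, sequence,
dot-bracket with trailing energy) can be parsed instead; the engine itself
is never invoked.

**Aptamer-likeness thresholds.**  A structure is aptamer-like iff energy
density ≤ −0.37 per nt AND unpaired fraction ≤ 0.26 AND ≥ 1 hairpin AND
longest stem ≥ 4.  The published screening criteria are qualitative
(stable structure, low free energy, stem-loops, few unpaired bases), so
the cut-offs are explicit assumptions, surfaced in configuration.  They
are calibrated to the fallback's pseudo-energy scale, on which the energy
density is −½ × (paired fraction): maximum-pairing folds of random
aptamer-length sequences concentrate near energy density −0.35 and
unpaired fraction 0.30, so these cut-offs put canonical stable hairpins
(long stems, mostly paired) on the aptamer-like side while typical random
sequences fail — which gives the negative generator a usable acceptance
rate (~80–85%) without making the screen vacuous.  Users running a
thermodynamic engine should supply kcal/mol-scale cut-offs instead.

**Negative generation.**  Candidate lengths and molecule kinds follow the
positive set's empirical length assignment (templates consumed in permuted
order, cycling), candidate bases are i.i.d. draws from the positives'
per-molecule mononucleotide frequencies, and a candidate is kept iff its
fold fails the aptamer-likeness screen.  Rejection statistics are logged;
generation aborts if the acceptance rate falls below a floor (thresholds
too aptamer-permissive) or a single template cannot produce a
screen-failing candidate within a bounded number of draws.

## Evaluation

Sn, Sp, Acc, Precision, F1 and MCC from confusion counts, with the
zero-denominator conventions MCC → 0, Precision → 0, F1 → 0 (documented
because degenerate all-one-class predictions do occur at extreme
thresholds).  AUC uses the tie-aware Mann–Whitney rank identity, which
equals the trapezoid area under the ROC curve evaluated at every distinct
score; ROC points (Sn vs 1 − Sp) are exported for plotting.  DeLong's
paired test compares two correlated AUCs via midrank placement values and
a two-sided normal p-value; identical score vectors return p = 1 by
convention.  The implementation reproduces R pROC's `roc.test` to 10
decimal places on a frozen fixture and its type-I error rate under a
simulated null is calibrated in the acceptance suite.

## The synthetic-data generator

The generator emulates the *shapes* of the original study inputs so the
pipeline can be exercised end-to-end; its defaults are those shapes:
pair partitions of 561/1682 (train) and 143/421 (test) after filtering,
with ~3% injected problematic rows (containing B, N or mixed U/T) for the
filter to remove; 704 positive aptamers and 700 screened negatives
(alternating DNA/RNA, ~350 each).

* **Lengths** are drawn from a discrete distribution on 15–120 nt with
  mode 40, secondary peaks at 30, 50 and 80, and 80% of mass in
  [30, 80] nt — the documented profile of selected aptamers.
* **Synthetic aptamers** are built as explicit stem-loops (random flank +
  arm + loop + reverse-complement arm + flank), the hallmark architecture
  of real aptamers, and verified to pass the likeness screen.  Arm bases
  follow a first-order step bias (preferred G↔C alternation, probability
  0.55) emulating the enrichment of strong G:C stacking steps in selected
  aptamer stems; this gives the positive class a dinucleotide-level
  signature that sequence features can detect, since negatives are
  matched on mononucleotide composition by construction.
* **Pair tables** plant a marginal signal: interacting and non-interacting
  pairs draw their protein residues and aptamer bases from class-specific
  frequency profiles separated by a logit shift (default 1.0, chosen once
  to give clear feature-space separation — the fixture's purpose is to
  verify that the pipeline recovers a known signal; shift 0 produces a
  null dataset with held-out AUC ≈ 0.5).

What the generator does **not** emulate, and hence what passing tests do
not show about real data: the bipartite structure of real interaction
tables (real proteins and aptamers recur across many pairs with mixed
labels; generated pairs use fresh sequences, so the signal is marginal
rather than relational); real binding chemistry (the planted composition
shift is a stand-in, and is cleaner than real signal — end-to-end AUCs on
the fixture land near 1.0, above the mid-0.8s reported on real
interaction data); homology/redundancy structure (no CD-HIT-style
clustering is needed or performed on i.i.d. sequences); and thermodynamic
folding (the fallback maximizes pairs; statistics sit on its pseudo-energy
scale).

## Problem sizes and determinism

The default test suite runs the full emulated shapes (2,243 + 564 pairs,
704 + 700 aptamers) once in the acceptance tests and small scales
elsewhere; the acceptance script repeats the full-shape run and completes
in about a minute on one CPU.  Every stochastic step (generation, SMOTE,
bootstrap resampling, forest fitting) derives from a single integer seed
through `numpy`'s `SeedSequence` machinery; identical config + seed gives
bitwise-identical models and prediction tables.

## Known limitations

* Nested secondary structures only; pseudoknots — which real aptamers do
  form — are rejected at parse time and never predicted by the fallback.
* The fallback folder maximizes base pairs; its statistics are not
  thermodynamic, and screening cut-offs must be re-specified when an
  external thermodynamic engine is used.
* The synthetic physicochemical distance matrix is a stand-in; SOCN
  values under it are internally consistent but not comparable to values
  computed with the original Schneider–Wrede table.
* CTD Transition/Distribution descriptors and trinucleotide structural
  profiles are out of scope.
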