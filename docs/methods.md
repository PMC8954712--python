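# Methods

## Problem setting and model

The package addresses qualitative SAR modeling of a small kinase-inhibitor
collection: a binary potency classification over precomputed substructure
fingerprints, followed by identification of the fingerprint bits that carry
the classification. The design center is a dataset of ~117 heterocyclic
inhibitors with a ~3:1 potent:non-potent imbalance and 881-bit binary
fingerprints; everything is sized and tested at that scale.

### Potency labeling

pIC50 = 6 − log10(IC50 [μM]). The class cutoff is pIC50 = 6.0 (IC50 = 1 μM),
with the boundary assigned to the potent class: "≥" makes 1 μM the last
potent value, and no realistic dataset places a compound exactly on the
cutoff, so the choice is inconsequential in practice but must be fixed for
determinism.

### Train/test splitting

`stratified_split` draws a seeded split at a train:test ratio (default 3:1).
Per-class test allocation uses largest-remainder proportional quotas, which
preserves class proportions to within one compound. Published splits of
comparable datasets are sometimes *not* proportionally stratified (e.g. a
29-compound test set with 20 P / 9 N where proportionality gives 22 / 7);
`test_counts` therefore accepts an explicit per-class allocation to
reproduce such layouts exactly. Membership is always seed-randomized — only
the counts are reproducible, since published member assignments are
generally unrecoverable.

## Balancing: SMOTE + Tomek links

Implemented from scratch over Euclidean distance on the raw 0/1 features
(equivalently √Hamming; no scaling — all coordinates share the same unit).
Nearest-neighbor ties break toward the lower row index, making every step
deterministic given the seed.

* **SMOTE**: each synthetic row interpolates a random minority sample toward
  one of its k = 5 minority nearest neighbors with a fresh u ~ Uniform(0,1).
  k is capped at the available neighbor count, so a 2-member minority still
  oversamples (degenerating to duplication when parents coincide). Synthetic
  rows are binarized at 0.5 with ties to 1, keeping them valid fingerprints
  for downstream fragment mining; `binarize=False` exposes the raw convex
  combinations.
* **Tomek links**: all cross-class mutual-nearest-neighbor pairs. The
  default removal policy deletes *both* members of each link. Because links
  are disjoint and cross-class, both-member removal preserves the exact
  parity SMOTE established (e.g. 69/19 → 69/69 → 67/67 with two links);
  this also matches the post-balance counts reported for comparable
  workflows. `policy="majority-only"` implements the alternative reading in
  which only the majority-class member is discarded.
* Balancing applies to training data only; test and external sets are never
  resampled.

No established hybrid-resampler package is available in the supported
environment, so correctness rests on brute-force oracles in the test suite:
an exhaustive-scan nearest-neighbor oracle, an O(n²) mutual-NN Tomek oracle,
parent bounding-box containment for every synthetic row, and parity checks
over 20 seeds.

## Classifier grid

Seven algorithms (SVM, LR, kNN, ANN, NB, RF, DT) behind one factory, backed
by scikit-learn. The random forest is pinned to 20 trees and maximum depth
15; every other hyperparameter keeps the backend default and is recorded in
the run manifest — the aim is a reproducible protocol, not replication of
any particular historical toolkit's defaults. Naive Bayes is the Bernoulli
variant, matching presence/absence features. Ranking scores are class
probabilities, except the SVM which ranks by its signed margin (uncalibrated
scores order identically for AUC purposes).

Cross-validation is stratified, seeded, and **pooled**: the out-of-fold
predictions of the 5 folds fill one confusion table whose total equals the
training-set size. `folds == n` degenerates to leave-one-out; a class
smaller than the fold count is refused.

**Balancing order.** With `balance=True` the hybrid is applied to the whole
training set *before* CV. This leaks synthetic rows' neighbors across folds
and optimistically biases the CV estimate — visibly so in the demo run,
where balanced CV metrics jump while the untouched test set barely moves.
It is nonetheless the default because it is the protocol the benchmark
workflow this package emulates demonstrably used (its balanced training
confusions sum to the post-balance size, which is only possible when
balancing precedes CV). `balance_within_folds=True` rebalances each fold's
training portion only, which is the statistically sound variant; the two
options make the bias itself measurable.

## Metric suite

SE, SP, CA, MCC and BA are exact rational functions of the confusion
counts. A metric whose defining margin is empty (e.g. MCC with no predicted
negatives) returns an explicit `UNDEFINED` marker — not NaN, not an
exception — because degenerate rows occur in real validation tables and
must render as `-`.

AUC is computed by midrank Mann–Whitney concordance (ties ½) and,
independently, by trapezoidal integration of the empirical ROC; the two
routes agree to 1e-12 on random tied score sets in the test suite, and the
concordance route is cross-checked against scikit-learn's implementation.

**Display rounding.** Reports round half-up to 3 decimals (0.8695 → 0.870),
matching the convention of printed SAR tables; Python's banker's rounding
would differ in the last digit. Displayed BA is the half-up mean of the
*displayed* SE and SP rather than of their full-precision values — the
convention printed benchmark tables follow — while `balanced_accuracy()`
itself returns full precision.

## Fragment mining

Per bit: occurrence counts in each class, base-2 information gain
IG = H(class) − H(class | present/absent) with 0·log 0 := 0, and the
class-frequency ratio freq_I = (N_fragment,I · N_total)/(N_fragment,total · N_I).
The totals are those of the modeling dataset (for the design-center dataset,
N_total = 117, N_I = 89) — verified arithmetically against every checkable
published row. The two frequencies satisfy the exact identity
freq_P·N_P + freq_N·N_N = N_total.

Ranking sorts by IG descending, ties by freq_P descending, then bit name.
Defaults: `min_support=2` (a bit seen once cannot be a reusable
pharmacophore), `min_ig=0`. Polarity is positive iff freq_P > freq_N,
negative iff the reverse, neutral otherwise; the positive/negative fragment
*counts* reported in comparable studies depend on unstated cutoffs, so
thresholds stay exposed as parameters rather than hard-coded.

## Chemical-space characterization

* Diversity: pairwise Euclidean distances over fingerprints, normalized by
  the maximum to [0, 1] by default (matching 0–1 heat-map color scales); raw
  distances by flag.
* Descriptor screening: drop columns whose modal value frequency exceeds
  80%, then greedily drop the later-listed member of every pair with
  |Pearson r| > 0.95 (keep-first is deterministic and row-order invariant).
* Projection: columns centered and scaled to unit variance (descriptor
  units are heterogeneous, so the correlation-matrix convention is the
  defensible default), then PCA.
* Lipinski profile: per-compound MW/logP/HBD/HBA/RotB plus min/median/max
  summaries for radar rendering. All chemspace artifacts are CSV/JSON;
  no image files are emitted.

## Synthetic data generator

The generator emulates the statistical structure the analysis consumes —
not chemistry. Bits are class-conditionally independent Bernoulli draws,
the simplest model consistent with per-bit frequency analysis; additional
structure is planted explicitly:

* exact class counts (default 89 P / 28 N of 117);
* enriched bits with per-class prevalences taken from the design-center
  dataset's privileged-substructure pattern (e.g. 49/89 vs 2/28);
* background prevalence 0.15 for all other bits — a mid-range sparsity
  typical of 881-bit substructure fingerprints;
* all-one constant bits; correlated pairs as duplicate-with-5%-flip copies;
* pIC50 values from class-conditional truncated normals, potent
  N(6.9, 0.5²) on [6.0, 8.5], non-potent N(5.4, 0.5²) on [4.5, 6.0) — the
  observed range with modes near 6 and 7; truncation at the cutoff makes
  label round-trips exact by construction.

What the generator does **not** emulate: real inter-bit correlation
structure (fingerprint bits are systematically nested and co-occurring),
scaffold clustering, activity cliffs, or any SMILES-level validity. Tests
passing on this generator demonstrate algorithmic correctness and protocol
behavior (e.g. the direction of the balancing effect), not predictive
performance on real chemistry.

## Problem sizes and determinism

All defaults target the design-center scale (117 × 881), where a full
7-algorithm grid runs in seconds; property tests use 20–100 seeded
replicates. Every stochastic component (generator, splits, SMOTE, CV folds,
models) takes an explicit seed, and the pipeline manifest records config,
seeds, package versions and SHA-256 digests of all outputs; identical
config and seed reproduce identical digests.

## Known limitations

* The classifier grid reports honest protocol results; it does not attempt
  to reproduce historical trained-model metrics, which depend on a
  particular legacy toolkit's unstated hyperparameters and on compound
  structures that were never machine-deposited.
* Balance-before-CV (the faithful default) overstates CV performance by
  construction; use `balance_within_folds` for honest CV estimates.
* Fingerprint bits are consumed precomputed; computing them from SMILES is
  out of scope, as is mapping bit names to SMARTS depictions.
* `screen_descriptors`' greedy keep-first correlation pruning is order-
  dependent by design (deterministic), not an optimal minimum-redundancy
  selection.
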