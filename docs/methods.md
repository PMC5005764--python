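# Methods

## Problem and model

`sbpred` classifies short biopanning-derived peptides as streptavidin
binders (SBP) or not, from sequence alone. The pipeline is:

1. **Preprocessing.** Circular-library peptides are linearized by removing
   at most one flanking cysteine per end (a peptide with a cysteine at only
   one end loses only that one); exact duplicate sequences are removed,
   keeping the first occurrence; sequences containing ambiguous residues
   (X, B, Z) or any letter outside the 20-letter alphabet (including J, O,
   U) are excluded; sequences shorter than 3 residues are excluded. The
   rules apply in that order, and every call returns an audit log whose
   removal counts balance the input count exactly. Preprocessing is
   idempotent. Training negatives are additionally screened for exact
   sequence overlap with the positives.
2. **Encoding.** AAC (20 residue frequencies, denominator L) and DPC (400
   overlapping adjacent-pair frequencies, denominator L−1). Dipeptides are
   read linearly — circular peptides were already linearized, so no
   wrap-around pair is counted. Compositions are always normalized over
   the full 20/400 space *before* any feature selection, so vectors
   restricted to a selected subset are sub-stochastic. Column order is
   fixed alphabetically for reproducible model files.
3. **Feature selection (OAAC/ODPC).** Each descriptor is scored alone by
   stratified k-fold CV accuracy of the downstream classifier (RBF-SVM);
   descriptors are ranked by that accuracy (ties broken lexicographically
   by token); prefixes of the ranking are evaluated by the same CV; the
   smallest prefix attaining the maximum accuracy is selected. All
   evaluations of one run share one seeded fold partition, so the
   procedure is bit-reproducible.
4. **Imbalance-handling ensemble.** Ten negative subsets of the
   positive-set size are drawn uniformly without replacement,
   independently of each other (a negative may appear in several subsets —
   the draws are repeated, not partitioned). One RBF-SVM is trained per
   balanced pair; for the optimized feature kinds, selection is re-run per
   pair, and the model reports a consensus of descriptors selected by at
   least half the submodels.
5. **Prediction.** Each submodel emits a calibrated probability; the
   ensemble reports their arithmetic mean, the number of submodels with
   probability ≥ 0.5 (the vote count, independent of the user threshold),
   and the call SBP iff mean ≥ tp. Raising tp can only shrink the SBP set
   (monotonicity), and a single-submodel ensemble is prediction-identical
   to its lone submodel.

## SVM details

- Kernel: RBF, `SVC` (libsvm) via scikit-learn. Composition features
  already lie in [0,1]; no extra scaling is applied, so the kernel width g
  is interpretable across implementations.
- Grid search over c (regularization) and g (kernel width) by stratified
  CV accuracy; ties resolved toward the smallest c, then the smallest g.
  The default grid is the canonical coarse log₂ grid
  c ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, g ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}. `SVMConfig.reduced()`
  is a 3×3 subgrid for benchmark-scale runs on one CPU, and
  `SVMConfig.fast()` a fixed single cell (c = 8, g = 8) for permutation
  loops. When grid re-search inside feature selection is disabled, subsets
  are evaluated at the *middle* grid cell: the smallest cell of a coarse
  grid underfits single composition features badly enough to corrupt the
  ranking.
- **Probability calibration** is a Platt sigmoid
  P(SBP | f) = 1/(1 + exp(A·f + B)) fitted by Newton's method with the
  standard regularized targets on *held-out* decision values from a seeded
  stratified 5-fold split, then applied to the decision values of the
  final model fitted on the whole pair. This is the same construction as
  libsvm's `-b 1` training; the package implements it directly so that a
  submodel's entire state (support vectors, dual coefficients, intercept,
  sigmoid A/B) serializes to plain JSON and reloads with bit-identical
  predictions. A test cross-checks the calibrated probabilities against
  `SVC(probability=True)` (agreement is close but not exact, since the
  internal CV partitions differ).

## Evaluation

- Sn, Sp, Acc from the pooled held-out confusion table; MCC with any zero
  denominator factor defined as 0; ROC by sweeping all distinct score
  thresholds (ties grouped) with trapezoidal AUC — verified in tests
  against a brute-force Mann–Whitney pair-count oracle.
- Cross-validation is stratified (equal class balance per fold) even
  though plain random equal-size folds would suffice in principle:
  stratification stabilizes Sn/Sp on ~400-sample pairs. For the optimized
  kinds the default protocol selects features once on the whole pair
  before splitting; a `nested` mode re-selects inside each training fold
  and is the statistically honest variant (the default mirrors the
  original protocol and therefore carries selection leakage).
- Ensemble-level performance is the mean ± sd of the per-pair CV metrics
  over the ten downsampled pairs (per-pair reports are also emitted).
- The permutation test shuffles the pair's labels uniformly, repeats the
  *full* cross-validation per trial, and counts trials whose accuracy is
  *strictly greater* than the observed one; zero exceedances are reported
  as an upper bound "p < 1/N". Optimized kinds re-run selection per
  permutation, which is why large permutation counts use a fixed-feature
  kind with the single-cell grid.
- Positive rates on independent sets are compared by a Pearson chi-square
  test on the 2×2 count table, 1 df, no continuity correction (expected
  counts in realistic tables are large enough that the correction is
  immaterial), two-sided.

## Synthetic benchmark

The generator emulates the structure of biopanning training data: by
default 199 positives vs a tenfold larger negative pool, lengths drawn
from a rounded normal (mean 9, sd 3.5) truncated below at 3 — matching the
published summary statistics of such libraries, whose true per-library
length mixtures are not disclosed. Negatives are i.i.d. uniform over the
alphabet with the HPQ motif rejection-sampled away, so the benchmark's
Bayes error is controllable. Positives carry the HPQ motif with
probability 0.9 at a uniform position; their background residues follow a
first-order chain in which the binder-associated dipeptides HP, PQ, PP,
LP, PL, PS, SP, TP are oversampled threefold. Sequences are unique within
and across the two sets, so generated data pass preprocessing with zero
removals. Everything is deterministic given the seed.

What this benchmark does *not* emulate: library codon biases, propagation
bias, topology mixtures, and — importantly — the looser correlation
structure of real binder sequences. In real binders, HP and PQ also occur
independently of the exact HPQ context; in the synthetic positives they
are almost perfectly collinear (each appears without the other in only
~2% of positives). A direct consequence: accuracy-ranked forward selection
with the smallest-prefix-at-maximum rule almost always stops at a single
dipeptide ({PQ} or occasionally {HP}), because the second motif dipeptide
adds no measurable CV accuracy. The ensemble consensus on the default
benchmark is therefore typically {PQ} alone, whereas on real data the
accuracy maximum sits deeper and the selected set is larger. Passing the
benchmark's accuracy checks shows the pipeline separates motif-bearing
from background peptides; it does not show that the selected feature set
on real data would be recovered.

## Problem sizes and numerical choices

- Benchmark-scale runs (ten pairs of 199 + 199 peptides) use the reduced
  3×3 grid and cap the forward-selection prefix search at the top 100
  ranked dipeptides (`selection_max_prefix=100`); with 400 descriptors the
  informative features sit at the top of the ranking and the accuracy
  curve is flat long before rank 100. The uncapped search (the library
  default) evaluates every prefix.
- Permutation analyses use 100 permutations on one balanced pair for the
  significance check and 50 repetitions × 20 permutations on 100-peptide
  no-signal pairs for the null-uniformity check.
- Reported percentages are rounded to 2 decimals in summaries; machine
  output keeps full precision. Model files store floats via JSON's
  shortest-round-trip representation, which is exact for doubles.
- Degenerate inputs: empty sets, single-class labels, peptides too short
  to encode, truncated model files and version mismatches all raise
  explicit errors — except during batch prediction, where an unencodable
  peptide yields a per-record error entry rather than aborting the run.

## Known limitations

- The default selection protocol leaks feature-selection information into
  the CV estimate (see `nested` mode above); the reported benchmark
  accuracies use the default protocol deliberately, to match the original
  construction.
- Calibration quality on near-separable pairs is limited: with few
  misclassified training points the Platt sigmoid saturates, and
  probabilities cluster near 0/1.
- The chi-square comparison is two-sided although the scientific
  hypothesis (anchoring-reagent sets contain *more* binders) is
  one-sided; halving the p-value for the one-sided reading is left to the
  caller.
- Only the 20 standard residues are modelled; modified residues and
  nucleotide input are out of scope.
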