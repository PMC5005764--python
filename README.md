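# sbpred

Ensemble SVM prediction of **streptavidin-binding peptides (SBP)** from
phage-display biopanning sequences.

Streptavidin appears in most biopanning systems — sometimes as the intended
target, more often as the anchoring molecule that captures a biotinylated
target. In the latter case, peptides that bind streptavidin itself are
*target-unrelated peptides* (TUP): they look like hits but bind the capture
reagent, not the target. `sbpred` trains and applies a sequence-only
classifier that flags likely SBP, so they can be excluded as TUP — or
short-listed when streptavidin binders (e.g. new affinity tags) are exactly
what is wanted.

## Method

A peptide sequence of length *L* is encoded by its compositions:

- **AAC** (amino-acid composition, 20 features): AAC*ᵢ* = *xᵢ*/*L*, the
  frequency of residue *i*;
- **DPC** (dipeptide composition, 400 features): DPC*ⱼ* = *yⱼ*/(*L*−1), the
  frequency of adjacent pair *j* among the *L*−1 overlapping pairs.

The optimized variants **OAAC/ODPC** are produced by accuracy-ranked forward
selection: each feature is scored alone by cross-validated SVM accuracy,
features are ranked, prefixes of the ranking are grown one feature at a
time, and the smallest prefix with maximal CV accuracy is kept.

Because negative peptides vastly outnumber binders, class imbalance is
handled by a **downsampling voting ensemble**: ten random negative subsets
of the positive-set size are drawn, one RBF-kernel SVM (C and γ tuned by
grid search, probabilities by a Platt sigmoid on cross-validated decision
values) is trained per balanced pair, and a query peptide receives

- the **mean probability** over the ten submodels,
- a **vote count** (submodels with probability ≥ 0.5), and
- a binary **call**: SBP iff the mean probability ≥ a user threshold
  *tp* (default 0.5).

Models are assessed by stratified fivefold cross-validation (Sn, Sp, Acc,
MCC, ROC/AUC), label-permutation significance testing, and — on independent
sets — positive rates compared with a Pearson chi-square test.

## Worked example

```bash
# a seeded synthetic benchmark: 199 motif-bearing binders vs 1990 negatives
sbpred simulate --out-pos pos.fa --out-neg neg.fa --seed 5

# train a 10-submodel ensemble on dipeptide composition
sbpred train --pos pos.fa --neg neg.fa --feature dpc --grid fast \
             --seed 1 --model-out model.json
# -> trained 10 submodels (DPC) -> model.json

# score peptides (here: the training positives, as a sanity check)
sbpred predict --model model.json --in pos.fa --out pred.tsv
# -> 199/199 peptides called SBP at tp=0.5 -> pred.tsv

# compare two independent-set positive rates (published counts)
sbpred compare-rates --a-pos 208 --a-total 1711 --b-pos 1169 --b-total 13272
# -> rate A=12.16%  rate B=8.81%  chi2=20.363  p=6.4e-06
```

`pred.tsv` has one row per peptide: id, sequence, mean probability (six
decimals), votes (0–10) and the SBP/non-SBP call. A mean probability of
0.97 with 10 votes is a confident binder call; 0.52 with 6 votes is
marginal — raise `--tp` (e.g. 0.95) to keep only high-confidence SBP, or
lower it to exclude every possible SBP from a biopanning hit list.

The same functionality is available as a library:

```python
from sbpred import (BenchmarkSpec, SVMConfig, generate_benchmark,
                    train_ensemble, predict)

pos, neg = generate_benchmark(BenchmarkSpec(seed=5))
model = train_ensemble(pos, neg, "ODPC", SVMConfig.reduced(),
                       n_subsets=10, seed=1, selection_max_prefix=100)
records = predict(model, pos, tp=0.5)
```

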