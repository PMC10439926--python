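# mitopath

Pathogenicity scoring for mitochondrial missense variants: an
imbalance-aware bagged KNN classifier with nested cross-validated model
selection, Bayesian calibration of scores into posterior pathogenicity
probabilities and five clinical classes, and Moran's I / LISA spatial
autocorrelation to localize fragile protein regions.

## Who this is for

Groups building or evaluating meta-predictors for mtDNA missense variants:
the package consumes per-variant feature tables (conservation scores,
component-predictor outputs, structural/positional features), curated
variant annotation tables (status, ACMG criteria codes, allele frequencies)
and PDB structures, and produces scores, calibrated probabilities, clinical
classes, and per-residue risk maps. A seeded synthetic-data module generates
corpus-shaped fixtures so every stage is testable without external
downloads.

## The method in brief

**Classifier.** Pathogenic training variants are rare (~7.5%), so each of
n bagged base learners is balanced internally: bootstrap the rows, randomly
under-sample the neutral majority to a ratio rho_r, SMOTE the pathogenic
minority to exact balance, then fit a KNN on a random ceil(rho_f·F)-feature
subset. The score of a variant is the mean positive-class vote fraction
over learners, in [0, 1]. Defaults (k = 3 neighbors, inverse-distance
weights, rho_r = rho_f = 1/4, 200 learners) are the grid-search optimum.
Out-of-bag (OOB) scores — averaging only learners whose bootstrap excluded
a row — give honest training-set scores for free.

**Calibration.** Class-conditional score densities are maximum-likelihood
Beta fits: f1 to OOB scores of pathogenic variants, f0 to a benign
reference. With prior P(C=1) = 0.1,

    P(C=1 | y) = f1(y) pi / (f1(y) pi + f0(y)(1 - pi)),

binned as benign (P <= 0.001), likely benign (<= 0.1), VUS, likely
pathogenic (>= 0.9), pathogenic (>= 0.99); monotonicity of the posterior is
checked, and each cutpoint is inverted to a score threshold by bisection.

**Spatial analysis.** Per-residue mean scores on CA coordinates, learners
using X/Y/Z features dropped first. Global Moran's I = Z'WZ (weights
d^-2 or binary within a cutoff radius, normalized to total 1; permutation
p-values; E[I] = -1/(N-1)); LISA decomposes I into per-site contributions
with BH-corrected permutation p-values, and contiguous high/low-risk runs
are reported.

## Worked example

```bash
mitopath simulate --out data.tsv --seed 3
mitopath train --dataset data.tsv --model-out model --n-learners 100 --seed 3
mitopath predict --model model --features features.tsv --out scores.tsv
```

`simulate` prints:

```
wrote 1874 variants x 22 features to data.tsv
```

i.e. a corpus-shaped table: 1874 variants, 140 labeled pathogenic, 22
features (5 informative, 14 noise, X/Y/Z helix coordinates) with 0.2-1%
missing cells per feature. `train` standardizes, imputes, drops features
under 1% information gain, fits the ensemble and prints:

```
trained 100 learners on 1874 variants
```

`predict` writes a TSV of `variant_id, score`; adding
`--calibration cal.json` (from `mitopath calibrate`) appends the posterior
probability and the five-way class. A full nested cross-validation of the
method on this synthetic corpus (`mitopath evaluate`) yields a mean test
auROC of ~0.93 and auPRC of ~0.65 (seed 1): the ensemble finds the five
informative features through the noise at 7.5% prevalence, and
label-permuted controls sit at chance (auROC ~0.5).

Python API mirrors the CLI: see `mitopath.ensemble.train_knn_rus_smote`,
`mitopath.evaluate.nested_cv`, `mitopath.calibrate.fit_calibration`,
`mitopath.spatial.morans_I`.

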