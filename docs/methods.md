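# Methods

## The problem

Missense variants in the 13 mtDNA-encoded OXPHOS proteins are hard to
interpret: curated pathogenic examples are rare (~7.5% of a curated corpus),
annotations are heterogeneous, and allele frequency alone cannot separate
pathogenic from benign because heteroplasmy, haplogroup effects and
synergistic variants confound it. `mitopath` implements a meta-predictor for
this setting: it consumes precomputed per-variant features (conservation
scores, component-predictor outputs, structural and positional features) and
learns a pathogenicity score, then calibrates that score into a posterior
probability and five clinical classes, and finally asks where on the protein
structures the predicted risk concentrates.

## Dataset construction

The training corpus pairs a "general" population variant list (candidate
neutrals) with a "disease" list (confirmed or reported pathogenic
candidates). Filters: variants on both lists are dropped from both; neutrals
additionally lose carriers of the ACMG rarity code PM2 (rare enough to
*support* pathogenicity, hence suspect as neutrals); synergistic or
conflicting variants never enter either class. Specificity sets are drawn
from population databases by requiring allele frequency at or above a
threshold (default 0.002%, i.e. 2e-5 as a fraction) in **both** homoplasmic
and heteroplasmic states, minus training overlaps. Variant identity is
nucleotide-level: (position, ref, alt) on NC_012920.1.

## Preprocessing

All preprocessing is fit on training rows only and replayed on held-out
rows, inside every cross-validation fold:

1. **Scaling** to zero mean, unit variance, with the population (biased)
   standard deviation. Constant features are flagged and map to 0.
2. **Imputation.** Five strategies are available: per-feature mean and
   median, k-nearest-neighbor (k = 5, Euclidean over co-observed features),
   and two round-robin iterative imputers regressing each feature on the
   others (Bayesian ridge; random forest with 100 trees). Iterative
   settings: mean initialization, features ordered by descending
   missingness, tolerance 1e-3 on the maximum change, at most 10 rounds.
3. **Feature selection** by a single unpruned Gini decision tree on the
   training fold; features explaining less than 1% of the total normalized
   information gain are dropped (if nothing survives, the single best
   feature is kept with a warning).

### Imputer benchmark

To pick an imputer empirically, a complete corpus is split into 20 folds;
each imputer is fit on 19 and evaluated on the held-out fold after masking
cells at rates controlled by a multiplier c in 0.25–3.00 (step 0.25): a
uniform draw U per cell is masked iff c·U < p_f, where p_f is the feature's
a-priori missing probability, so the expected masked fraction is
min(1, p_f/c). The error metric is the NRMSE, E[(X_true − X_imp)²]/V[X_true]
(note: no square root, following the defining formula), computed per feature
over its masked cells and averaged across features with masked-cell-count
weights so wide-scale features cannot dominate.

One convention matters here: masked cells are pooled **across folds** before
the ratio is taken, giving one NRMSE per (imputer, multiplier). Per-fold
ratios are unusable at small fold sizes — a feature with k ≤ 3 masked cells
has a variance estimate whose reciprocal has divergent expectation, and we
observed fold-mean NRMSE in the hundreds for the mean imputer where the
analytic value is 1. With pooling, the mean imputer scores ≈ 1 by
construction and correlated corpora let the iterative imputers win, as
theory predicts.

## The classifier

The reference method is a bagging ensemble whose base learners are
K-nearest-neighbor classifiers, balanced inside each bootstrap:

1. bootstrap the training rows with replacement at the original size;
2. random under-sampling (RUS) of the neutral majority down to a
   minority/majority ratio rho_r;
3. SMOTE over-sampling of the pathogenic minority to exact balance — each
   synthetic point is x + u·(x_nn − x), u ~ U[0,1), x_nn one of the k = 5
   nearest minority neighbors;
4. fit a KNN on ceil(rho_f · F) features sampled without replacement.

Defaults are the grid-search optimum: 3 neighbors, inverse-distance
weighting, rho_r = rho_f = 1/4, 200 learners for production models. SMOTE
interpolates in the full selected-feature space by default (balance first,
subset second); a switch moves it after subsetting. The ensemble score is
the mean positive-class neighbor-vote fraction over learners; a zero
distance gives that neighbor the whole vote (exact duplicates split it).
Every learner draws its randomness from a per-learner stream spawned from
one root seed, so growing the ensemble never reshuffles earlier learners.

The **out-of-bag (OOB) score** of a training variant averages only learners
whose bootstrap excluded it (≈ 1/e of the ensemble, ~74 of 200 learners);
rows covered by every bootstrap fall back to the full-ensemble score and are
flagged.

Four comparison classifiers share the evaluation harness: an RBF-kernel SVM
with frequency-balanced class weights, balanced bagging of Gaussian naive
Bayes and of KNN (per-learner RUS to exact balance, bootstrapped rows and
features), and a balanced random forest (per-tree balanced bootstrap).

## Evaluation protocol

Model selection uses stratified 20-fold cross-validation repeated five times
(100 test folds), with a stratified 10-fold grid search inside every outer
training fold; with d grid points that is 100·(10·d + 1) fits per method.
The inner selection metric is auPRC (the imbalance-appropriate choice; a
switch selects auROC). Preprocessing is re-fitted per outer fold, so no
held-out row influences scaling, imputation, feature selection or tuning —
the harness records an audit per fold and the test suite proves the property
by spying on every fitting entry point. auROC is trapezoidal; auPRC uses
step-wise (average-precision) interpolation.

Misclassification rates split scores at the median of a reference
whole-corpus score distribution, recalculated per test fold. The rates are a
property of that distribution's shape: on the synthetic benchmark the
neutral-class score distribution is unimodal, so its own median necessarily
strands a large fraction of neutrals above threshold — the statistic is
faithful, the synthetic score histogram simply is not the (heavily
right-skewed) real one. Specificity on benign-only sets is a 1-df chi-square
against a background non-benign frequency; score-shift comparisons use a
one-sided Mann-Whitney U.

The learning-curve harness trains on historical snapshot datasets, tests on
stratified partitions of a final corpus after purging any partition variant
from the snapshot, and summarizes the trend with Pearson's r over (year,
mean auROC).

## Calibration

Class-conditional score densities are Beta distributions fitted by
maximum likelihood (Nelder-Mead on log-parameters, method-of-moments
initialization, tolerance 1e-8, scores clipped to [1e-6, 1 − 1e-6] because
the densities diverge at the boundary). The pathogenic density fits OOB
scores of pathogenic training variants; the benign density fits an
independent benign reference, substituting OOB scores where a reference
variant also sits in training. With prior P(C=1) = 0.1,

    P(C=1|y) = f1(y)·0.1 / (f1(y)·0.1 + f0(y)·0.9)

and the five classes are: benign P ≤ 0.001 < likely benign ≤ 0.1 < VUS <
0.9 ≤ likely pathogenic < 0.99 ≤ pathogenic. Posterior monotonicity is
*checked* on a 10^4-point grid, not assumed — two Beta fits need not give a
monotone likelihood ratio, and a non-monotone posterior fails loudly instead
of being silently inverted. Each posterior cutpoint is then inverted to a
score threshold by bisection to 1e-6; unattainable cutpoints are reported as
such.

## Spatial autocorrelation

Scores are averaged per residue (CA atom locates the residue); multiple
structures are rigidly placed along the (1,1,1)/sqrt(3) bisector of 3D
space, 3d = 60 Å apart, so distance-based statistics see them as separate
clusters. Before any spatial analysis, base learners trained on any of the
X/Y/Z coordinate features are dropped and the corpus rescored, removing
positional circularity; the high/low-risk threshold is the median of the
rescored corpus.

Global Moran's I uses weights w_ij = d_ij^-2 (quadratic decay, prioritizing
short-range structure) or a binary cutoff matrix (1 − 1e-6 within radius r,
1e-6 outside — the epsilon keeps rows normalizable). Weights are
row-normalized then globally renormalized to total 1, after which
I = Z'WZ with Z the population-standardized scores; this equals the
textbook N/ΣΣw prefactor form, which the tests assert to 1e-9 against a
brute-force double loop. One-sided p-values come from score permutations
(10^4 by default; 10^3 for cutoff scans and LISA) with the add-one
estimator, never exactly zero; E[I] = −1/(N−1).

LISA decomposes I as l = Z ∘ (WZ), Σ l_i = I. Each site's p-value compares
its observed l_i with its own total-permutation distribution (conditional
permutation, holding site i fixed, is available as an option);
Benjamini-Hochberg controls the FDR across sites, per protein complex by
default, with significance at q < 0.01. Contiguous same-label runs of
residues at/above vs below the score threshold are emitted as high/low-risk
regions.

## Synthetic benchmark

The generator mirrors the curated corpus's shape: 1874 variants, exactly
140 pathogenic, 22 features = 5 informative + 14 noise + 3 spatial
coordinates (sampled from a toy helix so spatial-learner exclusion is
testable end to end), per-feature MCAR missingness drawn from 0.2–1%.
Informative features are class-conditional Gaussians separated by 1.5
within-class SDs and correlated through a shared latent factor (loading
0.3); this effect size is chosen so the corpus's ideal separability
(auROC ≈ 0.95 for the pooled informative block) matches what strongly
informative conservation/predictor panels achieve on real curated corpora.
Noise features are class-independent. The toy structure generator produces
ideal alpha-helical CA traces (rise 1.5 Å, 100°/residue, radius 2.3 Å;
consecutive-CA distance ≈ 3.8 Å) or straight lines, carrying a logistic
ramp or Gaussian patch score field of known smoothness plus Gaussian noise,
with the noise-free high-risk mask returned as ground truth.

What the synthetic data does *not* emulate: realistic mtDNA mutational
spectra, haplogroup structure, feature-specific (non-Gaussian, bounded)
score distributions, missingness that is informative rather than MCAR, and
the strongly right-skewed whole-genome score histogram. Passing tests
therefore demonstrate correctness of the machinery and calibration of its
statistics, not clinical performance on real variants.

## Problem sizes and numerical choices

- Nested CV in the test suite runs the full 20-fold × 5-repeat protocol
  with a 2-point grid and 30 base learners per ensemble; the
  label-permutation null uses one repeat and a singleton grid (the null
  does not depend on the repetition protocol). The acceptance script runs
  20 folds × 1 repeat. 200 learners remain the production default; 30 is
  the harness's choice to keep the full protocol tractable, and mean
  imputation is the harness default because benchmark missingness is
  0.2–1% MCAR (the iterative random-forest imputer is exercised separately
  in the imputer benchmark).
- Bootstraps lacking a class are redrawn (at most 100 attempts).
- Ties in grid search go to the first combination in grid order.
- Confidence intervals on fold metrics are normal approximations over the
  100 fold values.
- PDB altloc handling: highest occupancy, first-listed on ties; residues
  without a CA are skipped with a warning.

## Known limitations

- The package consumes features; it does not compute conservation scores,
  component predictions or fold-stability changes.
- Calibration quality depends on the benign reference being representative;
  with few pathogenic training variants the pathogenic Beta fit is wide and
  the pathogenic (P ≥ 0.99) threshold may be unattainable.
- The binary-cutoff LISA at very small radii has few neighbors per site and
  a coarse permutation distribution; with 10^3 permutations and BH at
  q < 0.01, discoveries at such radii require many tied minimum p-values.
  The quadratic-decay weighting is the primary analysis.
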