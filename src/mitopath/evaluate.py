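"""Model selection and evaluation: stratified repeated nested cross-validation
with an inner grid search, ranking metrics, misclassification and specificity
analyses, and the time-dependent learning-curve harness.

The outer loop is a stratified 20-fold split repeated five times (100 test
folds); within every outer training fold the full preprocessing chain
(scaling, imputation, information-gain feature selection) is re-fitted and a
stratified 10-fold grid search picks hyperparameters, so no held-out row ever
influences preprocessing or tuning. With d grid points the inner search costs
10*d fits and the final refit one more, i.e. 100*(10*d + 1) fits per method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from mitopath.datamodel import LabeledDataset
from mitopath.ensemble import make_method
from mitopath.preprocess import (
    apply_scaler,
    fit_imputer,
    fit_scaler,
    select_features,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Row-index folds of a stratified (optionally repeated) k-fold split."""

    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx) pairs
    k: int
    repeats: int
    seed: int


def stratified_kfold(
    labels: Sequence[int], k: int, seed: int, repeats: int = 1
) -> FoldPlan:
    """Stratified k-fold partition preserving the class ratio per fold.

    Each repeat is an independent seeded shuffle. Per-fold class counts
    differ from exact proportionality by at most one row. Fatal if any class
    has fewer than k members.
    """
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y)
    if (counts[counts > 0] < k).any():
        raise ValueError(
            f"every class needs >= k={k} members; class counts {counts.tolist()}"
        )
    folds = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        folds.extend((tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(y)), y))
    return FoldPlan(folds=folds, k=k, repeats=repeats, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricSet:
    auroc: float
    auprc: float
    sensitivity: float
    specificity: float
    threshold: float = 0.5


def compute_metrics(
    y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricSet:
    """Ranking and threshold metrics for one scored set.

    auROC is the trapezoidal area under the ROC curve; auPRC uses step-wise
    (average-precision) interpolation, which avoids the optimistic linear
    interpolation of precision. A score >= threshold calls a positive.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("metrics undefined: y_true contains a single class")
    pred = s >= threshold
    sens = float(pred[y == 1].mean())
    spec = float((~pred[y == 0]).mean())
    return MetricSet(
        auroc=float(roc_auc_score(y, s)),
        auprc=float(average_precision_score(y, s)),
        sensitivity=sens,
        specificity=spec,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    best_params: dict
    records: pd.DataFrame  # one row per combination: mean auPRC / auROC
    n_fits: int


def grid_search(
    train: LabeledDataset,
    grid: Sequence[Mapping],
    method: str,
    seed: int,
    inner_k: int = 10,
    selection_metric: str = "auprc",
) -> GridSearchResult:
    """Stratified inner-CV hyperparameter search.

    Every combination is scored by its mean inner-CV auPRC (auROC recorded
    secondarily); ties go to the first combination in grid order. Costs
    ``inner_k * len(grid)`` fits.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if selection_metric not in ("auprc", "auroc"):
        raise ValueError("selection_metric must be 'auprc' or 'auroc'")
    X = train.table.matrix()
    y = train.y
    plan = stratified_kfold(y, inner_k, seed)
    rows = []
    n_fits = 0
    for params in grid:
        aurocs, auprcs = [], []
        for tr_idx, te_idx in plan.folds:
            model = make_method(method, dict(params), rng_seed=seed)
            model.fit(X[tr_idx], y[tr_idx])
            n_fits += 1
            s = model.predict_score(X[te_idx])
            m = compute_metrics(y[te_idx], s)
            aurocs.append(m.auroc)
            auprcs.append(m.auprc)
        rows.append(
            {"params": dict(params), "auprc": float(np.mean(auprcs)),
             "auroc": float(np.mean(aurocs))}
        )
    records = pd.DataFrame(rows)
    best_i = int(records[selection_metric].to_numpy().argmax())  # first on ties
    return GridSearchResult(
        best_params=rows[best_i]["params"], records=records, n_fits=n_fits
    )


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldAudit:
    """Which rows preprocessing and tuning saw, per outer fold."""

    test_ids: frozenset
    fitted_on_ids: frozenset  # union of ids used by scaler/imputer/selector/GS

    @property
    def leaked(self) -> frozenset:
        return self.test_ids & self.fitted_on_ids


@dataclass
class MethodResult:
    name: str
    fold_metrics: list[MetricSet]
    fold_scores: list[pd.Series]  # test-fold scores indexed by variant id
    fold_labels: list[pd.Series]
    best_params: list[dict]
    n_fits: int

    def mean_metric(self, which: str) -> float:
        return float(np.mean([getattr(m, which) for m in self.fold_metrics]))

    def ci95(self, which: str) -> tuple[float, float]:
        vals = np.array([getattr(m, which) for m in self.fold_metrics])
        half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals))
        return (float(vals.mean() - half), float(vals.mean() + half))


@dataclass
class NestedCVResult:
    methods: dict[str, MethodResult]
    audits: list[FoldAudit]
    winner: str

    def assert_no_leakage(self) -> None:
        for i, audit in enumerate(self.audits):
            if audit.leaked:
                raise AssertionError(
                    f"outer fold {i}: test rows reached preprocessing/tuning: "
                    f"{sorted(audit.leaked)[:5]}"
                )


@dataclass
class PipelineConfig:
    """Per-fold preprocessing choices for the evaluation harness."""

    imputer: str = "mean"
    selection_threshold: float = 0.01
    selection_metric: str = "auprc"
    inner_k: int = 10


def _preprocess_fold(
    train: LabeledDataset,
    test: LabeledDataset,
    cfg: PipelineConfig,
    seed: int,
) -> tuple[LabeledDataset, LabeledDataset]:
    scaler = fit_scaler(train.table)
    train_t = apply_scaler(scaler, train.table)
    test_t = apply_scaler(scaler, test.table)
    imputer = fit_imputer(train_t, cfg.imputer, rng_seed=seed)
    train_t = imputer.transform(train_t)
    test_t = imputer.transform(test_t)
    report = select_features(
        LabeledDataset(train_t, train.labels), cfg.selection_threshold, rng_seed=seed
    )
    return (
        LabeledDataset(train_t.subset_features(report.kept), train.labels),
        LabeledDataset(test_t.subset_features(report.kept), test.labels),
    )


def nested_cv(
    dataset: LabeledDataset,
    methods: Mapping[str, Sequence[Mapping]],
    seed: int = 0,
    outer_k: int = 20,
    repeats: int = 5,
    config: PipelineConfig | None = None,
) -> NestedCVResult:
    """Repeated stratified nested cross-validation over one or more methods.

    ``methods`` maps a method name (``knn_rus_smote`` or a baseline kind) to
    its hyperparameter grid. The winner is the method with the highest mean
    test auROC across all outer folds and repeats.
    """
    cfg = config or PipelineConfig()
    dataset.require_both_classes()
    ids = np.array(dataset.table.variant_ids)
    plan = stratified_kfold(dataset.y, outer_k, seed, repeats=repeats)

    results = {
        name: MethodResult(name, [], [], [], [], 0) for name in methods
    }
    audits: list[FoldAudit] = []
    for fold_i, (tr_idx, te_idx) in enumerate(plan.folds):
        train = dataset.subset_rows(ids[tr_idx])
        test = dataset.subset_rows(ids[te_idx])
        fold_seed = seed * 100_003 + fold_i
        train_p, test_p = _preprocess_fold(train, test, cfg, fold_seed)
        audits.append(
            FoldAudit(
                test_ids=frozenset(ids[te_idx]),
                fitted_on_ids=frozenset(ids[tr_idx]),
            )
        )
        for name, grid in methods.items():
            gs = grid_search(
                train_p, grid, name, fold_seed,
                inner_k=cfg.inner_k, selection_metric=cfg.selection_metric,
            )
            model = make_method(name, dict(gs.best_params), rng_seed=fold_seed)
            model.fit(train_p.table.matrix(), train_p.y)
            scores = model.predict_score(test_p.table.matrix())
            res = results[name]
            res.n_fits += gs.n_fits + 1
            res.best_params.append(gs.best_params)
            res.fold_metrics.append(compute_metrics(test.y, scores))
            res.fold_scores.append(pd.Series(scores, index=ids[te_idx]))
            res.fold_labels.append(pd.Series(test.y, index=ids[te_idx]))
    winner = max(results, key=lambda n: results[n].mean_metric("auroc"))
    return NestedCVResult(methods=results, audits=audits, winner=winner)


# ---------------------------------------------------------------------------
# misclassification and specificity
# ---------------------------------------------------------------------------

def misclassification(
    fold_scores: Sequence[pd.Series],
    fold_labels: Sequence[pd.Series],
    reference_scores: Sequence[float] | Sequence[Sequence[float]],
) -> tuple[float, float]:
    """Median-split per-class misclassification rates over test folds.

    The pathogenic/benign threshold is the median of the reference score
    distribution (a whole-corpus score collection), recalculated per test
    fold when a per-fold list is supplied. Returns (rate of true pathogenic
    variants scored below threshold, rate of true neutral variants scored at
    or above it).
    """
    per_fold_ref = (
        len(reference_scores) == len(fold_scores)
        and not np.isscalar(reference_scores[0])
        and hasattr(reference_scores[0], "__len__")
    )
    miss_pos = n_pos = miss_neg = n_neg = 0
    for i, (s, y) in enumerate(zip(fold_scores, fold_labels)):
        ref = reference_scores[i] if per_fold_ref else reference_scores
        thr = float(np.median(np.asarray(ref, dtype=float)))
        sv, yv = s.to_numpy(dtype=float), y.to_numpy(dtype=int)
        miss_pos += int(((yv == 1) & (sv < thr)).sum())
        n_pos += int((yv == 1).sum())
        miss_neg += int(((yv == 0) & (sv >= thr)).sum())
        n_neg += int((yv == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("pooled folds must contain both classes")
    return miss_pos / n_pos, miss_neg / n_neg


def specificity_test(
    n_benign: int, n_nonbenign: int, background_nonbenign_freq: float
) -> tuple[float, float]:
    """One-degree-of-freedom chi-square test of a benign/non-benign split.

    The null expects ``background_nonbenign_freq`` of the N calls to be
    non-benign; the alternative is an excess of benign calls in the set
    under test. Expected counts must be >= 5.
    """
    n = n_benign + n_nonbenign
    e_non = n * background_nonbenign_freq
    e_ben = n - e_non
    if e_non <= 0 or e_ben <= 0:
        raise ValueError("expected counts must be positive")
    if min(e_non, e_ben) < 5:
        raise ValueError(
            f"chi-square approximation needs expected counts >= 5 "
            f"(got {e_ben:.1f} benign, {e_non:.1f} non-benign)"
        )
    chi2 = (n_benign - e_ben) ** 2 / e_ben + (n_nonbenign - e_non) ** 2 / e_non
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def compare_scores(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of 'a stochastically lower than b'."""
    res = stats.mannwhitneyu(a, b, alternative="less")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# time-dependent learning curve
# ---------------------------------------------------------------------------

@dataclass
class LearningCurveResult:
    per_year_auroc: pd.Series  # index: snapshot year, value: mean auROC
    pearson_r: float | None
    pearson_p: float | None


def learning_curve(
    snapshots: Mapping[int, LabeledDataset],
    final_test: LabeledDataset,
    seed: int = 0,
    method: str = "knn_rus_smote",
    grid: Sequence[Mapping] = ({},),
    n_partitions: int = 5,
    config: PipelineConfig | None = None,
) -> LearningCurveResult:
    """Performance of models trained on successive historical snapshots.

    The final test set is split into ``n_partitions`` stratified partitions.
    For every partition and snapshot, variants already present in the
    partition are removed from the snapshot (no leakage), a grid search picks
    hyperparameters, the model is trained and the partition scored. Per-year
    auROC is the mean over partitions; Pearson's r over (year, mean auROC)
    summarizes the trend (undefined with fewer than 3 years).
    """
    cfg = config or PipelineConfig()
    years = sorted(snapshots)
    test_ids = np.array(final_test.table.variant_ids)
    plan = stratified_kfold(final_test.y, n_partitions, seed)
    aurocs: dict[int, list[float]] = {yr: [] for yr in years}
    for part_i, (_, part_idx) in enumerate(plan.folds):
        partition = final_test.subset_rows(test_ids[part_idx])
        part_id_set = set(partition.table.variant_ids)
        for yr in years:
            snap = snapshots[yr]
            keep = [v for v in snap.table.variant_ids if v not in part_id_set]
            if not keep:
                logger.warning("snapshot %d emptied by overlap with partition %d", yr, part_i)
                continue
            train = snap.subset_rows(keep)
            try:
                train.require_both_classes()
            except ValueError:
                logger.warning("snapshot %d single-class after overlap removal", yr)
                continue
            fold_seed = seed * 99_991 + part_i
            train_p, test_p = _preprocess_fold(train, partition, cfg, fold_seed)
            gs = grid_search(train_p, grid, method, fold_seed,
                             inner_k=cfg.inner_k, selection_metric=cfg.selection_metric)
            model = make_method(method, dict(gs.best_params), rng_seed=fold_seed)
            model.fit(train_p.table.matrix(), train_p.y)
            scores = model.predict_score(test_p.table.matrix())
            aurocs[yr].append(compute_metrics(partition.y, scores).auroc)
    per_year = pd.Series(
        {yr: float(np.mean(v)) for yr, v in aurocs.items() if v}, dtype=float
    ).sort_index()
    if len(per_year) >= 3:
        r, p = stats.pearsonr(per_year.index.to_numpy(float), per_year.to_numpy())
        r, p = float(r), float(p)
    else:
        r = p = None
    return LearningCurveResult(per_year_auroc=per_year, pearson_r=r, pearson_p=p)
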