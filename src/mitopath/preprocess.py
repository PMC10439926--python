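"""Preprocessing: train-fitted scaling, imputation, the missingness-injection
NRMSE benchmark used to choose an imputer, and information-gain feature
selection.

All steps are fit on training rows only and then applied to held-out rows,
so they can be re-fitted inside every cross-validation fold without leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer, SimpleImputer
from sklearn.linear_model import BayesianRidge
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeClassifier

from mitopath.datamodel import FeatureTable, LabeledDataset

logger = logging.getLogger(__name__)

IMPUTER_KINDS = ("mean", "median", "knn5", "iterative_linear", "iterative_forest")

DEFAULT_MULTIPLIERS = tuple(np.arange(0.25, 3.01, 0.25))


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Per-feature mean and population standard deviation from training rows."""

    mean: pd.Series
    std: pd.Series
    constant_features: frozenset = frozenset()


def fit_scaler(train: FeatureTable) -> ScalerParams:
    """Estimate zero-mean/unit-variance parameters on training rows.

    Uses the population (biased) standard deviation. A feature with no
    observed training value is fatal; a constant feature is flagged and will
    map to zero under :func:`apply_scaler`.
    """
    values = train.values
    n_obs = values.notna().sum(axis=0)
    empty = n_obs[n_obs == 0].index.tolist()
    if empty:
        raise ValueError(f"features entirely missing in training rows: {empty}")
    mean = values.mean(axis=0)
    std = values.std(axis=0, ddof=0)
    constant = frozenset(std.index[std == 0.0])
    if constant:
        logger.warning("constant features flagged: %s", sorted(constant))
    return ScalerParams(mean=mean, std=std, constant_features=constant)


def apply_scaler(params: ScalerParams, table: FeatureTable) -> FeatureTable:
    """Standardize a table with training-fitted parameters.

    Missing cells stay missing; constant features map to 0.
    """
    std = params.std.replace(0.0, 1.0)
    scaled = (table.values - params.mean) / std
    for name in params.constant_features:
        observed = table.values[name].notna()
        scaled.loc[observed, name] = 0.0
    return table.with_values(scaled)


def unscale(params: ScalerParams, table: FeatureTable) -> FeatureTable:
    """Invert :func:`apply_scaler` (constant features return to their mean)."""
    std = params.std.replace(0.0, 1.0)
    raw = table.values * std + params.mean
    return table.with_values(raw)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def _make_imputer(kind: str, rng_seed: int | None):
    if kind == "mean":
        return SimpleImputer(strategy="mean")
    if kind == "median":
        return SimpleImputer(strategy="median")
    if kind == "knn5":
        return KNNImputer(n_neighbors=5)
    if kind == "iterative_linear":
        return IterativeImputer(
            estimator=BayesianRidge(),
            initial_strategy="mean",
            imputation_order="descending",
            tol=1e-3,
            max_iter=10,
            random_state=rng_seed,
        )
    if kind == "iterative_forest":
        return IterativeImputer(
            estimator=RandomForestRegressor(n_estimators=100, random_state=rng_seed),
            initial_strategy="mean",
            imputation_order="descending",
            tol=1e-3,
            max_iter=10,
            random_state=rng_seed,
        )
    raise ValueError(f"unknown imputer kind {kind!r}; choose from {IMPUTER_KINDS}")


@dataclass
class FittedImputer:
    """An imputer fit on training rows, applicable to new tables."""

    kind: str
    _imputer: object
    _feature_names: list[str]

    def transform(self, table: FeatureTable) -> FeatureTable:
        if table.feature_names != self._feature_names:
            raise ValueError("feature roster differs from the fitted table")
        values = table.values
        if values.notna().to_numpy().all():
            return table.copy()
        all_missing = values.isna().all(axis=1)
        if all_missing.any():
            logger.warning(
                "%d rows with every feature missing filled from feature means",
                int(all_missing.sum()),
            )
        filled = self._imputer.transform(values.to_numpy(dtype=float))
        out = pd.DataFrame(filled, index=values.index, columns=values.columns)
        # observed cells are authoritative; guard against estimator drift
        observed = values.notna()
        out = out.where(~observed, values)
        return table.with_values(out)


def fit_imputer(train: FeatureTable, kind: str, rng_seed: int | None = None) -> FittedImputer:
    """Fit an imputer of the requested kind on training rows.

    Kinds: mean, median, knn5 (k=5 Euclidean donors over co-observed
    features), iterative_linear (round-robin Bayesian-ridge regressions),
    iterative_forest (round-robin random-forest regressions, 100 trees).
    """
    values = train.values
    if (values.notna().sum(axis=0) == 0).any():
        raise ValueError("every feature needs at least one observed training value")
    imputer = _make_imputer(kind, rng_seed)
    imputer.fit(values.to_numpy(dtype=float))
    return FittedImputer(kind, imputer, train.feature_names)


def impute(table: FeatureTable, kind: str, rng_seed: int | None = None) -> FeatureTable:
    """Fit on the table itself and fill its missing cells."""
    return fit_imputer(table, kind, rng_seed).transform(table)


# ---------------------------------------------------------------------------
# missingness injection and NRMSE
# ---------------------------------------------------------------------------

@dataclass
class MissingnessProfile:
    """A-priori per-feature missing probabilities."""

    p: pd.Series

    def __post_init__(self) -> None:
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("missing probabilities must lie in [0, 1]")

    @classmethod
    def from_table(cls, table: FeatureTable) -> "MissingnessProfile":
        return cls(table.values.isna().mean(axis=0))


def inject_missingness(
    table: FeatureTable,
    profile: MissingnessProfile,
    multiplier: float,
    rng_seed: int,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Mask cells of a complete table at rates scaled by ``multiplier``.

    A uniform draw U in [0,1) is made per cell and multiplied by the
    multiplier c; the cell is masked iff c*U < p_f, so the expected masked
    fraction per feature is min(1, p_f / c). Returns the masked table and the
    boolean mask.
    """
    if multiplier <= 0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    if table.n_missing():
        raise ValueError("injection requires a complete table")
    rng = np.random.default_rng(rng_seed)
    u = rng.random(table.shape)
    p = profile.p.reindex(table.feature_names).to_numpy(dtype=float)
    mask = (multiplier * u) < p[np.newaxis, :]
    mask_df = pd.DataFrame(mask, index=table.values.index, columns=table.values.columns)
    masked = table.values.mask(mask_df)
    return table.with_values(masked), mask_df


def nrmse(truth: FeatureTable, imputed: FeatureTable, mask: pd.DataFrame) -> float:
    """Normalized imputation error over masked cells.

    Per feature: mean squared error of imputed vs true masked cells, divided
    by the population variance of the masked true values; features are then
    averaged with weights proportional to their masked-cell counts. Features
    whose masked truths are constant carry no variance information and are
    skipped; if every masked feature is degenerate the call is fatal.
    """
    if not mask.to_numpy().any():
        raise ValueError("empty mask: nothing to score")
    errors, weights = [], []
    n_degenerate = 0
    for name in truth.feature_names:
        m = mask[name].to_numpy()
        if not m.any():
            continue
        x_true = truth.values[name].to_numpy(dtype=float)[m]
        x_imp = imputed.values[name].to_numpy(dtype=float)[m]
        var = float(np.var(x_true))
        if var == 0.0:
            n_degenerate += 1
            continue
        errors.append(float(np.mean((x_true - x_imp) ** 2)) / var)
        weights.append(m.sum())
    if not errors:
        raise ValueError(
            f"all {n_degenerate} masked features have constant true values; "
            "NRMSE undefined"
        )
    return float(np.average(errors, weights=weights))


# ---------------------------------------------------------------------------
# imputer benchmark
# ---------------------------------------------------------------------------

@dataclass
class NRMSEReport:
    """Per-imputer, per-multiplier NRMSE grid."""

    scores: pd.DataFrame  # index: imputer kind, columns: multiplier
    winner: str

    def mean_by_imputer(self) -> pd.Series:
        return self.scores.mean(axis=1)

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = "imputer"
        out.to_csv(path, sep="\t")


def benchmark_imputers(
    corpus: FeatureTable,
    n_folds: int = 20,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
    rng_seed: int = 0,
    kinds: Sequence[str] = IMPUTER_KINDS,
    profile: MissingnessProfile | None = None,
) -> NRMSEReport:
    """Cross-validated imputer comparison by injected-missingness NRMSE.

    Rows with missing values are dropped to obtain a complete truth corpus,
    which is split into ``n_folds`` folds. For each fold, each imputer is fit
    on the other folds; the held-out fold is masked once per multiplier
    (fresh uniform draws each time, seeded) and imputed. Masked cells are
    pooled across folds, so each (imputer, multiplier) cell of the report is
    one NRMSE over the whole corpus — per-fold variance ratios over a
    handful of masked cells would be numerically unstable. The winner is the
    imputer with the lowest mean NRMSE across multipliers.

    The a-priori missingness profile defaults to the corpus's own observed
    missing fractions (computed before dropping incomplete rows).
    """
    if profile is None:
        profile = MissingnessProfile.from_table(corpus)
    complete = corpus.values.dropna(axis=0, how="any")
    if len(complete) < n_folds:
        raise ValueError(
            f"complete corpus has {len(complete)} rows < n_folds={n_folds}"
        )
    full = FeatureTable(complete, corpus.feature_groups, corpus.spatial_flags)

    ss = np.random.SeedSequence(rng_seed)
    fold_seed, mask_root = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)

    # corpus-wide accumulators: one mask and one imputed matrix per
    # (multiplier, kind), filled fold by fold
    mask_all = [pd.DataFrame(False, index=full.values.index, columns=full.values.columns)
                for _ in multipliers]
    imp_all = {k: [full.values.copy() for _ in multipliers] for k in kinds}
    row_ids = np.array(full.variant_ids)
    for fold_i, (train_idx, test_idx) in enumerate(kf.split(row_ids)):
        train = full.subset_rows(row_ids[train_idx])
        test = full.subset_rows(row_ids[test_idx])
        fitted = {k: fit_imputer(train, k, rng_seed=fold_seed + fold_i) for k in kinds}
        for m_i, mult in enumerate(multipliers):
            mask_seed = int(
                np.random.SeedSequence([mask_root, fold_i, m_i]).generate_state(1)[0]
                % 2**31
            )
            masked, mask = inject_missingness(test, profile, mult, mask_seed)
            mask_all[m_i].loc[mask.index] = mask
            if not mask.to_numpy().any():
                continue
            for k in kinds:
                imp_all[k][m_i].loc[mask.index] = fitted[k].transform(masked).values
    scores = pd.DataFrame(
        {mult: {k: nrmse(full, full.with_values(imp_all[k][m_i]), mask_all[m_i])
                for k in kinds}
         for m_i, mult in enumerate(multipliers)}
    )
    winner = scores.mean(axis=1).idxmin()
    return NRMSEReport(scores=scores, winner=str(winner))


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureSelectionReport:
    gains: pd.Series           # normalized information gain, sums to 1
    kept: list[str] = field(default_factory=list)
    threshold: float = 0.01


def select_features(
    train: LabeledDataset,
    threshold: float = 0.01,
    rng_seed: int = 0,
) -> FeatureSelectionReport:
    """Information-gain feature selection with a single decision tree.

    Fits one unpruned Gini decision tree on the (scaled, imputed) training
    set and keeps features whose normalized impurity-based importance is at
    least ``threshold`` (default 1% of the total information gain). If no
    feature clears the threshold the single best one is kept with a warning.
    Selection sees training rows only; the resulting roster is applied to
    both training and held-out tables by the caller.
    """
    X = train.table.matrix()
    if np.isnan(X).any():
        raise ValueError("feature selection requires an imputed table")
    tree = DecisionTreeClassifier(criterion="gini", random_state=rng_seed)
    tree.fit(X, train.y)
    gains = pd.Series(tree.feature_importances_, index=train.table.feature_names)
    kept = gains.index[gains >= threshold].tolist()
    if not kept:
        kept = [gains.idxmax()]
        logger.warning("no feature reached gain %.3f; keeping %s", threshold, kept[0])
    return FeatureSelectionReport(gains=gains, kept=kept, threshold=threshold)
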