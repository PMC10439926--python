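"""Imbalance-aware bagging: SMOTE, random under-sampling, the RUS+SMOTE KNN
bagging ensemble with feature subsampling and out-of-bag scoring, plus the
four comparison classifiers.

The reference method builds each base learner in four steps: (i) bootstrap
the training rows with replacement at the original size; (ii) randomly
under-sample the majority (neutral) class down to a target minority/majority
ratio; (iii) over-sample the minority (pathogenic) class with SMOTE until the
classes are exactly balanced; (iv) fit a K-nearest-neighbors classifier on a
random feature subset. The ensemble score of a variant is the mean
positive-class probability over learners; averaging only learners whose
bootstrap excluded a training row yields its out-of-bag (OOB) score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from mitopath.datamodel import FeatureTable, LabeledDataset

_MAX_BOOTSTRAP_ATTEMPTS = 100


@dataclass(frozen=True)
class HyperParams:
    """Hyperparameters of the RUS+SMOTE KNN bagging method.

    Defaults are the grid-search optimum: 3 neighbors weighted by inverse
    Euclidean distance, a 1/4 post-RUS minority/majority ratio, and each
    learner seeing 1/4 of the selected features. ``smote_k`` is fixed at 5.
    """

    k_neighbors: int = 3
    neighbor_weighting: str = "inverse_distance"  # or "uniform"
    feature_ratio: float = 0.25
    rus_ratio: float = 0.25
    n_learners: int = 200
    smote_k: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.feature_ratio <= 1 and 0 < self.rus_ratio <= 1):
            raise ValueError("feature_ratio and rus_ratio must lie in (0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.neighbor_weighting not in ("uniform", "inverse_distance"):
            raise ValueError(f"unknown weighting {self.neighbor_weighting!r}")


def smote_sample(
    minority: np.ndarray,
    k: int = 5,
    n_synthetic: int = 0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Generate synthetic minority rows by convex interpolation.

    Each synthetic point is x + u*(x_nn - x) with u ~ Uniform[0,1), x a
    random minority row and x_nn one of its k nearest minority neighbors
    (Euclidean). k is capped at |minority| - 1.
    """
    minority = np.asarray(minority, dtype=float)
    if len(minority) < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    rng = np.random.default_rng(rng)
    if n_synthetic == 0:
        return np.empty((0, minority.shape[1]))
    k = min(k, len(minority) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    # drop self (first neighbor at distance 0; duplicates are still fine
    # because interpolation between identical points is that point)
    neigh = nn.kneighbors(minority, return_distance=False)[:, 1:]
    base = rng.integers(0, len(minority), n_synthetic)
    pick = rng.integers(0, k, n_synthetic)
    partners = neigh[base, pick]
    u = rng.random((n_synthetic, 1))
    return minority[base] + u * (minority[partners] - minority[base])


def rus(
    majority: np.ndarray,
    target_ratio: float,
    n_minority: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Random under-sampling of the majority class.

    Keeps ceil(n_minority / target_ratio) majority rows, sampled uniformly
    without replacement, so the minority/majority ratio becomes
    ``target_ratio``. A no-op when the ratio is already satisfied.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    majority = np.asarray(majority)
    n_keep = math.ceil(n_minority / target_ratio)
    if n_keep >= len(majority):
        return majority
    rng = np.random.default_rng(rng)
    keep = rng.choice(len(majority), size=n_keep, replace=False)
    return majority[keep]


@dataclass
class BaseLearner:
    """One bagged KNN learner: its bootstrap, feature subset and fitted model."""

    bootstrap_row_indices: np.ndarray
    feature_subset: list[str]
    knn: KNeighborsClassifier
    _feature_idx: np.ndarray = field(repr=False, default=None)

    def positive_probability(self, X: np.ndarray) -> np.ndarray:
        proba = self.knn.predict_proba(X[:, self._feature_idx])
        classes = list(self.knn.classes_)
        if 1 not in classes:
            return np.zeros(len(X))
        return proba[:, classes.index(1)]


@dataclass
class BaggedEnsemble:
    learners: list[BaseLearner]
    training_ids: list[str]
    feature_names: list[str]
    hyperparams: HyperParams
    rng_seed: int
    spatial_flags: frozenset = frozenset()

    def __len__(self) -> int:
        return len(self.learners)


def _fit_one_learner(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    hp: HyperParams,
    rng: np.random.Generator,
    smote_before_subset: bool,
) -> BaseLearner:
    n, n_features = X.shape
    for _ in range(_MAX_BOOTSTRAP_ATTEMPTS):
        boot = rng.integers(0, n, n)
        yb = y[boot]
        if 0 < yb.sum() < len(yb):
            break
    else:
        raise RuntimeError("could not draw a bootstrap containing both classes")

    Xb = X[boot]
    counts = np.bincount(yb, minlength=2)
    minority_label = int(np.argmin(counts))
    majority_label = 1 - minority_label
    Xmin = Xb[yb == minority_label]
    Xmaj = Xb[yb == majority_label]

    Xmaj = rus(Xmaj, hp.rus_ratio, len(Xmin), rng)

    n_subset = math.ceil(hp.feature_ratio * n_features)
    feat_idx = np.sort(rng.choice(n_features, size=n_subset, replace=False))

    n_synth = len(Xmaj) - len(Xmin)
    if smote_before_subset:
        synth = smote_sample(Xmin, hp.smote_k, n_synth, rng) if n_synth > 0 else None
        Xmin_full = Xmin if synth is None else np.vstack([Xmin, synth])
        X_fit = np.vstack([Xmin_full, Xmaj])[:, feat_idx]
    else:
        Xmin_s, Xmaj_s = Xmin[:, feat_idx], Xmaj[:, feat_idx]
        synth = smote_sample(Xmin_s, hp.smote_k, n_synth, rng) if n_synth > 0 else None
        Xmin_full = Xmin_s if synth is None else np.vstack([Xmin_s, synth])
        X_fit = np.vstack([Xmin_full, Xmaj_s])
    y_fit = np.concatenate(
        [np.full(len(Xmin_full), minority_label), np.full(len(Xmaj), majority_label)]
    )
    assert (y_fit == 0).sum() == (y_fit == 1).sum(), "classes must balance exactly"

    weights = "distance" if hp.neighbor_weighting == "inverse_distance" else "uniform"
    knn = KNeighborsClassifier(
        n_neighbors=min(hp.k_neighbors, len(X_fit)), weights=weights
    )
    knn.fit(X_fit, y_fit)
    return BaseLearner(
        bootstrap_row_indices=boot,
        feature_subset=[feature_names[i] for i in feat_idx],
        knn=knn,
        _feature_idx=feat_idx,
    )


def train_knn_rus_smote(
    train: LabeledDataset,
    hp: HyperParams | None = None,
    rng_seed: int = 0,
    smote_before_subset: bool = True,
) -> BaggedEnsemble:
    """Fit the RUS+SMOTE-balanced KNN bagging ensemble.

    Every learner's class counts are exactly equal after SMOTE. All
    randomness flows from one root seed via per-learner spawned streams, so
    increasing ``n_learners`` extends the ensemble without reshuffling
    earlier learners. ``smote_before_subset`` controls whether SMOTE
    interpolates in the full selected-feature space (default) or in the
    learner's subsetted space.
    """
    hp = hp or HyperParams()
    train.require_both_classes()
    X = train.table.matrix()
    if np.isnan(X).any():
        raise ValueError("training table must be imputed before ensemble fitting")
    y = train.y
    root = np.random.SeedSequence(rng_seed)
    streams = root.spawn(hp.n_learners)
    learners = [
        _fit_one_learner(
            X, y, train.table.feature_names, hp,
            np.random.default_rng(stream), smote_before_subset,
        )
        for stream in streams
    ]
    return BaggedEnsemble(
        learners=learners,
        training_ids=train.table.variant_ids,
        feature_names=train.table.feature_names,
        hyperparams=hp,
        rng_seed=rng_seed,
        spatial_flags=train.table.spatial_flags,
    )


def _as_matrix(ensemble: BaggedEnsemble, X: FeatureTable | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureTable):
        missing = set(ensemble.feature_names) - set(X.feature_names)
        if missing:
            raise ValueError(f"table lacks ensemble features: {sorted(missing)}")
        return X.values.loc[:, ensemble.feature_names].to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def learner_probabilities(
    ensemble: BaggedEnsemble, X: FeatureTable | np.ndarray
) -> np.ndarray:
    """(n_learners, n_rows) matrix of per-learner positive-class probabilities."""
    mat = _as_matrix(ensemble, X)
    return np.array([lr.positive_probability(mat) for lr in ensemble.learners])


def predict_score(ensemble: BaggedEnsemble, X: FeatureTable | np.ndarray) -> np.ndarray:
    """Ensemble pathogenicity score in [0, 1]: mean learner probability."""
    return learner_probabilities(ensemble, X).mean(axis=0)


def oob_scores(
    ensemble: BaggedEnsemble, train: FeatureTable | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag score per training row.

    Row i is scored by averaging only learners whose bootstrap excluded it.
    Rows covered by every bootstrap (possible only with few learners) fall
    back to the full-ensemble score; the returned boolean flag array marks
    them.
    """
    probs = learner_probabilities(ensemble, train)  # (L, N)
    n = probs.shape[1]
    in_bag = np.zeros((len(ensemble.learners), n), dtype=bool)
    for li, lr in enumerate(ensemble.learners):
        in_bag[li, np.unique(lr.bootstrap_row_indices)] = True
    oob_mask = ~in_bag
    counts = oob_mask.sum(axis=0)
    scores = np.where(
        counts > 0,
        (probs * oob_mask).sum(axis=0) / np.maximum(counts, 1),
        probs.mean(axis=0),
    )
    fallback = counts == 0
    return scores, fallback


# ---------------------------------------------------------------------------
# comparison classifiers
# ---------------------------------------------------------------------------

class _BalancedBagging:
    """Bagging of a weak learner with per-learner RUS balancing.

    Each learner draws ceil(sample_ratio * n) rows with replacement, randomly
    under-samples the majority class within the bootstrap to exact balance,
    samples ceil(feature_ratio * F) features without replacement, and fits
    the base estimator. Scores are mean positive-class probabilities.
    """

    def __init__(self, base_factory, n_learners=200, sample_ratio=1.0,
                 feature_ratio=1.0, rng_seed=0):
        self.base_factory = base_factory
        self.n_learners = n_learners
        self.sample_ratio = sample_ratio
        self.feature_ratio = feature_ratio
        self.rng_seed = rng_seed
        self._members: list[tuple[np.ndarray, object]] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BalancedBagging":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n, F = X.shape
        n_rows = max(2, math.ceil(self.sample_ratio * n))
        n_feats = max(1, math.ceil(self.feature_ratio * F))
        root = np.random.SeedSequence(self.rng_seed)
        self._members = []
        for stream in root.spawn(self.n_learners):
            rng = np.random.default_rng(stream)
            for _ in range(_MAX_BOOTSTRAP_ATTEMPTS):
                boot = rng.integers(0, n, n_rows)
                yb = y[boot]
                if 0 < yb.sum() < len(yb):
                    break
            else:
                raise RuntimeError("bootstrap never contained both classes")
            pos = boot[yb == 1]
            neg = boot[yb == 0]
            m = min(len(pos), len(neg))
            pos = rng.choice(pos, m, replace=False) if len(pos) > m else pos
            neg = rng.choice(neg, m, replace=False) if len(neg) > m else neg
            rows = np.concatenate([pos, neg])
            feats = np.sort(rng.choice(F, n_feats, replace=False))
            est = self.base_factory(rng)
            est.fit(X[rows][:, feats], y[rows])
            self._members.append((feats, est))
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for feats, est in self._members:
            proba = est.predict_proba(X[:, feats])
            classes = list(est.classes_)
            out += proba[:, classes.index(1)] if 1 in classes else 0.0
        return out / len(self._members)


class _BalancedRandomForest:
    """Random forest where every tree sees a balanced bootstrap.

    Each tree's sample draws n_minority rows with replacement from each
    class; tree depth, per-split feature count and leaf minima are tunable.
    """

    def __init__(self, n_trees=200, max_depth=None, max_features="sqrt",
                 min_samples_split=2, min_samples_leaf=1, rng_seed=0):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.max_features = max_features
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.rng_seed = rng_seed
        self._trees: list[DecisionTreeClassifier] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        m = min(len(idx_pos), len(idx_neg))
        root = np.random.SeedSequence(self.rng_seed)
        self._trees = []
        for stream in root.spawn(self.n_trees):
            rng = np.random.default_rng(stream)
            rows = np.concatenate(
                [rng.choice(idx_pos, m, replace=True), rng.choice(idx_neg, m, replace=True)]
            )
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                max_features=self.max_features,
                min_samples_split=self.min_samples_split,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[rows], y[rows])
            self._trees.append(tree)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for tree in self._trees:
            proba = tree.predict_proba(X)
            classes = list(tree.classes_)
            out += proba[:, classes.index(1)] if 1 in classes else 0.0
        return out / len(self._trees)


class _SvcScorer:
    """RBF-kernel SVM with balanced class weights; Platt-style calibration
    maps the margin to a probability."""

    def __init__(self, C=1.0, gamma="scale", rng_seed=0):
        from sklearn.calibration import CalibratedClassifierCV

        self.svc = CalibratedClassifierCV(
            SVC(kernel="rbf", C=C, gamma=gamma, class_weight="balanced",
                random_state=rng_seed),
            ensemble=False,
        )

    def fit(self, X, y):
        self.svc.fit(X, y)
        return self

    def predict_score(self, X) -> np.ndarray:
        proba = self.svc.predict_proba(X)
        classes = list(self.svc.classes_)
        return proba[:, classes.index(1)]


class KnnRusSmoteModel:
    """The reference method behind the generic fit/predict_score interface."""

    def __init__(self, hp: HyperParams | None = None, rng_seed: int = 0,
                 smote_before_subset: bool = True):
        self.hp = hp or HyperParams()
        self.rng_seed = rng_seed
        self.smote_before_subset = smote_before_subset
        self.ensemble: BaggedEnsemble | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KnnRusSmoteModel":
        import pandas as pd

        n, F = np.asarray(X).shape
        table = FeatureTable(
            pd.DataFrame(X, index=[f"r{i}" for i in range(n)],
                         columns=[f"f{j}" for j in range(F)])
        )
        ds = LabeledDataset(table, pd.Series(y, index=table.variant_ids))
        self.ensemble = train_knn_rus_smote(
            ds, self.hp, self.rng_seed, self.smote_before_subset
        )
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return predict_score(self.ensemble, np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# serialization: versioned JSON header + npz arrays
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: BaggedEnsemble, prefix: str) -> None:
    """Persist an ensemble as ``<prefix>.json`` (header) + ``<prefix>.npz``.

    Each learner's balanced training sample is stored so the KNN state can
    be rebuilt exactly on load.
    """
    import json
    from pathlib import Path

    header = {
        "format_version": 1,
        "hyperparams": {
            "k_neighbors": ensemble.hyperparams.k_neighbors,
            "neighbor_weighting": ensemble.hyperparams.neighbor_weighting,
            "feature_ratio": ensemble.hyperparams.feature_ratio,
            "rus_ratio": ensemble.hyperparams.rus_ratio,
            "n_learners": ensemble.hyperparams.n_learners,
            "smote_k": ensemble.hyperparams.smote_k,
        },
        "rng_seed": ensemble.rng_seed,
        "feature_names": ensemble.feature_names,
        "spatial_flags": sorted(ensemble.spatial_flags),
        "training_ids": ensemble.training_ids,
        "n_learners_fitted": len(ensemble.learners),
    }
    Path(f"{prefix}.json").write_text(json.dumps(header))
    arrays = {}
    for i, lr in enumerate(ensemble.learners):
        arrays[f"boot_{i}"] = lr.bootstrap_row_indices
        arrays[f"featidx_{i}"] = lr._feature_idx
        arrays[f"Xfit_{i}"] = lr.knn._fit_X
        arrays[f"yfit_{i}"] = np.asarray(lr.knn.classes_)[np.asarray(lr.knn._y)]
    np.savez_compressed(f"{prefix}.npz", **arrays)


def load_ensemble(prefix: str) -> BaggedEnsemble:
    import json
    from pathlib import Path

    header = json.loads(Path(f"{prefix}.json").read_text())
    hp = HyperParams(**header["hyperparams"])
    data = np.load(f"{prefix}.npz")
    weights = "distance" if hp.neighbor_weighting == "inverse_distance" else "uniform"
    learners = []
    for i in range(header["n_learners_fitted"]):
        X_fit = data[f"Xfit_{i}"]
        y_fit = data[f"yfit_{i}"]
        knn = KNeighborsClassifier(
            n_neighbors=min(hp.k_neighbors, len(X_fit)), weights=weights
        )
        knn.fit(X_fit, y_fit)
        feat_idx = data[f"featidx_{i}"]
        learners.append(
            BaseLearner(
                bootstrap_row_indices=data[f"boot_{i}"],
                feature_subset=[header["feature_names"][j] for j in feat_idx],
                knn=knn,
                _feature_idx=feat_idx,
            )
        )
    return BaggedEnsemble(
        learners=learners,
        training_ids=list(header["training_ids"]),
        feature_names=list(header["feature_names"]),
        hyperparams=hp,
        rng_seed=header["rng_seed"],
        spatial_flags=frozenset(header["spatial_flags"]),
    )


BASELINE_KINDS = (
    "rbf_svc", "gnb_balanced_bagging", "knn_balanced_bagging", "balanced_rf",
)


def train_baseline(
    kind: str,
    train: LabeledDataset,
    params: dict | None = None,
    rng_seed: int = 0,
):
    """Fit one of the comparison classifiers; returns a scorer with
    ``predict_score(X) -> [0, 1]``.
    """
    params = dict(params or {})
    X = train.table.matrix()
    y = train.y
    model = make_baseline(kind, params, rng_seed)
    return model.fit(X, y)


def make_baseline(kind: str, params: dict, rng_seed: int):
    """Construct an unfitted comparison classifier."""
    params = dict(params)
    if kind == "rbf_svc":
        return _SvcScorer(rng_seed=rng_seed, **params)
    if kind == "gnb_balanced_bagging":
        smoothing = params.pop("var_smoothing", 1e-9)
        return _BalancedBagging(
            lambda rng: GaussianNB(var_smoothing=smoothing),
            rng_seed=rng_seed, **params,
        )
    if kind == "knn_balanced_bagging":
        k = params.pop("k_neighbors", 3)
        weighting = params.pop("neighbor_weighting", "uniform")
        weights = "distance" if weighting == "inverse_distance" else "uniform"
        return _BalancedBagging(
            lambda rng: KNeighborsClassifier(n_neighbors=k, weights=weights),
            rng_seed=rng_seed, **params,
        )
    if kind == "balanced_rf":
        return _BalancedRandomForest(rng_seed=rng_seed, **params)
    raise ValueError(f"unknown baseline kind {kind!r}; choose from {BASELINE_KINDS}")


def make_method(name: str, params: dict, rng_seed: int):
    """Factory shared by grid search and nested CV: name + params -> model."""
    if name == "knn_rus_smote":
        hp_fields = {f for f in HyperParams.__dataclass_fields__}
        hp = HyperParams(**{k: v for k, v in params.items() if k in hp_fields})
        extra = {k: v for k, v in params.items() if k not in hp_fields}
        return KnnRusSmoteModel(hp, rng_seed=rng_seed, **extra)
    return make_baseline(name, params, rng_seed)
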