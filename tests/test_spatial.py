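"""Spatial weights, Moran's I with its brute-force oracle, LISA, cutoff
scans, spatial-learner exclusion, and region calling."""

import numpy as np
import pytest

from mitopath.datamodel import LabeledDataset, ResidueSite
from mitopath.ensemble import HyperParams, train_knn_rus_smote
from mitopath.spatial import (
    ResidueField,
    build_weights,
    call_regions,
    cutoff_scan,
    drop_spatial_learners,
    lisa,
    morans_I,
    residue_mean_scores,
)
from mitopath.synth import SynthTableSpec, ToyStructureSpec, gen_feature_table, gen_toy_structure


def brute_force_moran(y: np.ndarray, w: np.ndarray) -> float:
    """Direct double-loop evaluation with the N / sum(w) prefactor."""
    n = len(y)
    ybar = y.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (y[i] - ybar) * (y[j] - ybar)
    return (n / w.sum()) * num / ((y - ybar) ** 2).sum()


def random_field(rng, n):
    coords = rng.normal(scale=10.0, size=(n, 3))
    scores = rng.random(n)
    return coords, scores


class TestResidueMeanScores:
    def _sites(self):
        return {
            "r1": ResidueSite("c", "A", 1, (0.0, 0.0, 0.0)),
            "r2": ResidueSite("c", "A", 2, (3.8, 0.0, 0.0)),
        }

    def test_mean_and_singleton(self):
        sites = self._sites()
        field = residue_mean_scores(
            {"v1": 0.2, "v2": 0.4, "v3": 0.9, "v4": 0.7},
            {"v1": sites["r1"], "v2": sites["r1"], "v3": sites["r1"], "v4": sites["r2"]},
        )
        by_res = {s.residue_index: s.mean_score for s in field.sites}
        assert by_res[1] == pytest.approx(0.5)
        assert by_res[2] == pytest.approx(0.7)

    def test_unmapped_variants_ignored(self):
        sites = self._sites()
        field = residue_mean_scores(
            {"v1": 0.3, "orphan": 0.9}, {"v1": sites["r1"]}
        )
        assert len(field) == 1


class TestDropSpatialLearners:
    def _ensemble(self, feature_ratio):
        ds = gen_feature_table(SynthTableSpec(n_variants=150, seed=3))
        from mitopath.preprocess import apply_scaler, fit_scaler, impute

        table = impute(apply_scaler(fit_scaler(ds.table), ds.table), "mean")
        ds2 = LabeledDataset(table, ds.labels)
        hp = HyperParams(n_learners=30, feature_ratio=feature_ratio)
        return train_knn_rus_smote(ds2, hp, rng_seed=0)

    def test_mixed_ensemble_filtered_by_subset(self):
        ens = self._ensemble(0.25)
        spatial = {"X", "Y", "Z"}
        expected = sum(
            1 for lr in ens.learners if not (set(lr.feature_subset) & spatial)
        )
        assert 0 < expected < len(ens.learners)
        kept = drop_spatial_learners(ens)
        assert len(kept) == expected
        assert all(not (set(lr.feature_subset) & spatial) for lr in kept.learners)

    def test_all_learners_spatial_fatal(self):
        ens = self._ensemble(1.0)  # every learner holds all features incl. X/Y/Z
        with pytest.raises(ValueError, match="spatial"):
            drop_spatial_learners(ens)


class TestWeights:
    def test_two_sites_always_half(self):
        w = build_weights(np.array([[0.0, 0, 0], [7.3, 0, 0]]), "quadratic_decay")
        assert w.matrix[0, 1] == pytest.approx(0.5)
        assert w.matrix[1, 0] == pytest.approx(0.5)

    def test_binary_all_within_radius_uniform(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        w = build_weights(coords, "binary_cutoff", r=10.0)
        off = w.matrix[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_quadratic_scale_invariance(self):
        rng = np.random.default_rng(0)
        coords, _ = random_field(rng, 12)
        a = build_weights(coords, "quadratic_decay").matrix
        b = build_weights(2.0 * coords, "quadratic_decay").matrix
        assert np.allclose(a, b)

    def test_total_weight_one_and_zero_diagonal(self):
        rng = np.random.default_rng(1)
        coords, _ = random_field(rng, 20)
        for kind, r in (("quadratic_decay", None), ("binary_cutoff", 8.0)):
            w = build_weights(coords, kind, r=r)
            assert w.matrix.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.diag(w.matrix).max() == 0.0

    def test_coincident_sites_fatal(self):
        coords = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1]], float)
        with pytest.raises(ValueError, match="coincident"):
            build_weights(coords, "quadratic_decay")


class TestMoran:
    def test_two_sites_return_expected_value(self):
        w = build_weights(np.array([[0.0, 0, 0], [5.0, 0, 0]]), "quadratic_decay")
        res = morans_I(np.array([0.0, 1.0]), w, n_perm=0)
        assert res.I == pytest.approx(-1.0)
        assert res.expected == -1.0

    @pytest.mark.parametrize("kind,r", [("quadratic_decay", None), ("binary_cutoff", 12.0)])
    def test_matches_brute_force_oracle(self, kind, r):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(5, 50))
            coords, scores = random_field(rng, n)
            w = build_weights(coords, kind, r=r)
            fast = morans_I(scores, w, n_perm=0).I
            assert fast == pytest.approx(brute_force_moran(scores, w.matrix), abs=1e-9)

    def test_smooth_gradient_strongly_significant(self, helix_field):
        field, _ = helix_field
        w = build_weights(field, "binary_cutoff", r=8.0)
        res = morans_I(field, w, n_perm=10_000, seed=0)
        assert res.I > res.expected
        assert res.p_value <= 0.001

    def test_shuffled_scores_near_null(self, helix_field):
        field, _ = helix_field
        rng = np.random.default_rng(3)
        shuffled = rng.permutation(field.scores)
        w = build_weights(field.coords, "quadratic_decay")
        res = morans_I(shuffled, w, n_perm=2_000, seed=1)
        assert abs(res.I - res.expected) < 0.15
        assert res.p_value > 0.01

    def test_permutation_null_mean_matches_expectation(self, helix_field):
        field, _ = helix_field
        w = build_weights(field.coords, "quadratic_decay")
        from mitopath.spatial import _permuted_I, _standardize

        z = _standardize(field.scores)
        perms = _permuted_I(z, w.matrix, 10_000, np.random.default_rng(4))
        se = perms.std(ddof=1) / np.sqrt(len(perms))
        assert abs(perms.mean() - (-1.0 / (len(z) - 1))) < 3 * se

    def test_affine_invariance(self, helix_field):
        field, _ = helix_field
        w = build_weights(field.coords, "quadratic_decay")
        base = morans_I(field.scores, w, n_perm=0).I
        scaled = morans_I(3.0 * field.scores + 7.0, w, n_perm=0).I
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_zero_variance_fatal(self):
        coords = np.random.default_rng(5).normal(size=(10, 3))
        w = build_weights(coords, "quadratic_decay")
        with pytest.raises(ValueError, match="variance"):
            morans_I(np.ones(10), w, n_perm=0)


class TestCutoffScan:
    def test_single_radius_degenerates_to_morans(self, helix_field):
        field, _ = helix_field
        results, best = cutoff_scan(field, [8.0], n_perm=100, seed=0)
        w = build_weights(field, "binary_cutoff", r=8.0)
        direct = morans_I(field, w, n_perm=100, seed=0)
        assert best == 8.0
        assert results[8.0].I == pytest.approx(direct.I)
        assert results[8.0].p_value == direct.p_value

    def test_radius_beyond_diameter_near_expected(self, helix_field):
        field, _ = helix_field
        results, _ = cutoff_scan(field, [10_000.0], n_perm=0, seed=0)
        res = results[10_000.0]
        assert res.I == pytest.approx(res.expected, abs=1e-6)

    def test_unsorted_radii_fatal(self, helix_field):
        field, _ = helix_field
        with pytest.raises(ValueError, match="sorted"):
            cutoff_scan(field, [8.0, 4.0], n_perm=0)


class TestLISA:
    @pytest.mark.parametrize("kind,r", [("quadratic_decay", None), ("binary_cutoff", 9.0)])
    def test_sum_identity(self, helix_field, kind, r):
        field, _ = helix_field
        w = build_weights(field, kind, r=r)
        global_i = morans_I(field, w, n_perm=0).I
        local = lisa(field, w, n_perm=50, seed=0)
        assert local.local_i.sum() == pytest.approx(global_i, abs=1e-9)

    def test_site_with_same_sign_neighbors_positive(self):
        # two tight clusters far apart: low-score cluster and high-score cluster
        coords = np.vstack([
            np.random.default_rng(6).normal(0.0, 1.0, (10, 3)),
            np.random.default_rng(7).normal(100.0, 1.0, (10, 3)),
        ])
        scores = np.array([0.1] * 10 + [0.9] * 10) + np.linspace(0, 0.01, 20)
        w = build_weights(coords, "quadratic_decay")
        local = lisa(scores, w, n_perm=20, seed=0)
        assert (local.local_i > 0).all()

    def test_smooth_field_significant_inside_not_at_random_sites(self, helix_field):
        field, _ = helix_field
        w = build_weights(field, "binary_cutoff", r=9.0)
        local = lisa(field, w, n_perm=1000, seed=1)
        assert local.significant.sum() > 0.3 * len(field)
        # q-values never undercut their raw p-values
        assert (local.q_values >= local.p_values).all()

    def test_null_false_positive_rate_bounded(self, helix_field):
        field, _ = helix_field
        rng = np.random.default_rng(8)
        w = build_weights(field.coords, "quadratic_decay")
        fp = 0
        trials = 20
        for t in range(trials):
            shuffled = rng.permutation(field.scores)
            local = lisa(shuffled, w, n_perm=500, seed=t, alpha=0.05)
            fp += int(local.significant.sum() > 0)
        # under the global null BH keeps the family-wise discovery fraction
        # near the q-level; most shuffles should yield zero discoveries
        assert fp <= max(3, int(0.2 * trials))


class TestCallRegions:
    def _field(self, scores):
        sites = [
            ResidueSite("c", "A", i + 1, (3.8 * i, 0.0, 0.0), mean_score=s)
            for i, s in enumerate(scores)
        ]
        return ResidueField(sites)

    def test_constant_high_field_single_run(self):
        regions = call_regions(self._field([0.9] * 6), threshold=0.5)
        assert len(regions) == 1
        assert regions.iloc[0]["label"] == "high_risk"
        assert regions.iloc[0]["n_residues"] == 6

    def test_alternating_scores_unit_runs(self):
        regions = call_regions(self._field([0.9, 0.1] * 3), threshold=0.5)
        assert len(regions) == 6
        assert (regions["n_residues"] == 1).all()

    def test_median_threshold_splits_evenly(self):
        rng = np.random.default_rng(9)
        scores = rng.random(200)
        field = self._field(scores)
        regions = call_regions(field, threshold=float(np.median(scores)))
        high = regions.loc[regions["label"] == "high_risk", "n_residues"].sum()
        assert high == 100
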