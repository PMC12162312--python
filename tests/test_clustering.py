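"""K-means, silhouette, model selection, assignment, persistence."""

import itertools
import json

import numpy as np
import pytest

from audioclust import SlopeFeatures, adjusted_rand_index
from audioclust.clustering import (
    ClusterModel,
    assign,
    fit_model,
    kmeans_fit,
    lloyd,
    load_model,
    save_model,
    select_k,
    silhouette_mean,
    standardize,
)
from audioclust.errors import (
    ContractError,
    DegenerateDataError,
    ModelFormatError,
)


def brute_force_best_sse(X):
    """Global minimum 2-cluster SSE by enumerating all 2-partitions."""
    n = len(X)
    best = np.inf
    for mask_bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        if mask.all() or not mask.any():
            continue
        sse = 0.0
        for part in (X[mask], X[~mask]):
            sse += ((part - part.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


def brute_force_silhouette(X, labels):
    """Mean silhouette straight from the definition, pairwise loops."""
    n = len(X)
    dist = lambda i, j: float(np.linalg.norm(X[i] - X[j]))
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = float(np.mean([dist(i, j) for j in own]))
        bs = []
        for other in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            bs.append(float(np.mean([dist(i, j) for j in members])))
        b = min(bs)
        scores.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(scores))


class TestStandardize:
    def test_symmetric_pair_standardizes_to_itself(self):
        X = np.array([[1.0, 1, 1], [-1, -1, -1]])
        Z, (mean, sd) = standardize(X)
        assert np.allclose(Z, X) and np.allclose(mean, 0) and np.allclose(sd, 1)

    def test_identity_stats_leave_rows_unchanged(self):
        X = np.array([[3.0, -2, 7], [0, 1, 2]])
        Z, _ = standardize(X, stats=((0, 0, 0), (1, 1, 1)))
        assert np.allclose(Z, X)

    def test_population_sd_convention(self):
        X = np.array([[0.0, 0, 0], [2, 4, 6]])
        Z, (mean, sd) = standardize(X)
        assert np.allclose(mean, [1, 2, 3]) and np.allclose(sd, [1, 2, 3])
        assert np.allclose(Z, [[-1, -1, -1], [1, 1, 1]])

    def test_zero_variance_feature_named(self):
        X = np.array([[1.0, 5, 1], [2, 5, 2], [3, 5, 3]])
        with pytest.raises(DegenerateDataError, match="kb"):
            standardize(X)


class TestKMeans:
    def test_two_coincident_groups(self):
        X = np.repeat([[0.0, 0, 0], [10, 10, 10]], 3, axis=0)
        centers, labels, inertia = kmeans_fit(X, 2, seed=0, n_init=5)
        assert inertia == pytest.approx(0.0)
        assert {tuple(c) for c in centers} == {(0, 0, 0), (10, 10, 10)}
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_two_tight_balls_split_correctly(self):
        rng = np.random.default_rng(1)
        X = np.vstack([
            rng.normal(0, 0.1, (3, 3)), rng.normal(5, 0.1, (3, 3))
        ])
        _, labels, inertia = kmeans_fit(X, 2, seed=0)
        assert len(set(labels[:3])) == 1 and labels[0] != labels[3]
        assert inertia == pytest.approx(brute_force_best_sse(X), abs=1e-9)

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kmeans_fit(np.zeros((5, 3)), 2, seed=0)

    def test_inertia_non_increasing_within_lloyd(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        for trial in range(10):
            init = X[rng.choice(40, size=2, replace=False)]
            _, _, _, history = lloyd(X, init)
            assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_best_of_restarts_attains_global_optimum_small(self):
        rng = np.random.default_rng(3)
        for trial in range(25):
            n = int(rng.integers(4, 11))
            X = rng.normal(size=(n, 3))
            _, _, inertia = kmeans_fit(X, 2, seed=trial, n_init=50)
            assert inertia == pytest.approx(brute_force_best_sse(X), abs=1e-8)

    def test_fixed_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        a = kmeans_fit(X, 2, seed=9, n_init=10)
        b = kmeans_fit(X, 2, seed=9, n_init=10)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert a[2] == b[2]


class TestSilhouette:
    def test_coincident_duplicated_clusters_score_one(self):
        X = np.array([[0.0, 0, 0]] * 3 + [[4.0, 0, 0]] * 3)
        labels = [0, 0, 0, 1, 1, 1]
        assert silhouette_mean(X, labels) == pytest.approx(1.0)

    def test_fully_mixed_coincident_clusters_score_nonpositive(self):
        X = np.array([[0.0, 0, 0], [4, 0, 0]] * 3)
        labels = [0, 1, 1, 0, 0, 1]
        assert silhouette_mean(X, labels) <= 0.0

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0], [1.0], [10.0]])
        expected = brute_force_silhouette(X, [0, 0, 1])
        assert silhouette_mean(X, [0, 0, 1]) == pytest.approx(expected, abs=1e-12)
        # hand value: s(0) = (10-1)/10, s(1) = (9-1)/9, s(10) = 0 (singleton)
        assert expected == pytest.approx((9.0 / 10.0 + 8.0 / 9.0) / 3.0, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(6)
        for trial in range(30):
            n = int(rng.integers(5, 12))
            k = int(rng.integers(2, 4))
            X = rng.normal(size=(n, 3))
            labels = rng.integers(0, k, size=n)
            if len(set(labels.tolist())) < 2:
                continue
            assert silhouette_mean(X, labels) == pytest.approx(
                brute_force_silhouette(X, labels.tolist()), abs=1e-12
            )

    def test_single_cluster_is_contract_error(self):
        with pytest.raises(ContractError):
            silhouette_mean(np.zeros((4, 2)), [0, 0, 0, 0])

    def test_cross_check_against_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 3))
        labels = rng.integers(0, 3, size=50)
        assert silhouette_mean(X, labels) == pytest.approx(
            float(sklearn.silhouette_score(X, labels)), abs=1e-10
        )


class TestSelectK:
    def test_two_balls_choose_two(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.3, (30, 3)), rng.normal(6, 0.3, (30, 3))])
        report = select_k(X, [2, 3, 4, 5], seed=0, n_init=10)
        assert report.chosen_k == 2
        assert report.mean_silhouette[0] == max(report.mean_silhouette)

    def test_three_balls_choose_three(self):
        rng = np.random.default_rng(9)
        X = np.vstack([
            rng.normal(c, 0.3, (20, 3)) for c in ([0, 0, 0], [6, 0, 0], [0, 6, 0])
        ])
        assert select_k(X, [2, 3], seed=0, n_init=10).chosen_k == 3

    def test_single_candidate(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(10, 3))
        assert select_k(X, [2], seed=0, n_init=10).chosen_k == 2


class TestModel:
    def make_model(self):
        features = [
            SlopeFeatures(-2 + 0.1 * i, -15 + 0.2 * i, -20 + 0.3 * i)
            for i in range(10)
        ] + [
            SlopeFeatures(0.1 * i, -1 + 0.05 * i, -1 + 0.05 * i)
            for i in range(30)
        ]
        return fit_model(features, seed=1, n_init=10)

    def test_orientation_x_has_lower_mid_high_slopes(self):
        model, codes = self.make_model()
        c = np.asarray(model.centroids)
        assert c[0, 1:].mean() < c[1, 1:].mean()
        assert (codes[:10] == 0).all() and (codes[10:] == 1).all()

    def test_assign_returns_exact_centroids_and_tie_to_x(self):
        model, _ = self.make_model()
        mean = np.asarray(model.standardize_mean)
        sd = np.asarray(model.standardize_sd)
        cx, cy = (np.asarray(c) for c in model.centroids)
        pre_x = SlopeFeatures(*(cx * sd + mean))
        pre_y = SlopeFeatures(*(cy * sd + mean))
        midpoint = SlopeFeatures(*((cx + cy) / 2 * sd + mean))
        assert assign(model, pre_x) == (0, "X")
        assert assign(model, pre_y) == (1, "Y")
        assert assign(model, midpoint) == (0, "X")

    def test_json_round_trip_is_lossless(self, tmp_path):
        model, _ = self.make_model()
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back == model

    def test_missing_field_is_model_format_error(self, tmp_path):
        model, _ = self.make_model()
        path = tmp_path / "model.json"
        save_model(model, path)
        payload = json.loads(path.read_text())
        del payload["centroids"]
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFormatError, match="centroids"):
            load_model(path)

    def test_non_bijective_label_map_rejected(self, tmp_path):
        model, _ = self.make_model()
        path = tmp_path / "model.json"
        save_model(model, path)
        payload = json.loads(path.read_text())
        payload["label_map"] = {"0": "X", "1": "X"}
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFormatError, match="bijection"):
            load_model(path)

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ModelFormatError, match="coincide"):
            ClusterModel(
                feature_names=("ka", "kb", "kc"),
                standardize_mean=(0, 0, 0), standardize_sd=(1, 1, 1),
                centroids=((1, 1, 1), (1, 1, 1)),
            )


class TestAdjustedRandIndex:
    def test_identical_partitions_score_one(self):
        assert adjusted_rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_cross_check_against_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.integers(0, 3, size=40)
            b = rng.integers(0, 4, size=40)
            assert adjusted_rand_index(a, b) == pytest.approx(
                float(sklearn.adjusted_rand_score(a, b)), abs=1e-12
            )


class TestRecoveryOnSyntheticCohort:
    def test_x_cluster_matches_steep_descent_class(self, default_cohort):
        from audioclust.slope_features import cohort_features, features_matrix

        records, truth = default_cohort
        feats = cohort_features(records)
        model, codes = fit_model(feats, seed=42)
        F = features_matrix(feats)
        x_mask = codes == 0
        # cluster X carries the descending mid-to-high-frequency audiograms
        assert F[x_mask, 1].mean() < F[~x_mask, 1].mean()
        assert F[x_mask, 2].mean() < F[~x_mask, 2].mean()
        true = (truth.true_class == "Y").astype(int).to_numpy()
        assert adjusted_rand_index(codes, true) > 0.8
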