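"""Correlation distance, PAM k-medoids vs brute force, and Silhouette sweep."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from seg2surv.cluster import (
    ClusteringResult,
    correlation_distance,
    correlation_distance_matrix,
    drop_constant_features,
    kmedoids,
    load_clustering,
    save_clustering,
    select_medoids,
    silhouette_sweep,
)
from seg2surv.features import FeatureTable


def _table(values):
    values = np.asarray(values, dtype=float)
    idx = pd.DataFrame(
        {"modality": "CT", "x": 0, "y": 0, "z": 0, "channel": range(values.shape[1])}
    )
    return FeatureTable(values, idx, [f"P{i}" for i in range(values.shape[0])])


def brute_force_kmedoids_cost(D, k):
    """Exhaustive PAM objective: best summed distance to nearest medoid."""
    n = D.shape[0]
    best = np.inf
    for medoids in combinations(range(n), k):
        cost = D[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return best


class TestCorrelationDistance:
    def test_self_distance_zero(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert correlation_distance(x, x) == pytest.approx(0.0)

    def test_anticorrelated_distance_two(self):
        x = np.array([1.0, 2.0, 3.0])
        assert correlation_distance(x, -x) == pytest.approx(2.0)

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        # R = 3 / (sqrt(2) * sqrt(14/3)) = 0.981981...
        assert correlation_distance(x, y) == pytest.approx(1 - 0.9819805061, abs=1e-9)

    def test_constant_column_convention(self):
        assert correlation_distance(np.ones(5), np.arange(5.0)) == 1.0

    def test_matrix_properties(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((12, 9))
        D = correlation_distance_matrix(v)
        np.testing.assert_allclose(D, D.T, atol=1e-6)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-7)
        assert (D >= -1e-6).all() and (D <= 2 + 1e-6).all()
        # matches the pairwise scalar implementation
        assert D[2, 5] == pytest.approx(correlation_distance(v[:, 2], v[:, 5]), abs=1e-6)

    def test_scalar_input_contract(self):
        with pytest.raises(ValueError):
            correlation_distance(np.ones(2), np.ones(2))


class TestKMedoids:
    def test_k_equals_n_features_zero_cost(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((10, 6))
        res = kmedoids(v, k=6, n_init=3, seed=0)
        assert res.inner_distance_sum == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_array_equal(np.sort(res.medoid_indices), np.arange(6))

    def test_two_correlated_triples_recovered(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        # affine copies have correlation exactly 1 within each triple
        v = np.column_stack([a, 2 * a + 1, 0.5 * a - 3, b, 3 * b, b + 2])
        res = kmedoids(v, k=2, n_init=10, seed=3)
        groups = [set(np.flatnonzero(res.assignment == c)) for c in range(2)]
        assert {frozenset(g) for g in groups} == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_exhaustive_search_on_small_instances(self, k):
        rng = np.random.default_rng(4)
        v = rng.standard_normal((15, 8))
        D = correlation_distance_matrix(v)
        res = kmedoids(v, k=k, n_init=20, seed=5)
        assert res.inner_distance_sum == pytest.approx(
            brute_force_kmedoids_cost(D, k), abs=1e-6
        )

    def test_medoid_property_and_assignment_consistency(self):
        rng = np.random.default_rng(6)
        v = rng.standard_normal((12, 10))
        res = kmedoids(v, k=3, n_init=5, seed=7)
        D = correlation_distance_matrix(v)
        for c, m in enumerate(res.medoid_indices):
            assert res.assignment[m] == c  # medoid belongs to its own cluster
        # every feature sits with its nearest medoid
        nearest = np.argmin(D[:, res.medoid_indices], axis=1)
        mismatches = res.assignment != nearest
        # ties may differ; verify distance equality where they do
        for i in np.flatnonzero(mismatches):
            d_assigned = D[i, res.medoid_indices[res.assignment[i]]]
            d_nearest = D[i, res.medoid_indices[nearest[i]]]
            assert d_assigned == pytest.approx(d_nearest, abs=1e-7)

    def test_cost_monotone_in_k(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal((10, 8))
        costs = [
            kmedoids(v, k=k, n_init=20, seed=9).inner_distance_sum for k in range(2, 7)
        ]
        assert all(c1 >= c2 - 1e-9 for c1, c2 in zip(costs, costs[1:]))

    def test_k_out_of_range_rejected(self):
        v = np.random.default_rng(10).standard_normal((8, 4))
        with pytest.raises(ValueError):
            kmedoids(v, k=5, n_init=1, seed=0)

    def test_deterministic_under_seed(self):
        v = np.random.default_rng(11).standard_normal((10, 7))
        a = kmedoids(v, k=3, n_init=5, seed=12)
        b = kmedoids(v, k=3, n_init=5, seed=12)
        np.testing.assert_array_equal(a.medoid_indices, b.medoid_indices)
        np.testing.assert_array_equal(a.assignment, b.assignment)


def _grouped_features(rng, n_groups, per_group, n=40, noise=0.05):
    bases = rng.standard_normal((n, n_groups))
    cols = [
        bases[:, g] * rng.uniform(0.5, 2.0) + noise * rng.standard_normal(n)
        for g in range(n_groups)
        for _ in range(per_group)
    ]
    return np.column_stack(cols)


class TestSilhouetteSweep:
    @pytest.mark.parametrize("n_groups", [2, 3])
    def test_recovers_planted_group_count(self, n_groups):
        rng = np.random.default_rng(13 + n_groups)
        v = _grouped_features(rng, n_groups, per_group=5)
        k_opt, curve, results = silhouette_sweep(v, range(2, 7), n_init=5, seed=1)
        assert k_opt == n_groups
        assert curve["mean_silhouette"].between(-1, 1).all()
        assert k_opt in results

    def test_empty_range_rejected(self):
        v = np.random.default_rng(14).standard_normal((10, 6))
        with pytest.raises(ValueError):
            silhouette_sweep(v, [], n_init=2, seed=0)

    def test_silhouette_matches_sklearn_oracle(self):
        from sklearn.metrics import silhouette_score

        from seg2surv.cluster import _silhouette

        rng = np.random.default_rng(40)
        v = rng.standard_normal((20, 30))
        D = correlation_distance_matrix(v).astype(np.float64)
        for k in (2, 3, 5):
            assign = kmedoids(D, k=k, n_init=3, seed=k, precomputed=True).assignment
            ours = _silhouette(D, assign)
            theirs = silhouette_score(D, assign, metric="precomputed")
            assert ours == pytest.approx(theirs, abs=1e-6)

    def test_constant_features_detected(self):
        v = np.random.default_rng(15).standard_normal((10, 5))
        v[:, 2] = 4.0
        keep = drop_constant_features(v)
        np.testing.assert_array_equal(keep, [0, 1, 3, 4])


class TestSelectMedoids:
    def test_reduced_table_is_medoid_columns(self):
        rng = np.random.default_rng(16)
        v = _grouped_features(rng, 3, per_group=4)
        table = _table(v)
        res = kmedoids(v, k=3, n_init=10, seed=17)
        reduced = select_medoids(table, res)
        assert reduced.n_features == 3
        np.testing.assert_array_equal(reduced.values, v[:, res.medoid_indices])
        # one representative per planted group
        groups = {tuple(sorted(range(g * 4, g * 4 + 4))) for g in range(3)}
        for m in res.medoid_indices:
            assert any(m in g for g in groups)

    def test_index_mismatch_rejected(self):
        v = np.random.default_rng(18).standard_normal((10, 6))
        res = kmedoids(v, k=2, n_init=2, seed=0)
        with pytest.raises(ValueError):
            select_medoids(_table(v[:, :5]), res)

    def test_json_roundtrip(self, tmp_path):
        v = np.random.default_rng(19).standard_normal((10, 6))
        res = kmedoids(v, k=2, n_init=2, seed=1)
        save_clustering(res, tmp_path / "c.json")
        back = load_clustering(tmp_path / "c.json")
        assert back.k == res.k
        np.testing.assert_array_equal(back.assignment, res.assignment)
        np.testing.assert_array_equal(back.medoid_indices, res.medoid_indices)
        assert back.inner_distance_sum == pytest.approx(res.inner_distance_sum)
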