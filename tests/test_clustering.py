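"""k-means behaviour, the Calinski-Harabasz index, and K selection."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from cnvpheno.clustering import (
    adjusted_rand_index,
    calinski_index,
    characterize_clusters,
    kmeans,
    select_k,
)
from cnvpheno.simulate import GeneratorConfig, generate_phenotypes


def _two_block_data(n_a=40, n_b=38, n_features=80, p_a=0.8, p_b=0.1, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack(
        [
            (rng.random((n_a, n_features)) < p_a).astype(float),
            (rng.random((n_b, n_features)) < p_b).astype(float),
        ]
    )
    truth = np.array([1] * n_a + [2] * n_b)
    return x, truth


class TestKmeans:
    def test_singleton_clusters_zero_wss(self):
        x = np.arange(12, dtype=float).reshape(4, 3)
        labels, _, wss = kmeans(x, k=4, restarts=5, seed=0)
        assert wss == pytest.approx(0.0)
        assert sorted(labels) == [1, 2, 3, 4]

    def test_duplicated_rows_perfect_split(self):
        u = np.array([1.0, 0.0, 1.0, 0.0])
        v = np.array([0.0, 1.0, 0.0, 1.0])
        x = np.vstack([np.tile(u, (10, 1)), np.tile(v, (10, 1))])
        labels, centroids, wss = kmeans(x, k=2, restarts=5, seed=0)
        assert wss == pytest.approx(0.0)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]
        recovered = {tuple(c) for c in centroids}
        assert recovered == {tuple(u), tuple(v)}

    def test_deterministic_given_seed(self):
        x, _ = _two_block_data(seed=5)
        first = kmeans(x, 2, restarts=10, seed=42)
        second = kmeans(x, 2, restarts=10, seed=42)
        assert np.array_equal(first[0], second[0])
        assert np.array_equal(first[1], second[1])
        assert first[2] == second[2]

    def test_k_exceeding_distinct_rows_errors(self):
        x = np.vstack([np.zeros(3), np.zeros(3), np.ones(3)])
        with pytest.raises(ValueError, match="distinct rows"):
            kmeans(x, k=3)

    def test_recovers_planted_blocks(self):
        aris = []
        for seed in range(20):
            x, truth = _two_block_data(seed=seed)
            labels, _, _ = kmeans(x, 2, restarts=10, seed=seed)
            aris.append(adjusted_rand_index(labels, truth))
        assert min(aris) >= 0.95


class TestCalinskiIndex:
    def test_hand_computed_value(self):
        """1-D points (0,1,10,11) split in the middle: B=100, W=1, CH=200."""
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = [1, 1, 2, 2]
        assert calinski_index(x, labels) == pytest.approx(200.0)

    def test_zero_within_variance_sentinel(self):
        x = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert math.isinf(calinski_index(x, [1, 1, 2, 2]))

    def test_matches_sklearn_reference(self):
        """Agreement with an independent implementation on random instances."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            n, d = int(rng.integers(8, 40)), int(rng.integers(2, 10))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, d))
            labels = rng.integers(1, k + 1, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert calinski_index(x, labels) == pytest.approx(
                calinski_harabasz_score(x, labels), rel=1e-9
            )

    def test_random_labels_on_homogeneous_data_near_one(self):
        rng = np.random.default_rng(12)
        values = []
        for _ in range(100):
            x = rng.normal(size=(40, 5))
            labels = rng.integers(1, 3, size=40)
            if len(np.unique(labels)) < 2:
                continue
            values.append(calinski_index(x, labels))
        assert np.mean(values) == pytest.approx(1.0, abs=0.25)

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            calinski_index(np.zeros((4, 2)), [1, 1, 1, 1])


class TestSelectK:
    def test_planted_two_clusters(self):
        x, _ = _two_block_data(seed=0)
        result = select_k(x, restarts=10, seed=0)
        assert result.chosen_k == 2
        assert set(result.per_k_ch) == set(range(2, 11))
        assert result.per_k_ch[result.chosen_k] == max(result.per_k_ch.values())

    def test_assignments_cover_all_rows(self):
        x, _ = _two_block_data(seed=1)
        result = select_k(x, restarts=5, seed=1)
        assert len(result.assignments) == x.shape[0]
        assert set(result.assignments).issubset(set(range(1, result.chosen_k + 1)))

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            select_k(np.zeros((5, 2)), k_range=[1, 2])


class TestCharacterizeClusters:
    def test_identical_clusters_show_no_signal(self, study):
        """Random labels on one homogeneous cluster's data: no q < 0.05."""
        sub = study.matrix.subset(study.matrix.subjects[40:])  # low-burden cluster
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 3, size=sub.n_subjects)
        from cnvpheno.clustering import ClusterResult
        import pandas as pd

        result = ClusterResult(
            assignments=pd.Series(labels, index=sub.subjects),
            centroids=np.zeros((2, len(sub.features))),
            wss=0.0, per_k_ch={2: 1.0}, chosen_k=2, seed=0, restarts=1,
        )
        character = characterize_clusters(sub, result)
        assert (character.feature_table["q_value"] >= 0.05).all()
        assert character.count_tests["p_value"].iloc[0] > 0.05

    def test_planted_burden_difference_detected(self, study):
        result = select_k(study.matrix, restarts=20, seed=2)
        character = characterize_clusters(study.matrix, result)
        assert character.count_tests["p_value"].iloc[0] < 0.05
        means = sorted(character.mean_counts)
        assert character.mean_counts.max() > character.mean_counts.min() + 10

    def test_single_cluster_errors(self, study):
        from cnvpheno.clustering import ClusterResult
        import pandas as pd

        result = ClusterResult(
            assignments=pd.Series(1, index=study.matrix.subjects),
            centroids=np.zeros((1, len(study.matrix.features))),
            wss=0.0, per_k_ch={}, chosen_k=1, seed=0, restarts=1,
        )
        with pytest.raises(ValueError):
            characterize_clusters(study.matrix, result)


class TestAdjustedRandIndex:
    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = rng.integers(0, 4, size=30)
            b = rng.integers(0, 3, size=30)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_perfect_and_relabeled_agreement(self):
        a = np.array([1, 1, 2, 2, 3])
        assert adjusted_rand_index(a, a) == 1.0
        assert adjusted_rand_index(a, a + 10) == 1.0
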