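"""Gaussian KL, k-NN accuracy, centroids and distance-to-target rewards."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motiondda import (
    LABELS,
    LatentEmbedding,
    PriorMixture,
    compute_centroids,
    gaussian_kl,
    knn_accuracy,
    latent_distances,
    mean_cluster_kl,
    sample_prior,
)
from motiondda.latent_eval import CentroidSet


class TestGaussianKL:
    def test_identical_gaussians_have_zero_divergence(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert gaussian_kl([1, 2], cov, [1, 2], cov) == 0.0

    def test_unit_mean_shift_with_identity_covariances_is_half(self):
        I = np.eye(2)
        assert gaussian_kl([0, 0], I, [1, 0], I) == pytest.approx(0.5)

    def test_doubled_covariance_case_matches_hand_computation(self):
        # 0.5 * (1 - 2 + ln 4) = 0.19314718...
        val = gaussian_kl([0, 0], np.eye(2), [0, 0], 2 * np.eye(2))
        assert val == pytest.approx(0.5 * (1 - 2 + np.log(4)))

    def test_divergence_is_asymmetric(self):
        p = ([0.0, 0.0], np.eye(2))
        q = ([2.0, 0.0], np.diag([3.0, 0.5]))
        assert gaussian_kl(*p, *q) != pytest.approx(gaussian_kl(*q, *p))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_divergence_is_non_negative_for_random_gaussians(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 2, 2))
        cov_p = a @ a.T + 0.1 * np.eye(2)
        cov_q = b @ b.T + 0.1 * np.eye(2)
        assert gaussian_kl(rng.normal(size=2), cov_p, rng.normal(size=2), cov_q) >= 0.0

    def test_singular_covariance_is_regularized_not_fatal(self):
        val = gaussian_kl([0, 0], np.eye(2), [0, 0], np.diag([1.0, 0.0]))
        assert np.isfinite(val) and val > 0


class TestMeanClusterKL:
    def _prior_embedding(self, n_per, rng_seed=0, offset=0.0):
        mix = PriorMixture()
        labels = np.repeat(np.arange(6), n_per)
        pts, _ = sample_prior(mix, len(labels), labels, rng_seed=rng_seed)
        return LatentEmbedding(pts + offset, labels), mix

    def test_embedding_drawn_from_prior_scores_near_zero(self):
        emb_small, mix = self._prior_embedding(50)
        emb_large, _ = self._prior_embedding(2000)
        m_small = mean_cluster_kl(emb_small, mix)
        m_large = mean_cluster_kl(emb_large, mix)
        assert m_large < m_small
        assert m_large < 0.01

    def test_shifted_embedding_scores_strictly_worse(self):
        emb, mix = self._prior_embedding(500)
        shifted, _ = self._prior_embedding(500, offset=2.0)
        assert mean_cluster_kl(shifted, mix) > mean_cluster_kl(emb, mix)

    def test_mean_is_over_the_six_per_label_divergences(self):
        emb, mix = self._prior_embedding(100, rng_seed=3)
        per_label = []
        for k in range(6):
            pts = emb.points[emb.labels == k]
            per_label.append(
                gaussian_kl(mix.means()[k], mix.covariances()[k],
                            pts.mean(axis=0), np.cov(pts, rowvar=False, ddof=1))
            )
        assert mean_cluster_kl(emb, mix) == pytest.approx(np.mean(per_label))

    def test_optimal_assignment_recovers_a_permuted_embedding(self):
        # points drawn from the prior but with labels cyclically shifted:
        # label matching scores badly, optimal matching stays near zero
        mix = PriorMixture()
        labels = np.repeat(np.arange(6), 500)
        pts, _ = sample_prior(mix, len(labels), labels, rng_seed=4)
        shifted = LatentEmbedding(pts, (labels + 1) % 6)
        assert mean_cluster_kl(shifted, mix, assignment="label") > 1.0
        assert mean_cluster_kl(shifted, mix, assignment="optimal") < 0.05

    def test_tiny_cluster_is_rejected(self):
        emb = LatentEmbedding(np.zeros((2, 2)), np.array([0, 0]))
        with pytest.raises(ValueError, match=">= 3"):
            mean_cluster_kl(emb, PriorMixture())


class TestKnnAccuracy:
    def _clusters(self, rng, spread=0.05):
        centers = 10 * np.array([[np.cos(a), np.sin(a)]
                                 for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)])
        labels = np.repeat(np.arange(6), 30)
        pts = centers[labels] + rng.normal(0, spread, size=(180, 2))
        return pts, labels

    def test_well_separated_clusters_score_one(self, rng):
        pts, labels = self._clusters(rng)
        emb = LatentEmbedding(pts, labels)
        assert knn_accuracy(emb, emb, k=10) == 1.0

    def test_matches_brute_force_oracle_on_random_points(self, rng):
        train = LatentEmbedding(rng.normal(size=(50, 2)), rng.integers(0, 6, 50))
        test = LatentEmbedding(rng.normal(size=(50, 2)), rng.integers(0, 6, 50))
        k = 10
        correct = 0
        train_names = np.array([LABELS[i] for i in train.labels])
        for p, true_lab in zip(test.points, test.labels):
            d = np.linalg.norm(train.points - p, axis=1)
            nearest = np.argsort(d, kind="stable")[:k]
            votes: dict[str, int] = {}
            sums: dict[str, float] = {}
            for j in nearest:
                lab = train_names[j]
                votes[lab] = votes.get(lab, 0) + 1
                sums[lab] = sums.get(lab, 0.0) + d[j]
            best = max(votes.values())
            tied = [lab for lab, c in votes.items() if c == best]
            pred = min(tied, key=lambda lab: (sums[lab], LABELS.index(lab)))
            correct += pred == LABELS[true_lab]
        assert knn_accuracy(train, test, k=k) == pytest.approx(correct / 50)

    def test_invariant_under_joint_rigid_transform(self, rng):
        pts, labels = self._clusters(rng, spread=3.0)
        test_pts = pts + rng.normal(0, 3.0, size=pts.shape)
        base = knn_accuracy(LatentEmbedding(pts, labels),
                            LatentEmbedding(test_pts, labels))
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([5.0, -7.0])
        moved = knn_accuracy(LatentEmbedding(pts @ R.T + shift, labels),
                             LatentEmbedding(test_pts @ R.T + shift, labels))
        assert moved == pytest.approx(base)

    def test_empty_test_set_is_rejected(self, rng):
        train = LatentEmbedding(rng.normal(size=(20, 2)), rng.integers(0, 6, 20))
        with pytest.raises(ValueError, match="empty"):
            knn_accuracy(train, LatentEmbedding(np.empty((0, 2)), np.empty(0, dtype=int)))


class TestCentroids:
    def test_single_point_per_label_gives_the_points_back(self, rng):
        pts = rng.normal(size=(6, 2))
        cents = compute_centroids(LatentEmbedding(pts, np.arange(6)))
        for i, lab in enumerate(LABELS):
            np.testing.assert_allclose(cents.centroids[lab], pts[i])

    def test_symmetric_cluster_centroid_is_origin(self, rng):
        sym = np.array([[1.0, 2.0], [-1.0, -2.0], [3.0, -1.0], [-3.0, 1.0]])
        pts = np.vstack([sym] + [rng.normal(size=(1, 2)) for _ in range(5)])
        labels = np.array([0] * 4 + list(range(1, 6)))
        cents = compute_centroids(LatentEmbedding(pts, labels))
        np.testing.assert_allclose(cents.centroids[LABELS[0]], [0.0, 0.0], atol=1e-12)

    def test_matches_manual_mean_on_listed_points(self):
        cluster = np.array([[0, 0], [1, 0], [2, 3], [-1, 1], [3, 1]], dtype=float)
        pts = np.vstack([cluster, np.zeros((5, 2))])
        labels = np.array([2] * 5 + [0, 1, 3, 4, 5])
        cents = compute_centroids(LatentEmbedding(pts, labels))
        np.testing.assert_allclose(cents.centroids[LABELS[2]], [1.0, 1.0])

    def test_missing_label_is_rejected_by_name(self, rng):
        emb = LatentEmbedding(rng.normal(size=(5, 2)), np.arange(5))
        with pytest.raises(ValueError, match=LABELS[5]):
            compute_centroids(emb)


class TestLatentDistances:
    def _embedding(self, rng, n_sched=20, n_noise=3):
        n = 6 * n_sched * n_noise
        labels = np.repeat(np.arange(6), n_sched * n_noise)
        sched = np.tile(np.repeat(np.arange(n_sched), n_noise), 6)
        noise = np.tile(np.arange(n_noise), 6 * n_sched)
        return LatentEmbedding(rng.normal(size=(n, 2)), labels,
                               schedule_index=sched, noise_index=noise)

    def _centroids(self, rng):
        return CentroidSet({lab: rng.normal(size=2) for lab in LABELS})

    def test_point_at_its_centroid_has_zero_distance(self):
        cents = CentroidSet({lab: np.array([float(i), 0.0])
                             for i, lab in enumerate(LABELS)})
        pts = np.array([[float(i), 0.0] for i in range(6)])
        emb = LatentEmbedding(pts, np.arange(6),
                              schedule_index=np.zeros(6, int),
                              noise_index=np.zeros(6, int))
        seq = latent_distances(emb, cents)
        np.testing.assert_allclose(seq.distances, 0.0)

    def test_pythagorean_distance(self):
        cents = CentroidSet({lab: np.zeros(2) for lab in LABELS})
        pts = np.tile([3.0, 4.0], (6, 1))
        emb = LatentEmbedding(pts, np.arange(6),
                              schedule_index=np.zeros(6, int),
                              noise_index=np.zeros(6, int))
        np.testing.assert_allclose(latent_distances(emb, cents).distances, 5.0)

    def test_standard_dataset_yields_60_iterations_per_label(self, rng):
        seq = latent_distances(self._embedding(rng), self._centroids(rng))
        assert seq.distances.shape == (6, 60)
        assert np.all(seq.distances >= 0)

    def test_iterations_are_ordered_by_schedule_then_noise(self, rng):
        emb = self._embedding(rng, n_sched=2, n_noise=2)
        cents = self._centroids(rng)
        seq = latent_distances(emb, cents)
        mask = emb.labels == 0
        pts = emb.points[mask]
        order = np.lexsort((emb.noise_index[mask], emb.schedule_index[mask]))
        expected = np.linalg.norm(pts[order] - cents.centroids[LABELS[0]], axis=1)
        np.testing.assert_allclose(seq.distances[0], expected)

    def test_invariant_under_joint_translation(self, rng):
        emb = self._embedding(rng)
        cents = self._centroids(rng)
        base = latent_distances(emb, cents).distances
        shift = np.array([11.0, -4.0])
        emb2 = LatentEmbedding(emb.points + shift, emb.labels,
                               schedule_index=emb.schedule_index,
                               noise_index=emb.noise_index)
        cents2 = CentroidSet({k: v + shift for k, v in cents.centroids.items()})
        np.testing.assert_allclose(latent_distances(emb2, cents2).distances, base,
                                   atol=1e-9)
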