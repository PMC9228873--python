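"""Latent-space quality metrics and distance-to-target reward extraction.

Quality is measured two ways: the mean closed-form KL divergence between each
prior mixture component and a Gaussian fitted to its label's embedded points
(lower is better), and k-nearest-neighbour classification accuracy of test
embeddings against train embeddings (higher is better).  For the bandit
stage, each embedded test point is reduced to the Euclidean distance to its
label's target centroid, ordered by schedule progression into a 60-iteration
reward sequence per label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from motiondda.shapes import LABELS

logger = logging.getLogger(__name__)

_REG_EPS = 1e-8


@dataclass
class LatentEmbedding:
    """2-D encoder outputs with labels and optional schedule annotations."""

    points: np.ndarray
    labels: np.ndarray
    schedule_index: np.ndarray | None = None
    noise_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.labels) != len(self.points):
            raise ValueError("one label per point required")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("embedding contains non-finite coordinates")


@dataclass
class CentroidSet:
    """One target centroid per label, from the embedded reference motions."""

    centroids: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.centroids) != set(LABELS):
            raise ValueError(f"expected exactly the {len(LABELS)} labels {LABELS}")


@dataclass
class RewardSequence:
    """Per-label distance trajectories d_l(t), t = 1..horizon.

    ``distances`` has shape (n_labels, horizon), rows ordered as ``labels``.
    """

    distances: np.ndarray
    labels: tuple[str, ...] = LABELS
    subject: int = 0

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 2 or self.distances.shape[0] != len(self.labels):
            raise ValueError("distances must be (n_labels, horizon)")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @property
    def horizon(self) -> int:
        return self.distances.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": self.subject, "label": lab, "t": t + 1, "distance": d}
            for i, lab in enumerate(self.labels)
            for t, d in enumerate(self.distances[i])
        ]
        return pd.DataFrame(rows)


def _regularize(cov: np.ndarray, name: str) -> np.ndarray:
    """Return a positive-definite version of cov, nudging by +eps*I if needed."""
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"{name} covariance is not symmetric")
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        logger.warning("%s covariance singular; regularizing by +%gI", name, _REG_EPS)
        reg = cov + _REG_EPS * np.eye(cov.shape[0])
        np.linalg.cholesky(reg)  # raises if still not PD
        return reg


def gaussian_kl(
    mean_p: np.ndarray, cov_p: np.ndarray, mean_q: np.ndarray, cov_q: np.ndarray
) -> float:
    """Closed-form KL divergence D(p || q) between two Gaussians.

    D = 1/2 [ tr(Σq⁻¹Σp) + (μq−μp)ᵀΣq⁻¹(μq−μp) − γ + ln(det Σq / det Σp) ]
    with γ the dimension.  Non-negative; zero iff the distributions coincide.
    """
    mean_p = np.asarray(mean_p, dtype=float)
    mean_q = np.asarray(mean_q, dtype=float)
    cov_p = _regularize(cov_p, "p")
    cov_q = _regularize(cov_q, "q")
    d = mean_p.shape[0]
    cov_q_inv = np.linalg.inv(cov_q)
    diff = mean_q - mean_p
    _, logdet_p = np.linalg.slogdet(cov_p)
    _, logdet_q = np.linalg.slogdet(cov_q)
    kl = 0.5 * (
        np.trace(cov_q_inv @ cov_p) + diff @ cov_q_inv @ diff - d + logdet_q - logdet_p
    )
    return float(max(kl, 0.0))


def mean_cluster_kl(
    embedding: LatentEmbedding, mixture, assignment: str = "label"
) -> float:
    """Mean KL from each prior component to the Gaussian fitted to its cluster.

    Each label's embedded points are summarised by their sample mean and
    covariance q; the divergence D(prior component p || q) is averaged over
    the labels present.  With ``assignment="label"`` (the default) labels map
    to components by their index in :data:`~motiondda.shapes.LABELS` — the
    semi-supervised convention, where the discriminator pins each label to
    its own component.  With ``assignment="optimal"`` clusters are matched to
    components by minimum-cost assignment, appropriate for unsupervised
    embeddings whose cluster-to-component correspondence is arbitrary.
    """
    if assignment not in ("label", "optimal"):
        raise ValueError("assignment must be 'label' or 'optimal'")
    means = mixture.means()
    covs = mixture.covariances()
    names = _label_array_to_names(embedding.labels)
    labels_present = [lab for lab in LABELS if np.any(names == lab)]
    if not labels_present:
        raise ValueError("embedding has no recognised labels")
    fitted = []
    for lab in labels_present:
        pts = embedding.points[names == lab]
        if len(pts) < 3:
            raise ValueError(f"label {lab!r} has {len(pts)} points; >= 3 required")
        fitted.append((pts.mean(axis=0), np.cov(pts, rowvar=False, ddof=1)))
    if assignment == "label":
        kls = [
            gaussian_kl(means[LABELS.index(lab)], covs[LABELS.index(lab)], mu_q, cov_q)
            for lab, (mu_q, cov_q) in zip(labels_present, fitted)
        ]
        return float(np.mean(kls))
    from scipy.optimize import linear_sum_assignment

    cost = np.array([
        [gaussian_kl(means[k], covs[k], mu_q, cov_q) for mu_q, cov_q in fitted]
        for k in range(mixture.n_components)
    ])
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def _label_array_to_names(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if np.issubdtype(labels.dtype, np.integer):
        return np.array([LABELS[i] for i in labels])
    return labels


def knn_accuracy(
    train_embedding: LatentEmbedding,
    test_embedding: LatentEmbedding,
    k: int = 10,
) -> float:
    """k-NN majority-vote accuracy of test points against train points.

    Ties in the vote are broken by the smallest summed neighbour distance
    among the tied classes, then by label order, so predictions are
    deterministic.
    """
    if len(test_embedding.points) == 0:
        raise ValueError("empty test set")
    if k > len(train_embedding.points):
        raise ValueError(f"k={k} exceeds {len(train_embedding.points)} training points")
    train_labels = _label_array_to_names(train_embedding.labels)
    test_labels = _label_array_to_names(test_embedding.labels)
    nn = NearestNeighbors(n_neighbors=k).fit(train_embedding.points)
    dist, idx = nn.kneighbors(test_embedding.points)
    correct = 0
    for row_labels, row_dist, truth in zip(train_labels[idx], dist, test_labels):
        counts: dict[str, int] = {}
        sums: dict[str, float] = {}
        for lab, d in zip(row_labels, row_dist):
            counts[lab] = counts.get(lab, 0) + 1
            sums[lab] = sums.get(lab, 0.0) + d
        best = max(counts.values())
        tied = [lab for lab, c in counts.items() if c == best]
        pred = min(tied, key=lambda lab: (sums[lab], LABELS.index(lab)))
        correct += pred == truth
    return correct / len(test_labels)


def compute_centroids(reference_embedding: LatentEmbedding) -> CentroidSet:
    """Per-label arithmetic mean of the reference embedding coordinates."""
    names = _label_array_to_names(reference_embedding.labels)
    missing = [lab for lab in LABELS if lab not in names]
    if missing:
        raise ValueError(f"missing label(s) in reference embedding: {', '.join(missing)}")
    cents = {
        lab: reference_embedding.points[names == lab].mean(axis=0) for lab in LABELS
    }
    return CentroidSet(cents)


def latent_distances(
    test_embedding: LatentEmbedding, centroids: CentroidSet, subject: int = 0
) -> RewardSequence:
    """Euclidean distance of each point to its own label's target centroid.

    Points are ordered into iterations t = 1..horizon by ascending schedule
    index, with noise replicates occupying consecutive iterations (so a
    20-point schedule with 3 replicates yields a 60-iteration sequence).
    """
    if test_embedding.schedule_index is None or test_embedding.noise_index is None:
        raise ValueError("embedding must carry schedule_index and noise_index annotations")
    names = _label_array_to_names(test_embedding.labels)
    sched = np.asarray(test_embedding.schedule_index)
    noise = np.asarray(test_embedding.noise_index)
    per_label = []
    horizon = None
    for lab in LABELS:
        mask = names == lab
        order = np.lexsort((noise[mask], sched[mask]))
        pts = test_embedding.points[mask][order]
        d = np.linalg.norm(pts - centroids.centroids[lab], axis=1)
        if horizon is None:
            horizon = len(d)
        elif len(d) != horizon:
            raise ValueError("labels have unequal numbers of points")
        per_label.append(d)
    return RewardSequence(np.stack(per_label), labels=LABELS, subject=subject)
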