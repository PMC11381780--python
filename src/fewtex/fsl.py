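"""N-way K-shot episodes: sampling, Euclidean distances, KNN prediction.

An episode draws K support vectors per class (the support set) and
classifies every remaining vector in the pool (the query set) by the
majority label among its k nearest support vectors under the Euclidean
metric D(s, q) = sqrt(sum_i (s_i - q_i)^2).  For the reference task this
is 3-way 3-shot: 9 support images, 9 distances per query.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

from fewtex.metrics import confusion_matrix

__all__ = [
    "Episode", "KnnConfig", "sample_episode", "euclidean_distance",
    "distance_matrix", "knn_predict", "run_episode", "zscore_by_support",
]


@dataclasses.dataclass(frozen=True)
class Episode:
    """Support set (N classes x K shots) plus disjoint query set."""

    n_way: int
    k_shot: int
    support_vectors: np.ndarray  # (N*K, dim)
    support_labels: np.ndarray  # (N*K,)
    query_vectors: np.ndarray  # (Q, dim)
    query_labels: np.ndarray  # (Q,)
    support_ids: tuple[str, ...] = ()
    query_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.support_vectors.shape[0] != self.n_way * self.k_shot:
            raise ValueError("support must contain exactly N*K items")
        counts = np.bincount(self.support_labels, minlength=self.n_way)
        if not np.all(counts[:self.n_way] == self.k_shot):
            raise ValueError("support must contain exactly K items per class")
        if self.query_vectors.shape[1] != self.support_vectors.shape[1]:
            raise ValueError("support and query vectors must share dimensionality")


@dataclasses.dataclass(frozen=True)
class KnnConfig:
    k: int = 3
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def sample_episode(
    vectors: np.ndarray,
    labels: np.ndarray,
    n_way: int,
    k_shot: int,
    seed: int,
    sample_ids: list[str] | None = None,
) -> Episode:
    """Draw K support items per class without replacement; the rest are queries.

    Classes are the label values 0..n_way-1; a class with <= K items is
    rejected by name so the caller knows which class is too small.
    """
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    support_idx = []
    for cls in range(n_way):
        idx = np.nonzero(labels == cls)[0]
        if idx.size <= k_shot:
            raise ValueError(
                f"class {cls} has {idx.size} items; need more than K={k_shot} to form a query set"
            )
        support_idx.extend(rng.choice(idx, size=k_shot, replace=False))
    support_idx = np.array(support_idx)
    query_mask = np.ones(len(labels), dtype=bool)
    query_mask[support_idx] = False
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(labels))]
    return Episode(
        n_way=n_way,
        k_shot=k_shot,
        support_vectors=vectors[support_idx],
        support_labels=labels[support_idx],
        query_vectors=vectors[query_mask],
        query_labels=labels[query_mask],
        support_ids=tuple(ids[i] for i in support_idx),
        query_ids=tuple(ids[i] for i in np.nonzero(query_mask)[0]),
    )


def euclidean_distance(s: np.ndarray, q: np.ndarray) -> float:
    """D(s, q) = sqrt(sum_i (s_i - q_i)^2)."""
    s = np.asarray(s, dtype=float)
    q = np.asarray(q, dtype=float)
    if s.shape != q.shape:
        raise ValueError(f"dimension mismatch: {s.shape} vs {q.shape}")
    return float(np.sqrt(np.sum((s - q) ** 2)))


def distance_matrix(episode: Episode) -> np.ndarray:
    """All query-to-support Euclidean distances, shape (|query|, N*K)."""
    return cdist(episode.query_vectors, episode.support_vectors, metric="euclidean")


def knn_predict(distances: np.ndarray, support_labels: np.ndarray, config: KnnConfig = KnnConfig()) -> int:
    """Majority label among the k nearest supports, deterministically tie-broken.

    Neighbors are ranked by (distance, support index) — a stable order —
    and the majority label among the first k wins.  A tied vote goes to
    the tied class whose voting neighbors have the smallest mean
    distance, then to the smallest class index.
    """
    distances = np.asarray(distances, dtype=float)
    support_labels = np.asarray(support_labels, dtype=int)
    if distances.size == 0:
        raise ValueError("empty distance row")
    if config.k > distances.size:
        raise ValueError(f"k={config.k} exceeds the {distances.size} support items")
    order = np.lexsort((np.arange(distances.size), distances))
    top = order[:config.k]
    top_labels = support_labels[top]
    votes = np.bincount(top_labels)
    best = votes.max()
    tied = np.nonzero(votes == best)[0]
    if tied.size == 1:
        return int(tied[0])
    means = [distances[top[top_labels == cls]].mean() for cls in tied]
    return int(tied[int(np.argmin(means))])  # argmin takes the first (smallest class) on ties


def zscore_by_support(episode: Episode) -> Episode:
    """Z-score every vector per dimension using support-set statistics.

    Used when episode vectors are handcrafted features with
    incommensurate units; zero-variance dimensions are left centered.
    """
    mu = episode.support_vectors.mean(axis=0)
    sd = episode.support_vectors.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return dataclasses.replace(
        episode,
        support_vectors=(episode.support_vectors - mu) / sd,
        query_vectors=(episode.query_vectors - mu) / sd,
    )


def run_episode(episode: Episode, config: KnnConfig = KnnConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Classify every query item; returns (predictions, confusion matrix)."""
    sup = episode.support_vectors
    qry = episode.query_vectors
    if config.normalize:
        norms = np.linalg.norm(sup, axis=1, keepdims=True)
        sup = sup / np.where(norms > 0, norms, 1.0)
        qnorms = np.linalg.norm(qry, axis=1, keepdims=True)
        qry = qry / np.where(qnorms > 0, qnorms, 1.0)
    dm = cdist(qry, sup, metric="euclidean")
    preds = np.array([knn_predict(row, episode.support_labels, config) for row in dm])
    cm = confusion_matrix(episode.query_labels, preds, episode.n_way)
    return preds, cm
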