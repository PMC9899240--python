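"""Clustering-based evaluation and metastability diagnostics.

The embedding quality criterion follows the standard recipe for this
problem: cluster the per-snapshot embeddings with k-means (k = number of
metastable states) and score the agreement with the ground-truth state
labels by the Adjusted Rand Index.  A PCA baseline on flattened adjacency
matrices provides the reference embedding, and the empirical transition
matrix of a label sequence quantifies how metastable a labelling is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .graphgen import TimeEvolvingGraph

__all__ = [
    "kmeans_cluster",
    "adjusted_rand_index",
    "AdjacencyPCA",
    "pca_baseline",
    "metastability_diagnostics",
    "ClusteringResult",
    "temporal_split",
    "evaluate_embedding",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    ari: float
    seed: int


def kmeans_cluster(points: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means labels: k-means++ init, 10 restarts, Lloyd to tol 1e-6."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if k < 1 or k > len(points):
        raise ValueError(f"need 1 <= k <= number of points, got k={k}, T={len(points)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                tol=1e-6, random_state=seed)
    return km.fit_predict(points)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement from the contingency table.

    ARI = (sum_ij C(n_ij,2) - E) / (max_index - E) where E is the
    permutation-model expectation.  Returns 1.0 when both labelings are the
    same degenerate partition (all pairs agree).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 elements")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions degenerate in the same way
        return 1.0 if sum_ij == max_index else 0.0
    return float((sum_ij - expected) / (max_index - expected))


class AdjacencyPCA(BaseEstimator, TransformerMixin):
    """PCA baseline: flatten each snapshot's full adjacency matrix, project.

    The full n^2 matrix (not just the upper triangle) is flattened; for
    symmetric adjacencies this is equivalent up to scaling.  Components are
    fitted on mean-centred flattened snapshots via SVD.
    """

    def __init__(self, d: int = 32):
        self.d = d

    @staticmethod
    def _flatten(g: TimeEvolvingGraph) -> np.ndarray:
        return g.snapshots.reshape(g.T, -1).astype(float)

    def fit(self, g: TimeEvolvingGraph, y=None):
        X = self._flatten(g)
        if self.d > min(X.shape):
            raise ValueError(f"d={self.d} exceeds min(T, n^2)={min(X.shape)}")
        self.pca_ = PCA(n_components=self.d, svd_solver="full")
        self.pca_.fit(X)
        self.n_nodes_ = g.n
        return self

    def transform(self, g: TimeEvolvingGraph) -> np.ndarray:
        if not hasattr(self, "pca_"):
            raise RuntimeError("not fitted")
        if g.n != self.n_nodes_:
            raise ValueError("node count differs from the fitted graph")
        return self.pca_.transform(self._flatten(g))

    def fit_transform(self, g: TimeEvolvingGraph, y=None) -> np.ndarray:
        return self.fit(g).transform(g)


def pca_baseline(g: TimeEvolvingGraph, d: int = 32) -> np.ndarray:
    """Convenience wrapper: fit-and-transform :class:`AdjacencyPCA` on `g`."""
    if g.T < 2:
        raise ValueError("need at least 2 snapshots")
    return AdjacencyPCA(d=d).fit_transform(g)


def metastability_diagnostics(labels, s: int | None = None):
    """Empirical transition matrix of a label sequence and stay-probability.

    Returns (P, stay) where P[i, j] is the empirical probability of moving
    from state i to state j in one step (rows of unvisited states are
    zero), and stay is the mean diagonal over visited states.  A sequence
    is metastable when stay is close to 1.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) < 2:
        raise ValueError("need at least 2 time points")
    if s is None:
        s = int(labels.max()) + 1
    counts = np.zeros((s, s))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    rowsums = counts.sum(axis=1)
    visited = rowsums > 0
    P = np.zeros_like(counts)
    P[visited] = counts[visited] / rowsums[visited, None]
    stay = float(np.diag(P)[visited].mean())
    return P, stay


def temporal_split(T: int, train_fraction: float = 0.8) -> tuple[slice, slice]:
    """Contiguous temporal train/test split (train first, test last)."""
    cut = int(round(T * train_fraction))
    cut = min(max(cut, 1), T - 1)
    return slice(0, cut), slice(cut, T)


def evaluate_embedding(embeddings: np.ndarray, true_labels: np.ndarray, k: int,
                       test_index=None, seed: int = 0) -> ClusteringResult:
    """Cluster embeddings with k-means and score ARI against true labels.

    When ``test_index`` is given, clustering and scoring are restricted to
    those time points (the held-out part of a temporal split).
    """
    embeddings = np.asarray(embeddings)
    true_labels = np.asarray(true_labels)
    if len(embeddings) != len(true_labels):
        raise ValueError("embeddings and labels must align")
    if test_index is not None:
        embeddings = embeddings[test_index]
        true_labels = true_labels[test_index]
    labels = kmeans_cluster(embeddings, k, seed=seed)
    ari = adjusted_rand_index(labels, true_labels)
    return ClusteringResult(labels=labels, k=k, ari=ari, seed=seed)
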