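"""k-means clustering of filtered HVG coefficient vectors.

Genes whose entire filtered coefficient row is zero are dropped; the rest
are clustered on their A-length coefficient vectors with k-means
(k-means++ init, 10 restarts, seeded) for each k in [k_min, k_max], and
the k with the largest mean silhouette wins (ties toward the smaller k).
The silhouette convention: singleton clusters and 0/0 both contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .exceptions import ValidationError


def silhouette_mean(points: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b) over points.

    Singleton-cluster points contribute 0; a degenerate 0/0 is defined
    as 0.
    """
    x = np.asarray(points, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    d = cdist(x, x)
    scores = np.zeros(len(x))
    for i in range(len(x)):
        same = labels == labels[i]
        n_same = same.sum()
        if n_same == 1:
            continue  # singleton contributes 0
        a = d[i, same].sum() / (n_same - 1)
        b = min(d[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        scores[i] = (b - a) / denom if denom > 0 else 0.0
    return float(scores.mean())


@dataclass
class GeneClusterResult:
    """Chosen clustering of one cell type's retained HVGs."""

    cell_type: str
    gene_ids: np.ndarray
    assignments: np.ndarray
    k: int
    silhouette_by_k: dict
    centers: np.ndarray


class GeneClusterer(ClusterMixin, BaseEstimator):
    """Silhouette-selected k-means over gene coefficient vectors.

    Parameters
    ----------
    k_min, k_max : int
        Range of cluster counts evaluated; the upper end is capped at
        n_genes - 1.
    n_init : int
        k-means restarts per k.
    random_state : int

    Attributes
    ----------
    labels_ : cluster index per row (0-based).
    k_ : chosen cluster count.
    silhouette_by_k_ : dict mapping evaluated k to mean silhouette.
    cluster_centers_ : (k, A) ndarray.
    """

    def __init__(self, k_min: int = 2, k_max: int = 15, n_init: int = 10,
                 random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float)
        n = x.shape[0]
        if n < self.k_min + 2:
            raise ValidationError(
                f"need at least k_min + 2 = {self.k_min + 2} genes, got {n}"
            )
        k_hi = min(self.k_max, n - 1)
        best = None
        self.silhouette_by_k_ = {}
        for k in range(self.k_min, k_hi + 1):
            km = KMeans(n_clusters=k, init="k-means++", n_init=self.n_init,
                        random_state=self.random_state)
            labels = km.fit_predict(x)
            sil = silhouette_mean(x, labels)
            self.silhouette_by_k_[k] = sil
            if best is None or sil > best[0]:
                best = (sil, k, labels, km.cluster_centers_)
        _, self.k_, self.labels_, self.cluster_centers_ = best
        return self


def cluster_hvgs(coefficients: np.ndarray, gene_ids, k_min: int = 2, k_max: int = 15,
                 seed: int = 0, n_init: int = 10, cell_type: str = "") -> GeneClusterResult:
    """Drop all-zero coefficient rows and cluster the rest.

    Parameters
    ----------
    coefficients : (H, A) ndarray
        Filtered coefficient vectors, genes as rows.
    gene_ids : sequence of str, length H.
    """
    coef = np.asarray(coefficients, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    nonzero = np.any(coef != 0, axis=1)
    coef = coef[nonzero]
    genes = gene_ids[nonzero]
    model = GeneClusterer(k_min=k_min, k_max=k_max, n_init=n_init,
                          random_state=seed).fit(coef)
    return GeneClusterResult(
        cell_type=cell_type,
        gene_ids=genes,
        assignments=model.labels_,
        k=model.k_,
        silhouette_by_k=model.silhouette_by_k_,
        centers=model.cluster_centers_,
    )
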