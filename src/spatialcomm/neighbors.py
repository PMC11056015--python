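"""Neighbor-cell-type scores from spatial coordinates and labels.

Each cell c receives one scalar per cell type b summarizing the spatial
presence of that type around it:

    f'_{c,b} = sum over cells m != c with label b of log10(dist_{c,m} / dist0)

where dist0 is the minimum pairwise distance in the dataset. Columns are
then z-scored (sample sd) to give the predictor matrix F of the
downstream regression. The score as stated increases with distance; an
alternative exponentially decaying kernel exp(-dist/dist0) is available
via ``kernel="exp_decay"`` for users who want proximity-weighted scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ValidationError


def pairwise_distances(coordinates: np.ndarray) -> np.ndarray:
    """Full Z x Z Euclidean distance matrix (symmetric, zero diagonal)."""
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValidationError("need at least 2 cells with 2-D coordinates")
    if not np.all(np.isfinite(coords)):
        raise ValidationError("non-finite coordinate")
    return squareform(pdist(coords, metric="euclidean"))


def min_pairwise_distance(distances: np.ndarray) -> float:
    """Smallest off-diagonal distance; errors on coincident cells."""
    d = np.asarray(distances, dtype=float)
    z = d.shape[0]
    if z < 2:
        raise ValidationError("need at least 2 cells")
    off = d[~np.eye(z, dtype=bool)]
    dist0 = float(off.min())
    if dist0 <= 0:
        raise ValidationError(
            "coincident cells give a zero minimum pairwise distance; "
            "enable the jitter option or deduplicate coordinates"
        )
    return dist0


def jitter_coordinates(coordinates: np.ndarray, seed: int = 0, scale: float = 1e-6) -> np.ndarray:
    """Displace coordinates by uniform noise of magnitude scale * bounding box."""
    coords = np.asarray(coordinates, dtype=float)
    rng = np.random.default_rng(seed)
    span = float(np.ptp(coords, axis=0).max())
    span = span if span > 0 else 1.0
    return coords + rng.uniform(-scale, scale, size=coords.shape) * span


def zscore_columns(matrix: np.ndarray) -> np.ndarray:
    """Center each column and scale by its sample sd; constant columns -> 0."""
    m = np.asarray(matrix, dtype=float)
    centered = m - m.mean(axis=0, keepdims=True)
    sd = m.std(axis=0, ddof=1, keepdims=True)
    out = np.zeros_like(centered)
    np.divide(centered, sd, out=out, where=sd > 0)
    return out


def raw_neighbor_scores(
    labels: np.ndarray,
    type_order: np.ndarray,
    distances: np.ndarray,
    dist0: float,
    kernel: str = "log10_ratio",
) -> np.ndarray:
    """Raw Z x A score matrix f'_{c,b} (no self term)."""
    if dist0 <= 0:
        raise ValidationError("dist0 must be positive")
    labels = np.asarray(labels, dtype=object)
    d = np.asarray(distances, dtype=float)
    z = d.shape[0]
    if kernel == "log10_ratio":
        with np.errstate(divide="ignore"):
            s = np.log10(d / dist0)
    elif kernel == "exp_decay":
        s = np.exp(-d / dist0)
    else:
        raise ValidationError(f"unknown kernel {kernel!r}")
    np.fill_diagonal(s, 0.0)  # exclude the self term
    raw = np.empty((z, len(type_order)))
    for j, b in enumerate(type_order):
        raw[:, j] = s[:, labels == b].sum(axis=1)
    return raw


@dataclass
class NeighborScoreMatrix:
    """Raw and z-scored per-cell neighbor-type scores."""

    raw: np.ndarray
    zscored: np.ndarray
    dist0: float
    type_order: np.ndarray


def neighbor_score_matrix(
    dataset,
    kernel: str = "log10_ratio",
    jitter: bool = False,
    jitter_seed: int = 0,
) -> NeighborScoreMatrix:
    """Compute the full :class:`NeighborScoreMatrix` for a dataset."""
    coords = dataset.coordinates
    if jitter:
        coords = jitter_coordinates(coords, seed=jitter_seed)
    d = pairwise_distances(coords)
    dist0 = min_pairwise_distance(d)
    raw = raw_neighbor_scores(dataset.labels, dataset.cell_types, d, dist0, kernel=kernel)
    return NeighborScoreMatrix(
        raw=raw, zscored=zscore_columns(raw), dist0=dist0, type_order=dataset.cell_types
    )


class NeighborScorer(TransformerMixin, BaseEstimator):
    """Transformer facade over :func:`neighbor_score_matrix`.

    ``transform`` maps a :class:`~spatialcomm.io.SpatialExpressionDataset`
    to the z-scored Z x A score matrix.
    """

    def __init__(self, kernel: str = "log10_ratio", jitter: bool = False, jitter_seed: int = 0):
        self.kernel = kernel
        self.jitter = jitter
        self.jitter_seed = jitter_seed

    def fit(self, X, y=None):
        self.result_ = neighbor_score_matrix(
            X, kernel=self.kernel, jitter=self.jitter, jitter_seed=self.jitter_seed
        )
        self.type_order_ = self.result_.type_order
        return self

    def transform(self, X):
        result = neighbor_score_matrix(
            X, kernel=self.kernel, jitter=self.jitter, jitter_seed=self.jitter_seed
        )
        return result.zscored
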