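"""Directed MIMO cell-type communication graph.

Per receiver type, gene-cluster coefficient rows are averaged into a
cluster x sender matrix; each receiver keeps its k_min largest-norm
clusters (k_min = the minimum cluster count over receivers, so cluster
counts never bias the comparison) and the sender->receiver weight is the
Euclidean norm over kept clusters. The aggregated matrix is thresholded
at the mean of its off-diagonal entries, and indirect communication is
accumulated over all simple directed paths with per-edge attenuation:
an edge at position s along a path contributes weight - mean * 10^(1-s),
so later edges are discounted toward their full weight. All matrices are
stored sender x receiver: entry (i, j) is the weight of edge i -> j.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .exceptions import ValidationError
from .io import FLOAT_FMT, write_edge_list_csv, write_matrix_tsv


def cluster_coefficient_matrix(coefficients: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """Average filtered coefficients over each gene cluster.

    Parameters
    ----------
    coefficients : (H, A) ndarray
        Filtered coefficient vectors of the retained genes (rows).
    assignments : (H,) ndarray
        0-based cluster index per gene.

    Returns
    -------
    (k, A) ndarray with row m the mean coefficient vector of cluster m.
    """
    coef = np.asarray(coefficients, dtype=float)
    labels = np.asarray(assignments)
    k = int(labels.max()) + 1
    out = np.empty((k, coef.shape[1]))
    for m in range(k):
        members = labels == m
        if not members.any():
            raise ValidationError(f"cluster {m} is empty")
        out[m] = coef[members].mean(axis=0)
    return out


def aggregate_pair_weights(cluster_matrices: dict, type_order, k_min: int | None = None) -> tuple[np.ndarray, int]:
    """Aggregate per-receiver cluster matrices into the A x A weight matrix.

    Parameters
    ----------
    cluster_matrices : dict mapping receiver type -> (k_a, A) ndarray
        Cluster-level coefficients toward each sender type.
    type_order : sequence of the A type names (matrix column order).
    k_min : int, optional
        Number of clusters kept per receiver; defaults to the minimum
        cluster count over receivers. Each receiver keeps its ``k_min``
        largest-L2-norm cluster rows.

    Returns
    -------
    weights : (A, A) ndarray, entry (i, j) = weight of sender i -> receiver j.
    k_min : int actually used.
    """
    type_order = list(type_order)
    a = len(type_order)
    counts = {t: m.shape[0] for t, m in cluster_matrices.items()}
    auto_min = min(counts.values()) if counts else 0
    if k_min is None:
        k_min = auto_min
    if k_min < 1:
        raise ValidationError("k_min must be >= 1")
    if any(k_min > c for c in counts.values()):
        raise ValidationError(
            f"k_min={k_min} exceeds a receiver's cluster count {counts}"
        )
    weights = np.zeros((a, a))
    for j, receiver in enumerate(type_order):
        m = np.asarray(cluster_matrices.get(receiver))
        if m is None or m.ndim != 2:
            continue
        norms = np.linalg.norm(m, axis=1)
        kept = np.argsort(-norms, kind="stable")[:k_min]
        weights[:, j] = np.sqrt((m[kept] ** 2).sum(axis=0))
    return weights, int(k_min)


def threshold_by_mean(aggregated: np.ndarray) -> tuple[np.ndarray, float]:
    """Zero the diagonal and every entry below the off-diagonal mean."""
    w = np.asarray(aggregated, dtype=float)
    a = w.shape[0]
    if a < 2 or w.shape[1] != a:
        raise ValidationError("aggregated matrix must be square with A >= 2")
    off = ~np.eye(a, dtype=bool)
    mean_weight = float(w[off].mean())
    out = np.where(w >= mean_weight, w, 0.0)
    np.fill_diagonal(out, 0.0)
    return out, mean_weight


def attenuate_paths(thresholded: np.ndarray, mean_weight: float,
                    max_path_len: int | None = None) -> np.ndarray:
    """Sum attenuated contributions of all simple directed paths.

    For a path with edges e_1..e_L the contribution is
    ``sum_s weight(e_s) - mean_weight * 10**(1 - s)``; R[src, dst] is the
    sum over all simple paths from src to dst (0 when none exists). After
    mean-thresholding every term is nonnegative.
    """
    w = np.asarray(thresholded, dtype=float)
    a = w.shape[0]
    if np.any(np.diagonal(w) != 0):
        raise ValidationError("thresholded matrix must have a zero diagonal")
    cutoff = max_path_len if max_path_len is not None else a - 1
    g = nx.DiGraph()
    g.add_nodes_from(range(a))
    for i, j in np.argwhere(w != 0):
        g.add_edge(int(i), int(j), weight=w[i, j])
    r = np.zeros((a, a))
    for src in range(a):
        for dst in range(a):
            if src == dst:
                continue
            total = 0.0
            for path in nx.all_simple_paths(g, src, dst, cutoff=cutoff):
                for s, (i, j) in enumerate(zip(path[:-1], path[1:]), start=1):
                    total += w[i, j] - mean_weight * 10.0 ** (1 - s)
            r[src, dst] = total
    return r


@dataclass
class CommunicationGraph:
    """Aggregated, thresholded and path-attenuated cell-type matrices.

    All matrices are sender x receiver over ``type_order``.
    """

    type_order: np.ndarray
    aggregated: np.ndarray
    mean_weight: float
    thresholded: np.ndarray
    attenuated: np.ndarray
    max_path_len: int
    k_min_clusters: int


def build_communication_graph(cluster_matrices: dict, type_order,
                              k_min: int | None = None) -> CommunicationGraph:
    """Aggregate, threshold and attenuate in one step."""
    aggregated, k_used = aggregate_pair_weights(cluster_matrices, type_order, k_min=k_min)
    thresholded, mean_weight = threshold_by_mean(aggregated)
    attenuated = attenuate_paths(thresholded, mean_weight)
    return CommunicationGraph(
        type_order=np.asarray(list(type_order), dtype=object),
        aggregated=aggregated,
        mean_weight=mean_weight,
        thresholded=thresholded,
        attenuated=attenuated,
        max_path_len=len(list(type_order)) - 1,
        k_min_clusters=k_used,
    )


def _edges(matrix: np.ndarray, names) -> list:
    return [
        (names[i], names[j], float(matrix[i, j]))
        for i, j in np.argwhere(np.asarray(matrix) != 0)
    ]


def _write_dot(matrix: np.ndarray, names, path: Path) -> None:
    lines = ["digraph communication {"]
    for name in names:
        lines.append(f'  "{name}";')
    for s, t, w in _edges(matrix, names):
        lines.append(f'  "{s}" -> "{t}" [weight={FLOAT_FMT % w}, label="{FLOAT_FMT % w}"];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def export_graph(graph: CommunicationGraph, out_dir: str | Path) -> dict:
    """Write matrices (TSV) and thresholded/attenuated graphs (CSV/GraphML/DOT)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = list(graph.type_order)
    written = {}
    for key in ("aggregated", "thresholded", "attenuated"):
        p = out_dir / f"{key}_matrix.tsv"
        write_matrix_tsv(getattr(graph, key), names, names, p)
        written[f"{key}_matrix"] = p
    for key in ("thresholded", "attenuated"):
        matrix = getattr(graph, key)
        edges = _edges(matrix, names)
        p_csv = out_dir / f"{key}_edges.csv"
        write_edge_list_csv(edges, p_csv)
        written[f"{key}_edges"] = p_csv
        g = nx.DiGraph()
        g.add_nodes_from(names)
        for s, t, w in edges:
            g.add_edge(s, t, weight=w)
        p_gml = out_dir / f"{key}.graphml"
        nx.write_graphml(g, p_gml)
        written[f"{key}_graphml"] = p_gml
        p_dot = out_dir / f"{key}.dot"
        _write_dot(matrix, names, p_dot)
        written[f"{key}_dot"] = p_dot
    return written
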