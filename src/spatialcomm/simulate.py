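"""Synthetic spatial transcriptomics with planted neighbor-type effects.

Cells of each type are laid out in contiguous spatial stripes (or Poisson
scatter with region labels), so neighbor-type scores differ strongly
across types. A chosen fraction of genes is "responsive": its expression
is a linear function of the z-scored neighbor-type score of one sender
type (planted coefficient +/- effect_size) plus Gaussian noise; the rest
is pure noise. Expression is shifted per gene to be nonnegative, which
leaves all downstream z-scoring untouched. The neighbor scores are
computed with the package's own scorer so the generative model matches
the inference model by construction; tests keep an independent
brute-force scorer to break that circularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import SpatialExpressionDataset, write_mtx, write_table_tsv
from .neighbors import (
    min_pairwise_distance,
    pairwise_distances,
    raw_neighbor_scores,
    zscore_columns,
)


@dataclass
class SimulationSpec:
    """Parameters of the generative model.

    ``beta`` may be supplied explicitly as an (n_types, n_genes) matrix;
    otherwise it is drawn from the seed: ``round(frac_responsive *
    n_genes)`` genes each get one sender type and sign +/- effect_size.
    """

    n_cells: int = 600
    n_genes: int = 200
    n_types: int = 3
    layout: str = "blocks"
    effect_size: float = 2.0
    noise_sd: float = 0.5
    frac_responsive: float = 0.2
    seed: int = 0
    transform: str = "shift"
    beta: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not 0 <= self.frac_responsive <= 1:
            raise ValidationError("frac_responsive must lie in [0, 1]")
        if self.n_types < 2:
            raise ValidationError("need at least 2 cell types")
        if self.layout not in ("blocks", "poisson"):
            raise ValidationError(f"unknown layout {self.layout!r}")
        if self.beta is not None:
            b = np.asarray(self.beta, dtype=float)
            if b.shape != (self.n_types, self.n_genes):
                raise ValidationError(
                    f"beta must be {(self.n_types, self.n_genes)}, got {b.shape}"
                )
            self.beta = b


def true_coefficients(spec: SimulationSpec):
    """The planted (n_types, n_genes) coefficient matrix and responsive mask."""
    if spec.beta is not None:
        beta = spec.beta.copy()
    else:
        rng = np.random.default_rng([int(spec.seed), 1])
        beta = np.zeros((spec.n_types, spec.n_genes))
        n_resp = int(round(spec.frac_responsive * spec.n_genes))
        genes = np.sort(rng.choice(spec.n_genes, size=n_resp, replace=False))
        senders = rng.integers(0, spec.n_types, size=n_resp)
        signs = rng.choice([-1.0, 1.0], size=n_resp)
        beta[senders, genes] = signs * spec.effect_size
    mask = np.any(beta != 0, axis=0)
    return beta, mask


def _place_cells(spec: SimulationSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    # Types occupy contiguous unit patches tiled over a near-square 2-D grid,
    # so each neighbor type lies in its own spatial direction and the
    # within-type score columns stay well conditioned (a single-axis stripe
    # arrangement makes them collinear).
    a = spec.n_types
    ncol = int(np.ceil(np.sqrt(a)))
    sizes = [len(chunk) for chunk in np.array_split(np.arange(spec.n_cells), a)]
    if spec.layout == "blocks":
        xs, labels = [], []
        for t, size in enumerate(sizes):
            gx, gy = t % ncol, t // ncol
            xs.append(np.column_stack([
                rng.uniform(gx, gx + 0.95, size=size),
                rng.uniform(gy, gy + 0.95, size=size),
            ]))
            labels.extend([f"type_{t}"] * size)
        coords = np.vstack(xs)
    else:  # poisson scatter over the same grid, labels by region
        nrow = int(np.ceil(a / ncol))
        coords = np.column_stack([
            rng.uniform(0.0, ncol, size=spec.n_cells),
            rng.uniform(0.0, nrow, size=spec.n_cells),
        ])
        region = (np.minimum(coords[:, 0].astype(int), ncol - 1)
                  + ncol * np.minimum(coords[:, 1].astype(int), nrow - 1))
        labels = [f"type_{min(int(r), a - 1)}" for r in region]
    return coords, np.asarray(labels, dtype=object)


def simulate_dataset(spec: SimulationSpec):
    """Generate a dataset and its ground truth.

    Returns
    -------
    dataset : SpatialExpressionDataset
    truth : dict with keys ``beta`` (n_types x n_genes), ``mask``
        (responsive-gene boolean vector), ``scores`` (the z-scored
        neighbor-score matrix the expression was generated from) and
        ``type_order``.
    """
    rng = np.random.default_rng(int(spec.seed))
    coords, labels = _place_cells(spec, rng)
    order = [f"type_{t}" for t in range(spec.n_types)]
    d = pairwise_distances(coords)
    dist0 = min_pairwise_distance(d)
    f = zscore_columns(raw_neighbor_scores(labels, np.asarray(order, dtype=object), d, dist0))

    beta, mask = true_coefficients(spec)
    raw = f @ beta + spec.noise_sd * rng.standard_normal((spec.n_cells, spec.n_genes))
    if spec.transform == "shift":
        expr = raw - raw.min(axis=0, keepdims=True)
    elif spec.transform == "exp":
        expr = np.exp(raw)
    else:
        raise ValidationError(f"unknown transform {spec.transform!r}")

    dataset = SpatialExpressionDataset(
        expression=expr,
        coordinates=coords,
        labels=labels,
        cell_ids=np.asarray([f"cell_{i:05d}" for i in range(spec.n_cells)], dtype=object),
        gene_ids=np.asarray([f"gene_{i:04d}" for i in range(spec.n_genes)], dtype=object),
    )
    truth = {"beta": beta, "mask": mask, "scores": f, "type_order": np.asarray(order, dtype=object)}
    return dataset, truth


def write_simulation(dataset: SpatialExpressionDataset, truth: dict, out_dir) -> None:
    """Write MTX triplet, coordinates/labels TSVs and the ground-truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mtx(dataset.expression, dataset.gene_ids, dataset.cell_ids, out_dir)
    write_table_tsv(
        pd.DataFrame({
            "cell_id": dataset.cell_ids,
            "x": dataset.coordinates[:, 0],
            "y": dataset.coordinates[:, 1],
        }),
        out_dir / "coordinates.tsv",
    )
    write_table_tsv(
        pd.DataFrame({"cell_id": dataset.cell_ids, "cell_type": dataset.labels}),
        out_dir / "labels.tsv",
    )
    beta = truth["beta"]
    rows = []
    for g, gene in enumerate(dataset.gene_ids):
        for t, sender in enumerate(truth["type_order"]):
            if beta[t, g] != 0:
                rows.append({"gene": gene, "sender_type": sender, "beta": beta[t, g]})
    write_table_tsv(
        pd.DataFrame(rows, columns=["gene", "sender_type", "beta"]),
        out_dir / "ground_truth.tsv",
    )
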