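"""Per-cell-type highly variable gene (HVG) selection and preprocessing.

HVGs are ranked by their variance-stabilized standardized variance: a
local (lowess) regression of log10(variance) on log10(mean) across genes
predicts each gene's expected standard deviation; expression is
standardized by that prediction, clipped at sqrt(n_cells), and genes are
ranked by the variance of the clipped standardized values. Selection runs
within each cell type, producing type-specific HVG sets whose pairwise
overlap is summarized by :func:`hvg_overlap_ratio`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import ValidationError
from .io import SpatialExpressionDataset
from .neighbors import zscore_columns

logger = logging.getLogger(__name__)


@dataclass
class CellTypeSlice:
    """One cell type's z-scored HVG expression block.

    Attributes
    ----------
    cell_type : str
    expression : (Z_a, H_a) ndarray
        z-scored (sample sd) expression of the retained HVGs.
    hvg_ids : ndarray of str
    cell_index : ndarray of int
        Row positions of this type's cells in the parent dataset.
    """

    cell_type: str
    expression: np.ndarray
    hvg_ids: np.ndarray
    cell_index: np.ndarray


def select_hvgs_vst(
    expression: np.ndarray,
    gene_ids,
    n_top: int = 2000,
    loess_span: float = 0.3,
) -> np.ndarray:
    """Rank genes by standardized variance and return the top ``n_top`` ids.

    Parameters
    ----------
    expression : (n_cells, n_genes) ndarray
        Expression of one cell type's cells; genes with zero total
        expression should have been excluded beforehand.
    gene_ids : sequence of str
    n_top : int
        Number of genes to keep (all genes, with a warning, if fewer exist).
    loess_span : float
        Fraction of genes used by the local mean-variance regression.
    """
    if n_top <= 0:
        raise ValidationError("n_top must be positive")
    x = np.asarray(expression, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_cells, n_genes = x.shape
    if n_cells < 10:
        raise ValidationError(f"need at least 10 cells, got {n_cells}")
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    varying = (var > 0) & (mean > 0)
    if varying.sum() < 3:
        raise ValidationError("fewer than 3 varying genes")
    if n_top > n_genes:
        logger.warning("n_top=%d exceeds gene count %d; returning all", n_top, n_genes)

    log_mean = np.log10(mean[varying])
    log_var = np.log10(var[varying])
    # lowess prediction of log-variance at each gene's log-mean
    fitted = lowess(
        log_var, log_mean, frac=loess_span, return_sorted=False, xvals=log_mean
    )
    expected_sd = np.sqrt(10.0 ** fitted)

    std_var = np.zeros(n_genes)
    clip = np.sqrt(n_cells)
    xv = x[:, varying]
    z = (xv - mean[varying]) / expected_sd
    z = np.minimum(z, clip)
    std_var[varying] = z.var(axis=0, ddof=1)

    order = np.argsort(-std_var, kind="stable")
    k = min(n_top, n_genes)
    return gene_ids[order[:k]]


def split_by_cell_type(
    dataset: SpatialExpressionDataset,
    n_top: int = 2000,
    loess_span: float = 0.3,
    min_cells: int = 10,
) -> list[CellTypeSlice]:
    """Build a z-scored HVG expression slice for each cell type.

    For each type: subset its cells, drop genes with zero expression
    across all of them, rank the rest with :func:`select_hvgs_vst`, and
    z-score each retained column (sample sd) within the type. Types with
    fewer than ``min_cells`` cells are skipped with a warning.
    """
    slices: list[CellTypeSlice] = []
    for cell_type in dataset.cell_types:
        idx = np.flatnonzero(dataset.labels == cell_type)
        if len(idx) < min_cells:
            logger.warning(
                "cell type %r has %d cells (< %d); skipped", cell_type, len(idx), min_cells
            )
            continue
        sub = dataset.expression[idx]
        nonzero = sub.sum(axis=0) > 0
        sub = sub[:, nonzero]
        genes = dataset.gene_ids[nonzero]
        hvgs = select_hvgs_vst(sub, genes, n_top=n_top, loess_span=loess_span)
        pos = {g: i for i, g in enumerate(genes)}
        cols = np.asarray([pos[g] for g in hvgs], dtype=int)
        expr = zscore_columns(sub[:, cols])
        slices.append(
            CellTypeSlice(
                cell_type=str(cell_type),
                expression=expr,
                hvg_ids=np.asarray(hvgs, dtype=object),
                cell_index=idx,
            )
        )
    if not slices:
        raise ValidationError("every cell type is below the minimum cell count")
    return slices


def hvg_overlap_ratio(hvg_sets, mode: str = "ordered_fraction") -> float:
    """Mean pairwise overlap between per-type HVG sets.

    ``ordered_fraction`` (default): mean over ordered pairs (i, j), i != j,
    of ``|H_i & H_j| / |H_i|``. ``min_fraction``: denominator is the
    smaller set size (then symmetric, averaged over unordered pairs).
    """
    sets = [set(s) for s in hvg_sets]
    if len(sets) < 2:
        raise ValidationError("need at least 2 HVG sets")
    if any(len(s) == 0 for s in sets):
        raise ValidationError("empty HVG set")
    vals = []
    for i, hi in enumerate(sets):
        for j, hj in enumerate(sets):
            if i == j:
                continue
            inter = len(hi & hj)
            denom = len(hi) if mode == "ordered_fraction" else min(len(hi), len(hj))
            vals.append(inter / denom)
    return float(np.mean(vals))
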