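"""Two-stage FDR filtering of the PLS coefficients.

Stage 1 tests, for every component c, the Pearson correlation of each
predictor column f_b with the x-score t_c and of each response column u_h
with the y-score l_c, converts correlations to two-sided t-test p-values
(df = n - 2), and Benjamini-Hochberg-adjusts them within the
{predictor x component} and {gene x component} families separately. The
per-component coefficient w_{b,h,c} is kept only if both adjusted values
fall below delta (default 0.05), otherwise zeroed.

Stage 2 sums the surviving tensor over components and, for each pair
(b, h) with a nonzero sum, tests the direct correlation between f_b and
u_h, BH-adjusting over all tested pairs; pairs with adjusted value >=
delta are zeroed. Filtering never alters the value of a retained
coefficient. Degenerate (zero-variance) correlations are treated as
non-significant (r = 0, p = 1).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError


def pearson_r(x, y) -> float:
    """Pearson correlation; 0.0 when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r needs two equal-length vectors")
    if len(x) < 3:
        raise ValidationError("need n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    den = np.sqrt((dx @ dx) * (dy @ dy))
    if den == 0:
        return 0.0
    return float(np.clip((dx @ dy) / den, -1.0, 1.0))


def corr_t_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of r under the t-test with n - 2 df."""
    if n < 3:
        raise ValidationError("need n >= 3")
    r = float(r)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def _corr_pvalues(columns: np.ndarray, score: np.ndarray) -> np.ndarray:
    n = len(score)
    return np.array(
        [corr_t_pvalue(pearson_r(columns[:, j], score), n) for j in range(columns.shape[1])]
    )


def filter_stage1(fit, f, u, delta: float = 0.05):
    """Mask the per-component tensor by the two score-correlation tests.

    Returns ``(stage1_tensor, q_predictor, q_gene)`` with q-value arrays of
    shape (A, C) and (H, C).
    """
    if not 0 < delta <= 1:
        raise ValidationError("delta must lie in (0, 1]")
    f = np.asarray(f, dtype=float)
    u = np.asarray(u, dtype=float)
    tensor = fit.coef_tensor_
    a, h, c = tensor.shape
    p_pred = np.empty((a, c))
    p_gene = np.empty((h, c))
    for comp in range(c):
        p_pred[:, comp] = _corr_pvalues(f, fit.x_scores_[:, comp])
        p_gene[:, comp] = _corr_pvalues(u, fit.y_scores_[:, comp])
    q_pred = bh_adjust(p_pred)
    q_gene = bh_adjust(p_gene)
    keep = (q_pred[:, None, :] < delta) & (q_gene[None, :, :] < delta)
    return np.where(keep, tensor, 0.0), q_pred, q_gene


def filter_stage2(stage1_tensor, f, u, delta: float = 0.05):
    """Mask summed coefficients by the direct predictor-gene correlation test.

    Returns ``(coefficients, q_pair)``; ``q_pair`` is (A, H) with NaN for
    untested (already-zero) pairs.
    """
    if not 0 < delta <= 1:
        raise ValidationError("delta must lie in (0, 1]")
    f = np.asarray(f, dtype=float)
    u = np.asarray(u, dtype=float)
    n = f.shape[0]
    w1 = np.asarray(stage1_tensor).sum(axis=2)
    a, h = w1.shape
    q_pair = np.full((a, h), np.nan)
    tested = np.argwhere(w1 != 0)
    if len(tested) == 0:
        return np.zeros_like(w1), q_pair
    pvals = np.array(
        [corr_t_pvalue(pearson_r(f[:, b], u[:, g]), n) for b, g in tested]
    )
    qvals = bh_adjust(pvals)
    coef = np.zeros_like(w1)
    for (b, g), q in zip(tested, qvals):
        q_pair[b, g] = q
        if q < delta:
            coef[b, g] = w1[b, g]
    return coef, q_pair


class CoefficientFilter(BaseEstimator):
    """Two-stage FDR filter over a fitted :class:`~spatialcomm.pls.PLS2Regression`.

    Parameters
    ----------
    delta : float
        FDR threshold applied in both stages (default 0.05).

    Attributes
    ----------
    stage1_tensor_ : (A, H, C) ndarray
        Per-component coefficients surviving stage 1 (others zeroed).
    coef_ : (A, H) ndarray
        Final filtered coefficients w''_{b,h}.
    q_predictor_ : (A, C); q_gene_ : (H, C); q_pair_ : (A, H)
        BH-adjusted values of the three test families.
    """

    def __init__(self, delta: float = 0.05):
        self.delta = delta

    def fit(self, pls_fit, F, U):
        tensor, q_pred, q_gene = filter_stage1(pls_fit, F, U, delta=self.delta)
        coef, q_pair = filter_stage2(tensor, F, U, delta=self.delta)
        self.stage1_tensor_ = tensor
        self.coef_ = coef
        self.q_predictor_ = q_pred
        self.q_gene_ = q_gene
        self.q_pair_ = q_pair
        return self
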