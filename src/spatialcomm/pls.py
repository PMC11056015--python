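"""Multi-response partial least squares (PLS2) regression.

Within each cell type the z-scored HVG expression block U (cells x genes)
is regressed on the z-scored neighbor-type score block F (cells x types):

    U = F W + G

W is estimated by NIPALS PLS2: components are extracted iteratively as
x-weights/scores/loadings and y-loadings/scores with deflation, and the
coefficient matrix decomposes per component,

    W = sum_c r_c q_c^T,   r_c = column c of W_x (P^T W_x)^{-1},

so each entry w_{b,h} is the sum over components of w_{b,h,c}. The number
of components is chosen by seeded k-fold cross-validation on the
out-of-fold root-mean-squared prediction error (ties broken toward the
smallest count). With as many components as the predictor rank, the PLS
solution coincides with ordinary least squares.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


def _validate_block(m, name):
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValidationError(f"{name} must be 2-D")
    if not np.all(np.isfinite(m)):
        raise ValidationError(f"{name} contains non-finite values")
    return m


def _nipals_pls2(xc: np.ndarray, yc: np.ndarray, n_components: int,
                 max_iter: int = 500, tol: float = 1e-12):
    """NIPALS PLS2 on centered blocks; returns weights/scores/loadings."""
    n, a = xc.shape
    h = yc.shape[1]
    e, f = xc.copy(), yc.copy()
    w_x = np.zeros((a, n_components))
    t_sc = np.zeros((n, n_components))
    u_sc = np.zeros((n, n_components))
    p_ld = np.zeros((a, n_components))
    q_ld = np.zeros((h, n_components))
    actual = 0
    for c in range(n_components):
        # start from the response column with the largest remaining variance
        u = f[:, int(np.argmax(f.var(axis=0)))].copy()
        if np.linalg.norm(f) < 1e-12 or np.linalg.norm(u) < 1e-12:
            # response block exhausted; fall back to dominant x direction
            u = e[:, int(np.argmax(e.var(axis=0)))].copy()
            if np.linalg.norm(u) < 1e-12:
                break
        t = np.zeros(n)
        for _ in range(max_iter):
            w = e.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-14:
                break
            w /= nw
            t_new = e @ w
            tt = t_new @ t_new
            if tt < 1e-14:
                break
            q = f.T @ t_new / tt
            nq = q @ q
            u_new = f @ q / nq if nq > 1e-14 else t_new.copy()
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t, u = t_new, u_new
                break
            t, u = t_new, u_new
        tt = t @ t
        if tt < 1e-14:
            break
        p = e.T @ t / tt
        q = f.T @ t / tt
        e = e - np.outer(t, p)
        f = f - np.outer(t, q)
        w_x[:, c], t_sc[:, c], u_sc[:, c], p_ld[:, c], q_ld[:, c] = w, t, u, p, q
        actual += 1
    if actual < n_components:
        logger.warning("predictor block exhausted after %d components (%d requested)",
                       actual, n_components)
        w_x, t_sc, u_sc = w_x[:, :actual], t_sc[:, :actual], u_sc[:, :actual]
        p_ld, q_ld = p_ld[:, :actual], q_ld[:, :actual]
    return w_x, t_sc, u_sc, p_ld, q_ld


class PLS2Regression(RegressorMixin, BaseEstimator):
    """NIPALS PLS2 with per-component coefficient decomposition.

    Parameters
    ----------
    n_components : int or "cv"
        Number of latent components; ``"cv"`` selects it by k-fold
        cross-validated RMSEP up to ``max_components``.
    max_components : int, optional
        Cap for CV search; defaults to ``min(n_predictors, n_cells - 1, 10)``.
    cv_folds : int
        Folds for component selection (reduced, with a warning, if the
        sample is smaller).
    random_state : int
        Seed for the CV shuffle.

    Attributes
    ----------
    coef_ : (A, H) ndarray
        Summed regression coefficients w_{b,h}.
    coef_tensor_ : (A, H, C) ndarray
        Per-component coefficients w_{b,h,c}; slices sum to ``coef_``.
    x_scores_, y_scores_ : (n, C) ndarray
        Component scores t_c and l_c.
    x_weights_, x_loadings_ : (A, C); y_loadings_ : (H, C)
    fitted_, residuals_ : (n, H) ndarray
    n_components_ : int
    """

    def __init__(self, n_components="cv", max_components=None, cv_folds: int = 10,
                 random_state: int = 0):
        self.n_components = n_components
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, Y):
        f = _validate_block(X, "predictor block")
        u = _validate_block(Y, "response block")
        if f.shape[0] != u.shape[0]:
            raise ValidationError("predictor and response row counts differ")
        n, a = f.shape
        if np.allclose(f.std(axis=0), 0):
            raise ValidationError("zero-variance predictor block")
        cap = min(a, n - 1)
        if self.n_components == "cv":
            c_max = self.max_components if self.max_components is not None else min(cap, 10)
            c_max = min(c_max, cap)
            c = select_components_cv(f, u, c_max=c_max, folds=self.cv_folds,
                                     seed=self.random_state)
        else:
            c = int(self.n_components)
            if c < 1 or c > cap:
                raise ValidationError(
                    f"n_components={c} outside [1, min(A, n-1)] = [1, {cap}]"
                )
        self.x_mean_ = f.mean(axis=0)
        self.y_mean_ = u.mean(axis=0)
        xc, yc = f - self.x_mean_, u - self.y_mean_
        w_x, t_sc, u_sc, p_ld, q_ld = _nipals_pls2(xc, yc, c)
        self.n_components_ = w_x.shape[1]
        # rotations r_c mapping centered X to scores: T = Xc R
        r = w_x @ np.linalg.pinv(p_ld.T @ w_x)
        self.x_weights_ = w_x
        self.x_scores_ = t_sc
        self.y_scores_ = u_sc
        self.x_loadings_ = p_ld
        self.y_loadings_ = q_ld
        self.x_rotations_ = r
        self.coef_tensor_ = np.einsum("ac,hc->ahc", r, q_ld)
        self.coef_ = self.coef_tensor_.sum(axis=2)
        self.fitted_ = xc @ self.coef_ + self.y_mean_
        self.residuals_ = u - self.fitted_
        return self

    def predict(self, X):
        f = _validate_block(X, "predictor block")
        if f.shape[1] != self.coef_.shape[0]:
            raise ValidationError(
                f"expected {self.coef_.shape[0]} predictor columns, got {f.shape[1]}"
            )
        return (f - self.x_mean_) @ self.coef_ + self.y_mean_


def fit_pls2(f, u, n_components) -> PLS2Regression:
    """Fit a :class:`PLS2Regression` with a fixed component count."""
    return PLS2Regression(n_components=n_components).fit(f, u)


def component_coefficients(fit: PLS2Regression) -> np.ndarray:
    """The A x H x C per-component coefficient tensor (slices sum to coef_)."""
    return fit.coef_tensor_


def select_components_cv(f, u, c_max: int, folds: int = 10, seed: int = 0) -> int:
    """Choose the component count minimizing mean out-of-fold RMSEP.

    Cells are shuffled with ``seed`` and split into ``folds`` contiguous
    near-equal blocks; ties prefer the smallest count.
    """
    f = _validate_block(f, "predictor block")
    u = _validate_block(u, "response block")
    if c_max < 1:
        raise ValidationError("c_max must be >= 1")
    if c_max == 1:
        return 1
    n = f.shape[0]
    if n < folds:
        logger.warning("only %d cells for %d folds; reducing folds", n, folds)
        folds = n
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_idx = np.array_split(perm, folds)
    rmsep = np.zeros(c_max)
    for test in fold_idx:
        train = np.setdiff1d(perm, test, assume_unique=True)
        c_cap = min(c_max, f.shape[1], len(train) - 1)
        model = PLS2Regression(n_components=c_cap).fit(f[train], u[train])
        xc = f[test] - model.x_mean_
        # cumulative predictions: adding components one at a time
        for c in range(c_max):
            cc = min(c, model.n_components_ - 1)
            coef_c = model.coef_tensor_[:, :, : cc + 1].sum(axis=2)
            pred = xc @ coef_c + model.y_mean_
            rmsep[c] += np.sqrt(np.mean((u[test] - pred) ** 2))
    rmsep /= folds
    return int(np.argmin(rmsep)) + 1
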