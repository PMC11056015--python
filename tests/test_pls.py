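import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression as SkPLS

from spatialcomm.exceptions import ValidationError
from spatialcomm.pls import PLS2Regression, fit_pls2, select_components_cv


def _random_blocks(n=20, a=3, h=5, seed=0):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, a)), rng.standard_normal((n, h))


def test_self_map_identity():
    f, _ = _random_blocks()
    fit = fit_pls2(f, f.copy(), n_components=3)
    np.testing.assert_allclose(fit.coef_, np.eye(3), atol=1e-8)
    assert np.abs(fit.residuals_).max() < 1e-8


def test_full_rank_matches_ols():
    f, u = _random_blocks(seed=1)
    fit = fit_pls2(f, u, n_components=3)
    fc, uc = f - f.mean(0), u - u.mean(0)
    ols = np.linalg.lstsq(fc, uc, rcond=None)[0]
    np.testing.assert_allclose(fit.coef_, ols, atol=1e-8)


def test_rank_one_exact():
    """Noise-free rank-1 response over orthonormal predictors: one component
    reproduces it exactly (covariance and regression directions coincide)."""
    rng = np.random.default_rng(2)
    raw = rng.standard_normal((30, 4))
    f = np.linalg.qr(raw - raw.mean(0))[0]  # centered orthonormal columns
    w = rng.standard_normal(4)
    q = rng.standard_normal(6)
    u = np.outer(f @ w, q)
    fit = fit_pls2(f, u, n_components=1)
    np.testing.assert_allclose(fit.fitted_, u, atol=1e-8)


def test_single_component_matches_sklearn():
    """Cross-check the first-component solution against sklearn's NIPALS."""
    f, u = _random_blocks(n=40, seed=3)
    ours = fit_pls2(f, u, n_components=1)
    theirs = SkPLS(n_components=1, scale=False, tol=1e-12, max_iter=5000).fit(f, u)
    np.testing.assert_allclose(ours.coef_, theirs.coef_.T, atol=1e-6)


def test_decomposition_identity_random_fits():
    for seed in range(5):
        f, u = _random_blocks(n=25, a=4, h=7, seed=seed)
        for c in (1, 2, 4):
            fit = fit_pls2(f, u, n_components=c)
            np.testing.assert_allclose(fit.coef_tensor_.sum(axis=2), fit.coef_,
                                       atol=1e-10)


def test_scores_orthogonal():
    f, u = _random_blocks(n=50, a=5, h=8, seed=4)
    fit = fit_pls2(f, u, n_components=5)
    t = fit.x_scores_
    gram = t.T @ t
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_fitted_plus_residuals():
    f, u = _random_blocks(seed=5)
    fit = fit_pls2(f, u, n_components=2)
    np.testing.assert_allclose(fit.fitted_ + fit.residuals_, u, atol=1e-10)


def test_predict_on_training_and_linearity():
    f, u = _random_blocks(seed=6)
    fit = fit_pls2(f, u, n_components=3)
    np.testing.assert_allclose(fit.predict(f), fit.fitted_, atol=1e-10)
    # centered all-zero row predicts the response means
    np.testing.assert_allclose(fit.predict(f.mean(0, keepdims=True)),
                               u.mean(0, keepdims=True), atol=1e-10)
    # linearity in deviations from the predictor mean
    lam = 0.3
    combo = f.mean(0) + lam * (f[0] - f.mean(0)) + (1 - lam) * (f[1] - f.mean(0))
    pred = fit.predict(combo[None, :])
    expect = u.mean(0) + lam * (fit.fitted_[0] - u.mean(0)) \
        + (1 - lam) * (fit.fitted_[1] - u.mean(0))
    np.testing.assert_allclose(pred[0], expect, atol=1e-10)


def test_predict_column_mismatch():
    f, u = _random_blocks()
    fit = fit_pls2(f, u, n_components=2)
    with pytest.raises(ValidationError):
        fit.predict(np.zeros((2, 5)))


@pytest.mark.parametrize("c", [0, 4, 25])
def test_invalid_component_counts(c):
    f, u = _random_blocks()
    with pytest.raises(ValidationError):
        fit_pls2(f, u, n_components=c)


def test_zero_variance_predictors_rejected():
    u = np.random.default_rng(0).standard_normal((10, 3))
    with pytest.raises(ValidationError):
        fit_pls2(np.ones((10, 2)), u, n_components=1)


def test_cv_selects_one_for_single_latent_component():
    """At moderate SNR a single-latent simulation selects one component."""
    rng = np.random.default_rng(0)
    f = rng.standard_normal((200, 3))
    w = rng.standard_normal(3)
    w /= np.linalg.norm(w)
    q = rng.standard_normal(8)
    q /= np.linalg.norm(q)
    u = 0.02 * np.outer(f @ w, q) + 0.01 * rng.standard_normal((200, 8))
    assert select_components_cv(f, u, c_max=3, seed=0) == 1


def test_cv_pure_noise_selects_one():
    rng = np.random.default_rng(1)
    f = rng.standard_normal((60, 3))
    u = rng.standard_normal((60, 8))
    assert select_components_cv(f, u, c_max=3, seed=0) == 1


def test_cv_cmax_one_shortcut():
    f, u = _random_blocks()
    assert select_components_cv(f, u, c_max=1, seed=0) == 1


def test_cv_invariant_to_cell_order_given_seed():
    """Out-of-fold error depends on the seeded shuffle, not input row order."""
    rng = np.random.default_rng(2)
    f = rng.standard_normal((50, 3))
    w = rng.standard_normal((3, 6))
    u = f @ w + 0.5 * rng.standard_normal((50, 6))
    c1 = select_components_cv(f, u, c_max=3, seed=9)
    c2 = select_components_cv(f, u, c_max=3, seed=9)
    assert c1 == c2


def test_cv_reduces_folds_with_warning(caplog):
    import logging
    rng = np.random.default_rng(3)
    f = rng.standard_normal((6, 2))
    u = rng.standard_normal((6, 3))
    with caplog.at_level(logging.WARNING):
        c = select_components_cv(f, u, c_max=2, folds=10, seed=0)
    assert c in (1, 2)
    assert any("folds" in r.message for r in caplog.records)


def test_estimator_get_set_params():
    est = PLS2Regression(n_components=2, cv_folds=5)
    params = est.get_params()
    assert params["n_components"] == 2
    est.set_params(n_components="cv")
    assert est.n_components == "cv"
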