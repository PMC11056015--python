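import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spatialcomm.exceptions import ValidationError
from spatialcomm.filtering import (
    CoefficientFilter,
    bh_adjust,
    corr_t_pvalue,
    filter_stage1,
    filter_stage2,
    pearson_r,
)
from spatialcomm.pls import fit_pls2


def test_pearson_hand_values():
    assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)


def test_pearson_degenerate_is_zero():
    assert pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 0.0


def test_corr_t_pvalue_against_scipy():
    rng = np.random.default_rng(0)
    for n in (5, 20, 100):
        x, y = rng.standard_normal((2, n))
        r = pearson_r(x, y)
        assert corr_t_pvalue(r, n) == pytest.approx(stats.pearsonr(x, y).pvalue,
                                                    rel=1e-9)


def test_corr_t_pvalue_edges():
    assert corr_t_pvalue(0.0, 10) == pytest.approx(1.0)
    assert corr_t_pvalue(1.0, 5) == 0.0
    # r=0.8, n=4: t = 1.8856, df = 2
    assert corr_t_pvalue(0.8, 4) == pytest.approx(
        2 * stats.t.sf(0.8 * np.sqrt(2 / (1 - 0.64)), df=2))
    with pytest.raises(ValidationError):
        corr_t_pvalue(0.5, 2)


def test_bh_hand_oracle():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(bh_adjust([0.05]), [0.05])
    np.testing.assert_allclose(bh_adjust([0.02, 0.04]), [0.04, 0.04])


def test_bh_rejects_invalid():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_stepup_properties(pvals):
    p = np.asarray(pvals)
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-12)
    assert np.all(q <= 1.0 + 1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in sorted-p order


def _planted_fit(n=100, a=3, h=10, seed=0, noise=0.1):
    """u depends strongly on f column 0 for the first half of genes."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, a))
    u = noise * rng.standard_normal((n, h))
    u[:, : h // 2] += np.outer(f[:, 0], np.ones(h // 2)) * 2.0
    fit = fit_pls2(f, u, n_components=a)
    return fit, f, u


def test_stage1_vacuous_delta_keeps_everything():
    fit, f, u = _planted_fit()
    tensor, _, _ = filter_stage1(fit, f, u, delta=1.0)
    np.testing.assert_array_equal(tensor, fit.coef_tensor_)


def test_stage1_invalid_delta():
    fit, f, u = _planted_fit()
    with pytest.raises(ValidationError):
        filter_stage1(fit, f, u, delta=0.0)


def test_filter_preserves_retained_values():
    """Filtering only zeroes entries; survivors keep their exact value."""
    fit, f, u = _planted_fit(seed=1)
    filt = CoefficientFilter(delta=0.05).fit(fit, f, u)
    # surviving tensor entries are the original values, untouched
    kept_slices = filt.stage1_tensor_ != 0
    np.testing.assert_array_equal(filt.stage1_tensor_[kept_slices],
                                  fit.coef_tensor_[kept_slices])
    # stage-2 survivors keep the stage-1 sum exactly
    kept = filt.coef_ != 0
    w1 = filt.stage1_tensor_.sum(axis=2)
    np.testing.assert_array_equal(filt.coef_[kept], w1[kept])
    # stage-1 zeros stay zero after stage 2
    assert np.all(filt.coef_[w1 == 0] == 0)


def test_planted_signal_retained():
    fit, f, u = _planted_fit(seed=2)
    filt = CoefficientFilter(delta=0.05).fit(fit, f, u)
    # predictor 0 drives the first half of genes: those pairs survive
    assert np.all(filt.coef_[0, : u.shape[1] // 2] != 0)


def test_noiseless_linear_gene_retained():
    rng = np.random.default_rng(3)
    f = rng.standard_normal((50, 3))
    u = rng.standard_normal((50, 4)) * 0.05
    u[:, 2] = 1.5 * f[:, 1]  # noiseless linear function of f_b
    fit = fit_pls2(f, u, n_components=3)
    filt = CoefficientFilter().fit(fit, f, u)
    assert filt.coef_[1, 2] != 0


def test_stage2_all_zero_input():
    fit, f, u = _planted_fit()
    coef, q = filter_stage2(np.zeros_like(fit.coef_tensor_), f, u)
    assert np.all(coef == 0)
    assert np.all(np.isnan(q))


def test_null_retention_small():
    """Independent f and u: almost nothing survives the two-stage filter."""
    retained = total = 0
    for seed in range(20):
        rng = np.random.default_rng([1, seed])
        f = rng.standard_normal((100, 3))
        u = rng.standard_normal((100, 20))
        fit = fit_pls2(f, u, n_components=3)
        filt = CoefficientFilter().fit(fit, f, u)
        retained += np.count_nonzero(filt.coef_)
        total += filt.coef_.size
    frac = retained / total
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)


def test_qvalues_within_unit_interval():
    fit, f, u = _planted_fit(seed=4)
    filt = CoefficientFilter().fit(fit, f, u)
    for q in (filt.q_predictor_, filt.q_gene_):
        assert np.all((q >= 0) & (q <= 1))
    tested = ~np.isnan(filt.q_pair_)
    assert np.all((filt.q_pair_[tested] >= 0) & (filt.q_pair_[tested] <= 1))
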