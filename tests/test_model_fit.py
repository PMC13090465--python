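import numpy as np
import pytest

from conftest import make_calibration
from scalenorm import irt, model_fit
from scalenorm.instruments import ResponseMatrix
from scalenorm.simulate import random_item_params, simulate_responses


def _matrix(values, ids=None):
    values = np.asarray(values)
    ids = ids or [str(j) for j in range(values.shape[1])]
    n = values.shape[0]
    return ResponseMatrix([f"p{i}" for i in range(n)], ids, values,
                          ["6-9"] * n, ["female"] * n)


# --------------------------------------------------------------------- loadings


def test_loading_conversion_closed_form():
    cal = make_calibration([irt.GRMItemParams("x", 1.702, (0.0,))])
    ls = model_fit.irt_to_loadings(cal)
    assert ls.loadings[0] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
    assert ls.uniquenesses[0] == pytest.approx(0.5, abs=1e-9)


def test_loading_limits_and_monotonicity():
    lams = []
    for a in (0.01, 0.5, 1.0, 3.0, 30.0):
        cal = make_calibration([irt.GRMItemParams("x", a, (0.0,))])
        lams.append(model_fit.irt_to_loadings(cal).loadings[0])
    assert lams[0] < 0.01
    assert all(np.diff(lams) > 0)
    assert lams[-1] > 0.99
    for lam in lams:
        assert 0 < lam < 1


def test_loading_identity():
    rng = np.random.default_rng(0)
    cal = make_calibration(random_item_params(rng, list("abcd"), 3))
    ls = model_fit.irt_to_loadings(cal)
    assert np.allclose(ls.loadings**2 + ls.uniquenesses, 1.0)


# --------------------------------------------------------------------------- M2


def test_m2_zero_when_margins_match():
    """Exact agreement of observed and implied margins gives M2 = 0."""
    e = np.zeros(10)
    pi = np.full(10, 0.1)
    Xi = np.eye(10) * 0.05
    Delta = np.random.default_rng(0).normal(size=(10, 3))
    m2, df, p = model_fit._m2_from_parts(pi, pi, Xi, Delta, 500, 3)
    assert m2 == pytest.approx(0.0, abs=1e-12)
    assert df == 7 and p == pytest.approx(1.0)


def test_m2_df_counts_margins_minus_parameters(null_calibration):
    m, cal = null_calibration
    fi = model_fit.m2_statistic(m, cal)
    # 5 items, K=3: 10 univariate + 40 bivariate margins, 15 free parameters
    assert fi.df == 35
    assert fi.p_value > 1e-4  # the generating model is not grossly rejected


def test_m2_rejects_two_factor_truth():
    """One-factor fit to two-factor data is rejected with high power."""
    rng = np.random.default_rng(21)
    block1 = random_item_params(rng, ["a1", "a2", "a3"], 3)
    block2 = random_item_params(rng, ["b1", "b2", "b3"], 3)
    t1 = np.random.default_rng(1).standard_normal(2000)
    t2 = np.random.default_rng(2).standard_normal(2000)   # independent factor
    m1 = simulate_responses(t1, block1, 31)
    m2_ = simulate_responses(t2, block2, 32)
    X = np.hstack([m1.responses, m2_.responses])
    m = _matrix(X, ids=m1.item_ids + m2_.item_ids)
    cal = irt.fit_grm(m, m.item_ids)
    fi = model_fit.m2_statistic(m, cal)
    assert fi.p_value < 0.01


def test_fit_indices_exact_fit_case():
    fi = model_fit.fit_indices_from_m2(35.0, 35, 1000, 900.0, 45)
    assert fi.RMSEA == 0.0
    assert fi.CFI == 1.0


def test_fit_indices_formula_arithmetic():
    fi = model_fit.fit_indices_from_m2(120.0, 100, 1001, 2100.0, 120)
    assert fi.RMSEA == pytest.approx(np.sqrt(20 / 100_000), abs=1e-6)
    ratio_b = 2100 / 120
    want_tli = (ratio_b - 1.2) / (ratio_b - 1)
    assert fi.TLI == pytest.approx(want_tli, abs=1e-9)
    assert fi.CFI == pytest.approx(1 - 20 / 1980, abs=1e-9)


def test_fit_indices_baseline_df_guard():
    with pytest.raises(ValueError):
        model_fit.fit_indices_from_m2(10.0, 5, 100, 20.0, 1)


def test_independence_baseline_much_larger_than_target(null_calibration):
    m, cal = null_calibration
    target = model_fit.m2_statistic(m, cal)
    base = model_fit.independence_baseline(m, cal)
    assert base.M2 > 10 * target.M2
    fi = model_fit.fit_indices_from_m2(target.M2, target.df, m.n_persons,
                                       base.M2, base.df)
    assert fi.CFI > 0.95 and fi.TLI > 0.95 and fi.RMSEA < 0.03


# ------------------------------------------------------------------------- SRMR


def test_srmr_small_under_model_and_order_invariant(null_calibration):
    m, cal = null_calibration
    val = model_fit.srmr(m, cal)
    assert 0 <= val < 0.05
    # item order invariance
    perm = list(reversed(cal.item_ids))
    cal_perm = make_calibration([cal.params[cal.item_ids.index(i)] for i in perm])
    assert model_fit.srmr(m, cal_perm) == pytest.approx(val, abs=1e-12)


# -------------------------------------------------------------------- residuals


def test_residuals_small_under_local_independence():
    rng = np.random.default_rng(13)
    params = random_item_params(rng, [str(j) for j in range(5)], 3)
    theta = np.random.default_rng(14).standard_normal(5000)
    m = simulate_responses(theta, params, 15)
    cal = irt.fit_grm(m, m.item_ids)
    rc = model_fit.residual_correlations(m, cal)
    assert max(abs(rc.min_r), abs(rc.max_r)) < 0.1
    assert rc.flagged_pairs == []
    assert np.allclose(rc.matrix, rc.matrix.T)


def test_duplicated_item_flagged_by_q3():
    """A near-duplicate item pair is flagged with |r| at the matrix maximum.

    Q3 is the detector here: the marginal method lets maximum likelihood
    absorb a pairwise dependence into the two discriminations, while the
    duplicated pair's residual vectors stay almost identical at any trait
    estimate.
    """
    rng = np.random.default_rng(13)
    params = random_item_params(rng, [str(j) for j in range(4)], 3)
    theta = np.random.default_rng(14).standard_normal(3000)
    m = simulate_responses(theta, params, 15)
    clone = m.responses[:, 0].copy()
    flip = np.random.default_rng(99).random(3000) < 0.1
    clone[flip] = np.random.default_rng(100).integers(0, 3, 3000)[flip]
    m_dup = _matrix(np.column_stack([m.responses, clone]),
                    ids=m.item_ids + ["clone"])
    cal = irt.fit_grm(m_dup, m_dup.item_ids)
    rc = model_fit.residual_correlations(m_dup, cal, method="q3")
    assert any({a, b} == {"0", "clone"} for a, b, _ in rc.flagged_pairs)
    iu = np.triu_indices(5, k=1)
    top = np.argmax(np.abs(rc.matrix[iu]))
    pair = {rc.item_ids[iu[0][top]], rc.item_ids[iu[1][top]]}
    assert pair == {"0", "clone"}


def test_q3_method_exposes_short_test_bias(null_calibration):
    m, cal = null_calibration
    rc = model_fit.residual_correlations(m, cal, method="q3")
    # Yen's Q3 pulls residual correlations toward -1/(p-1) on a 5-item scale
    assert rc.third_quartile < 0.0
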