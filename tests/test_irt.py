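import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from conftest import make_calibration
from scalenorm import irt
from scalenorm.instruments import ResponseMatrix
from scalenorm.simulate import random_item_params, simulate_responses


def _matrix(values, ids=None):
    values = np.asarray(values)
    ids = ids or [str(j) for j in range(values.shape[1])]
    n = values.shape[0]
    return ResponseMatrix([f"p{i}" for i in range(n)], ids, values,
                          ["6-9"] * n, ["female"] * n)


# ---------------------------------------------------------------- probabilities


def test_category_probs_worked_example():
    item = irt.GRMItemParams("x", 2.0, (-1.0, 1.0))
    assert np.allclose(irt.grm_category_probs(0.0, item),
                       [0.1192, 0.7616, 0.1192], atol=5e-5)


def test_boundary_probability_half_at_threshold():
    item = irt.GRMItemParams("x", 1.7, (-0.4, 0.9))
    p = irt.grm_category_probs(0.9, item)
    # P(X >= 2) = p_2 = 0.5 when theta sits on the second threshold
    assert p[2] == pytest.approx(0.5, abs=1e-12)
    p = irt.grm_category_probs(-0.4, item)
    assert p[1] + p[2] == pytest.approx(0.5, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    a=st.floats(0.2, 4.0),
    b1=st.floats(-3, 2),
    step=st.floats(0.1, 2.0),
    theta=st.floats(-5, 5),
)
def test_category_probs_sum_to_one(a, b1, step, theta):
    item = irt.GRMItemParams("x", a, (b1, b1 + step, b1 + 2 * step))
    p = irt.grm_category_probs(theta, item)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)
    assert (p >= 0).all()


def test_binary_item_reduces_to_2pl():
    item = irt.GRMItemParams("x", 1.4, (0.3,))
    for theta in (-2.0, 0.0, 1.7):
        p = irt.grm_category_probs(theta, item)
        assert p[1] == pytest.approx(expit(1.4 * (theta - 0.3)), abs=1e-12)


# ------------------------------------------------------------------- EAP scores


def test_eap_matches_dense_grid_oracle():
    """EAP on the default grid agrees with brute-force dense integration."""
    for a, b, x in [(1.3, 0.4, 0), (1.3, 0.4, 1), (0.7, -1.2, 1), (2.5, 2.0, 0)]:
        item = irt.GRMItemParams("i", a, (b,))
        cal = make_calibration([item])
        m = _matrix([[x]], ids=["i"])
        got = irt.eap_scores(m, cal).theta_eap[0]
        grid = np.linspace(-9, 9, 10_001)
        like = irt.grm_prob_table(item, grid)[x] * stats.norm.pdf(grid)
        want = np.trapezoid(grid * like, grid) / np.trapezoid(like, grid)
        assert got == pytest.approx(want, abs=1e-6)


def test_eap_zero_for_symmetric_middle_pattern():
    items = [irt.GRMItemParams(str(j), 1.5, (-0.8, 0.8)) for j in range(4)]
    cal = make_calibration(items)
    m = _matrix([[1, 1, 1, 1]], ids=[str(j) for j in range(4)])
    assert irt.eap_scores(m, cal).theta_eap[0] == pytest.approx(0.0, abs=1e-10)


def test_eap_strictly_increasing_in_any_response():
    rng = np.random.default_rng(5)
    items = random_item_params(rng, [str(j) for j in range(4)], 3)
    cal = make_calibration(items)
    base = [1, 0, 2, 1]
    t0 = irt.eap_scores(_matrix([base], ids=cal.item_ids), cal).theta_eap[0]
    for j in (1, 3):
        up = list(base)
        up[j] += 1
        t1 = irt.eap_scores(_matrix([up], ids=cal.item_ids), cal).theta_eap[0]
        assert t1 > t0


def test_eap_rejects_out_of_range_response():
    cal = make_calibration([irt.GRMItemParams("i", 1.0, (0.0,))])
    with pytest.raises(ValueError):
        irt.eap_scores(_matrix([[5]], ids=["i"]), cal)


# ------------------------------------------------------------------ calibration


def test_fit_recovers_parameters_single_cohort(null_calibration, five_item_params):
    m, cal = null_calibration
    assert cal.converged
    for est, true in zip(cal.params, five_item_params):
        assert est.a == pytest.approx(true.a, abs=0.4)
        assert np.allclose(est.b, true.b, atol=0.25)


def test_em_loglik_monotone_and_optimal(null_calibration, five_item_params):
    m, cal = null_calibration
    assert all(np.diff(cal.ll_history) > -1e-6 * abs(cal.ll_history[0]))
    ll_truth = irt.log_marginal_likelihood(m, five_item_params, cal.grid)
    assert cal.log_marginal_likelihood >= ll_truth - 1e-6


def test_constant_column_raises():
    X = np.column_stack([np.zeros(50, dtype=int), np.arange(50) % 3])
    with pytest.raises(irt.CalibrationError, match="categories"):
        irt.fit_grm(_matrix(X), ["0", "1"])


def test_too_few_items_raises(null_cohort):
    m, _ = null_cohort
    with pytest.raises(irt.CalibrationError):
        irt.fit_grm(m, ["i0"])


def test_grsm_nests_grm():
    """A GRSM fit on data with shared steps approaches the GRM solution."""
    steps = np.array([-0.7, 0.7])
    items = [
        irt.GRMItemParams(str(j), a, tuple(d + steps))
        for j, (a, d) in enumerate([(1.4, -0.5), (1.9, 0.2), (1.1, 0.6), (2.2, -0.1)])
    ]
    theta = np.random.default_rng(11).standard_normal(1500)
    m = simulate_responses(theta, items, 42)
    ids = [it.item_id for it in items]
    grm = irt.fit_grm(m, ids, model="grm")
    grsm = irt.fit_grm(m, ids, model="grsm")
    # GRSM is the constrained submodel: slightly lower likelihood, close fit
    assert grsm.log_marginal_likelihood <= grm.log_marginal_likelihood + 1e-6
    assert grm.log_marginal_likelihood - grsm.log_marginal_likelihood < 8.0
    for e, g in zip(grsm.params, grm.params):
        assert e.a == pytest.approx(g.a, abs=0.35)
        assert np.allclose(e.b, g.b, atol=0.3)


# ------------------------------------------------------------------ information


def test_information_nonnegative_everywhere():
    rng = np.random.default_rng(6)
    cal = make_calibration(random_item_params(rng, list("abc"), 4))
    grid = np.linspace(-6, 6, 121)
    assert (irt.test_information(cal, grid) >= 0).all()


def test_information_quadruples_for_binary_item_at_threshold():
    b = 0.3
    base = make_calibration([irt.GRMItemParams("x", 0.9, (b,))])
    doubled = make_calibration([irt.GRMItemParams("x", 1.8, (b,))])
    t = np.array([b])
    i1 = irt.test_information(base, t)[0]
    i4 = irt.test_information(doubled, t)[0]
    assert i4 == pytest.approx(4 * i1, rel=1e-12)


def test_information_single_peaked_for_one_item():
    cal = make_calibration([irt.GRMItemParams("x", 1.6, (-0.2, 0.2))])
    grid = np.linspace(-6, 6, 241)
    info = irt.test_information(cal, grid)
    d = np.diff(info)
    # one sign change: increasing then decreasing
    assert np.sum(np.diff(np.sign(d[np.abs(d) > 1e-12])) != 0) <= 1
    assert grid[np.argmax(info)] == pytest.approx(0.0, abs=0.3)


# --------------------------------------------------------- summed-score posterior


def test_single_item_posterior_is_marginal():
    item = irt.GRMItemParams("x", 1.3, (-0.6, 0.9))
    cal = make_calibration([item])
    ssp = irt.summed_score_posterior(cal)
    marginal = irt.grm_prob_table(item, cal.grid.nodes) @ cal.grid.weights
    assert np.allclose(ssp.probs, marginal, atol=1e-14)


def test_three_item_posterior_matches_enumeration():
    """Lord-Wingersky equals brute-force enumeration of all 27 patterns."""
    from itertools import product

    rng = np.random.default_rng(3)
    params = [
        irt.GRMItemParams(f"i{j}", float(rng.uniform(0.9, 2.2)),
                          tuple(np.sort(rng.uniform(-2, 2, 2))))
        for j in range(3)
    ]
    cal = make_calibration(params)
    ssp = irt.summed_score_posterior(cal)
    nodes, w = cal.grid.nodes, cal.grid.weights
    probs = np.zeros(7)
    tmoment = np.zeros(7)
    for pattern in product(range(3), repeat=3):
        like = np.ones_like(nodes)
        for j, x in enumerate(pattern):
            like = like * irt.grm_prob_table(params[j], nodes)[x]
        s = sum(pattern)
        probs[s] += like @ w
        tmoment[s] += (like * nodes) @ w
    assert np.abs(probs - ssp.probs).max() <= 1e-10
    assert np.abs(tmoment / probs - ssp.theta_given_s).max() <= 1e-10
    assert ssp.probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_expected_theta_nondecreasing_in_sum(null_calibration):
    _, cal = null_calibration
    ssp = irt.summed_score_posterior(cal)
    assert (np.diff(ssp.theta_given_s) > 0).all()


# ------------------------------------------------------------------------ infit


def test_infit_near_one_under_model():
    rng = np.random.default_rng(8)
    params = random_item_params(rng, [str(j) for j in range(5)], 3)
    theta = np.random.default_rng(9).standard_normal(5000)
    m = simulate_responses(theta, params, 10)
    cal = make_calibration(params)
    rep = irt.infit_mean_squares(m, cal)
    assert (rep.item_infit > 0.9).all() and (rep.item_infit < 1.1).all()
    assert rep.person_infit.mean() == pytest.approx(1.0, abs=0.1)


def test_infit_detects_noise_item():
    rng = np.random.default_rng(8)
    params = random_item_params(rng, [str(j) for j in range(5)], 3)
    theta = np.random.default_rng(9).standard_normal(3000)
    m = simulate_responses(theta, params, 10)
    noisy = m.responses.copy()
    noisy[:, 2] = np.random.default_rng(0).integers(0, 3, size=3000)
    m_noisy = _matrix(noisy, ids=m.item_ids)
    rep = irt.infit_mean_squares(m_noisy, make_calibration(params))
    assert rep.item_infit[2] > 1.5


def test_infit_point_method_runs(null_calibration):
    m, cal = null_calibration
    rep = irt.infit_mean_squares(m, cal, method="point")
    assert (rep.item_infit > 0).all()
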