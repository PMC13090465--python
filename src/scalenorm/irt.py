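"""Unidimensional graded-response IRT: calibration, scoring, diagnostics.

The graded response model (GRM) for an item with K ordered categories has a
discrimination ``a`` and ordered boundary thresholds ``b_1 < ... < b_{K-1}``
on the latent-trait scale.  Cumulative (boundary) probabilities follow
logistic curves,

    P(X >= k | theta) = sigma(a * (theta - b_k)),    k = 1..K-1,

with the conventions P(X >= 0) = 1 and P(X >= K) = 0, so the category
probability is the difference of adjacent boundary curves.  The logistic
metric is used without the 1.702 scaling constant; that constant enters only
when parameters are converted to normal-ogive factor loadings (see
:mod:`scalenorm.model_fit`).

The graded rating scale model (GRSM) is the constrained variant in which all
items share one ordered step vector ``t`` and each item contributes a single
location ``d_j``: ``b_jk = d_j + t_k``.  The steps are identified by
centering ``t`` at zero.

Calibration is marginal maximum likelihood with a standard-normal latent
prior, estimated by EM over a fixed quadrature grid.  With K = 2 the model
reduces exactly to the two-parameter logistic model; binary instruments run
through the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .instruments import ResponseMatrix

__all__ = [
    "GRMItemParams",
    "QuadratureGrid",
    "Calibration",
    "PersonScores",
    "InfitReport",
    "SummedScorePosterior",
    "CalibrationError",
    "default_grid",
    "grm_category_probs",
    "grm_prob_table",
    "fit_grm",
    "eap_scores",
    "test_information",
    "infit_mean_squares",
    "summed_score_posterior",
]


class CalibrationError(RuntimeError):
    """Raised when a subscale cannot be calibrated (degenerate data etc.)."""


@dataclass(frozen=True)
class GRMItemParams:
    """Discrimination and ordered boundary thresholds for one item."""

    item_id: str
    a: float
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        if not np.all(np.isfinite(b)) or not np.isfinite(self.a):
            raise ValueError(f"item {self.item_id}: non-finite parameters")
        if self.a <= 0:
            raise ValueError(f"item {self.item_id}: a must be > 0")
        if b.size >= 2 and not np.all(np.diff(b) > 0):
            raise ValueError(f"item {self.item_id}: thresholds must be increasing")
        object.__setattr__(self, "b", tuple(float(x) for x in b))

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed latent-trait integration grid with prior weights summing to 1."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValueError("nodes and weights must be matching 1-D vectors")
        if (weights < 0).any():
            raise ValueError("negative quadrature weight")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / weights.sum())


def default_grid(n_points: int = 61, bound: float = 6.0) -> QuadratureGrid:
    """Equally spaced nodes on [-bound, bound] with N(0,1) weights, renormalized."""
    nodes = np.linspace(-bound, bound, n_points)
    return QuadratureGrid(nodes=nodes, weights=stats.norm.pdf(nodes))


@dataclass
class Calibration:
    """Fitted parameters plus estimation metadata for one subscale."""

    params: list[GRMItemParams]
    model: str
    grid: QuadratureGrid
    log_marginal_likelihood: float
    n_iterations: int
    converged: bool
    ll_history: list[float] = field(default_factory=list)

    @property
    def item_ids(self) -> list[str]:
        return [p.item_id for p in self.params]


@dataclass
class PersonScores:
    """EAP latent-trait scores (posterior mean and sd) per person."""

    person_ids: list[str]
    theta_eap: np.ndarray
    theta_sd: np.ndarray


@dataclass
class InfitReport:
    """Information-weighted mean-square residuals by item and by person."""

    item_ids: list[str]
    item_infit: np.ndarray
    person_infit: np.ndarray


@dataclass
class SummedScorePosterior:
    """Distribution of the crude summed score and E[theta | S = s]."""

    scores: np.ndarray           # attainable sums 0..S_max
    probs: np.ndarray            # marginal P(S = s) under the N(0,1) prior
    theta_given_s: np.ndarray    # posterior mean of theta at each sum
    conditional: np.ndarray      # P(S = s | theta_q), shape (S_max+1, Q)


# ---------------------------------------------------------------------------
# model probabilities


def _boundary_probs(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P(X >= k | theta) for k = 1..K-1; shape (K-1, len(theta))."""
    z = a * (theta[None, :] - np.asarray(b, dtype=float)[:, None])
    return special.expit(z)


def grm_prob_table(item: GRMItemParams, theta: np.ndarray) -> np.ndarray:
    """Category probabilities P(X = k | theta), shape (K, len(theta))."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    pstar = _boundary_probs(item.a, np.asarray(item.b), theta)
    upper = np.vstack([np.ones_like(theta)[None, :], pstar])
    lower = np.vstack([pstar, np.zeros_like(theta)[None, :]])
    return np.clip(upper - lower, 1e-300, 1.0)


def grm_category_probs(theta: float, item: GRMItemParams) -> np.ndarray:
    """Category probability vector at a single trait value; sums to 1."""
    return grm_prob_table(item, np.array([theta]))[:, 0]


# ---------------------------------------------------------------------------
# M-step objective (per item, expected counts R of shape (K, Q))


def _item_nll_grad(a: float, b: np.ndarray, R: np.ndarray, nodes: np.ndarray):
    """Negative expected complete-data log-lik and its gradient wrt (a, b)."""
    K = R.shape[0]
    pstar = _boundary_probs(a, b, nodes)                      # (K-1, Q)
    upper = np.vstack([np.ones((1, nodes.size)), pstar])
    lower = np.vstack([pstar, np.zeros((1, nodes.size))])
    P = np.clip(upper - lower, 1e-12, 1.0)                    # (K, Q)
    nll = -float(np.sum(R * np.log(P)))
    S = pstar * (1.0 - pstar)                                 # (K-1, Q)
    ratio = R / P                                             # (K, Q)
    # d/db_m: a * S_m * (ratio_{m-1} - ratio_m), m = 1..K-1 (1-based)
    g_b = a * np.sum(S * (ratio[:-1] - ratio[1:]), axis=1)
    # d/da: sum_k ratio_k * [(theta - b_k) S_k - (theta - b_{k+1}) S_{k+1}]
    T = (nodes[None, :] - b[:, None]) * S                     # (K-1, Q)
    Tpad_hi = np.vstack([np.zeros((1, nodes.size)), T])       # index k
    Tpad_lo = np.vstack([T, np.zeros((1, nodes.size))])       # index k+1
    g_a = float(np.sum(ratio * (Tpad_hi - Tpad_lo)))
    return nll, -g_a, -g_b


def _unpack_item(x: np.ndarray, K: int) -> tuple[float, np.ndarray]:
    a = float(np.exp(x[0]))
    if K == 2:
        return a, x[1:2].copy()
    b = np.empty(K - 1)
    b[0] = x[1]
    b[1:] = x[1] + np.cumsum(np.exp(x[2:]))
    return a, b


def _pack_item(a: float, b: np.ndarray) -> np.ndarray:
    K = b.size + 1
    x = np.empty(1 + (K - 1))
    x[0] = np.log(a)
    x[1] = b[0]
    if K > 2:
        x[2:] = np.log(np.maximum(np.diff(b), 1e-4))
    return x


def _item_objective(x: np.ndarray, K: int, R: np.ndarray, nodes: np.ndarray):
    a, b = _unpack_item(x, K)
    nll, ga, gb = _item_nll_grad(a, b, R, nodes)
    grad = np.empty_like(x)
    grad[0] = ga * a                       # chain rule through log a
    grad[1] = gb.sum()                     # b_1 shifts every threshold
    if K > 2:
        steps = np.exp(x[2:])
        # gamma_t moves b_m for all m > t (0-based step t feeds b_{t+1}..)
        grad[2:] = steps * np.cumsum(gb[::-1])[::-1][1:]
    return nll, grad


# ---------------------------------------------------------------------------
# EM calibration


def _posterior(
    X: np.ndarray, params: Sequence[GRMItemParams], grid: QuadratureGrid
) -> tuple[np.ndarray, float]:
    """Posterior weights over nodes per person and the marginal log-lik."""
    n = X.shape[0]
    logL = np.zeros((n, grid.nodes.size))
    for j, item in enumerate(params):
        logP = np.log(grm_prob_table(item, grid.nodes))       # (K, Q)
        logL += logP[X[:, j], :]
    logL += np.log(grid.weights)[None, :]
    mx = logL.max(axis=1, keepdims=True)
    L = np.exp(logL - mx)
    norm = L.sum(axis=1, keepdims=True)
    ll = float(np.sum(np.log(norm) + mx))
    return L / norm, ll


def _start_values(X: np.ndarray, item_ids: Sequence[str], K_list: Sequence[int]):
    params = []
    for j, (iid, K) in enumerate(zip(item_ids, K_list)):
        counts = np.bincount(X[:, j], minlength=K).astype(float)
        if np.count_nonzero(counts) < 2:
            raise CalibrationError(
                f"item {iid}: fewer than 2 observed categories; collapse "
                "categories or drop the item"
            )
        cum = np.cumsum(counts)[:-1] / counts.sum()           # P(X <= k-1)
        b = stats.norm.ppf(np.clip(cum, 1e-3, 1 - 1e-3))
        # enforce strict ordering in case of empty middle categories
        for k in range(1, b.size):
            b[k] = max(b[k], b[k - 1] + 1e-3)
        params.append(GRMItemParams(item_id=str(iid), a=1.0, b=tuple(b)))
    return params


def _mstep_grm(params, R_list, nodes):
    new = []
    for item, R in zip(params, R_list):
        K = R.shape[0]
        x0 = _pack_item(item.a, np.asarray(item.b))
        # bounds keep a in [e^-6, e^3.4~30] and thresholds finite even for
        # degenerate items (e.g. a duplicated pair drives a to the boundary)
        bounds = [(-6.0, 3.4), (-30.0, 30.0)] + [(-12.0, 3.0)] * (K - 2)
        res = optimize.minimize(
            _item_objective,
            x0,
            args=(K, R, nodes),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 60, "ftol": 1e-10},
        )
        a, b = _unpack_item(res.x, K)
        a = float(np.clip(a, 1e-3, 60.0))
        new.append(GRMItemParams(item_id=item.item_id, a=a, b=tuple(b)))
    return new


def _grsm_build(a_vec, d_vec, gamma, K):
    steps = np.concatenate([[0.0], np.cumsum(np.exp(gamma))]) if K > 2 else np.array([0.0])
    t = steps - steps.mean()
    return [
        (float(a), d + t) for a, d in zip(a_vec, d_vec)
    ], t


def _mstep_grsm(params, R_list, nodes, K):
    p = len(params)

    def unpack(x):
        a_vec = np.exp(x[:p])
        d_vec = x[p : 2 * p]
        gamma = x[2 * p :]
        return a_vec, d_vec, gamma

    def nll(x):
        a_vec, d_vec, gamma = unpack(x)
        built, _ = _grsm_build(a_vec, d_vec, gamma, K)
        total = 0.0
        for (a, b), R in zip(built, R_list):
            v, _, _ = _item_nll_grad(a, b, R, nodes)
            total += v
        return total

    # current t from params (thresholds share spacing across items)
    b0 = np.asarray(params[0].b)
    t0 = b0 - b0.mean()
    gamma0 = np.log(np.maximum(np.diff(t0), 1e-3)) if K > 2 else np.empty(0)
    x0 = np.concatenate(
        [
            np.log([it.a for it in params]),
            [np.mean(it.b) for it in params],
            gamma0,
        ]
    )
    res = optimize.minimize(nll, x0, method="L-BFGS-B", options={"maxiter": 120})
    a_vec, d_vec, gamma = unpack(res.x)
    built, _ = _grsm_build(a_vec, d_vec, gamma, K)
    return [
        GRMItemParams(item_id=it.item_id, a=float(np.clip(a, 1e-3, 60.0)), b=tuple(b))
        for it, (a, b) in zip(params, built)
    ]


def fit_grm(
    m: ResponseMatrix,
    subscale: Sequence[str],
    *,
    model: str = "grm",
    grid: QuadratureGrid | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> Calibration:
    """Calibrate a subscale by EM marginal maximum likelihood.

    The latent trait is fixed to N(0,1) for identification.  The marginal
    log-likelihood is monotone nondecreasing across EM iterations; a
    decrease beyond numerical noise raises :class:`CalibrationError`.
    """
    if len(subscale) < 2:
        raise CalibrationError("need at least 2 items to calibrate")
    if model not in ("grm", "grsm"):
        raise ValueError(f"unknown model {model!r}")
    sub = m.subset_items(list(subscale))
    X = np.asarray(sub.responses, dtype=np.int64)
    K_list = [int(X[:, j].max()) + 1 for j in range(X.shape[1])]
    # K from observed data; a never-observed top category cannot be estimated
    params = _start_values(X, sub.item_ids, K_list)
    if model == "grsm" and len(set(K_list)) != 1:
        raise CalibrationError("GRSM requires equal category counts across items")
    grid = default_grid() if grid is None else grid

    ll_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post, ll = _posterior(X, params, grid)
        ll_history.append(ll)
        if len(ll_history) >= 2:
            if ll < ll_history[-2] - 1e-6 * max(1.0, abs(ll)):
                raise CalibrationError(
                    f"EM log-likelihood decreased at iteration {it}"
                )
            if abs(ll - ll_history[-2]) < tol:
                converged = True
                break
        R_list = _expected_counts(X, params, post)
        if model == "grm":
            params = _mstep_grm(params, R_list, grid.nodes)
        else:
            params = _mstep_grsm(params, R_list, grid.nodes, K_list[0])
    _, ll_final = _posterior(X, params, grid)
    return Calibration(
        params=params,
        model=model,
        grid=grid,
        log_marginal_likelihood=ll_final,
        n_iterations=it,
        converged=converged,
        ll_history=ll_history,
    )


def _expected_counts(X: np.ndarray, params, post: np.ndarray):
    """Expected category-by-node counts R_j (K x Q) for every item."""
    R_list = []
    for j, item in enumerate(params):
        K = item.n_categories
        R = np.zeros((K, post.shape[1]))
        for k in range(K):
            mask = X[:, j] == k
            if mask.any():
                R[k] = post[mask].sum(axis=0)
        R_list.append(R)
    return R_list


def log_marginal_likelihood(
    m: ResponseMatrix, params: Sequence[GRMItemParams], grid: QuadratureGrid
) -> float:
    """Marginal log-likelihood of a response matrix at given parameters."""
    sub = m.subset_items([p.item_id for p in params])
    _, ll = _posterior(np.asarray(sub.responses, dtype=np.int64), params, grid)
    return ll


# ---------------------------------------------------------------------------
# scoring and diagnostics


def eap_scores(m: ResponseMatrix, cal: Calibration) -> PersonScores:
    """Expected-a-posteriori trait scores under the N(0,1) prior."""
    sub = m.subset_items(cal.item_ids)
    X = np.asarray(sub.responses, dtype=np.int64)
    for j, item in enumerate(cal.params):
        if (X[:, j] > item.n_categories - 1).any():
            raise ValueError(f"response out of range for item {item.item_id}")
    post, _ = _posterior(X, cal.params, cal.grid)
    mean = post @ cal.grid.nodes
    second = post @ cal.grid.nodes**2
    sd = np.sqrt(np.maximum(second - mean**2, 1e-12))
    return PersonScores(person_ids=list(sub.person_ids), theta_eap=mean, theta_sd=sd)


def item_information(item: GRMItemParams, theta: np.ndarray) -> np.ndarray:
    """Fisher information of one graded item along the trait axis."""
    theta = np.asarray(theta, dtype=float)
    pstar = _boundary_probs(item.a, np.asarray(item.b), theta)
    S = pstar * (1 - pstar)
    Spad = np.vstack([np.zeros((1, theta.size)), S, np.zeros((1, theta.size))])
    P = grm_prob_table(item, theta)
    dP = item.a * (Spad[:-1] - Spad[1:])
    return np.sum(dP**2 / P, axis=0)


def test_information(cal: Calibration, theta: np.ndarray) -> np.ndarray:
    """Test information curve: sum of item informations; nonnegative."""
    theta = np.asarray(theta, dtype=float)
    return np.sum([item_information(it, theta) for it in cal.params], axis=0)


def infit_mean_squares(
    m: ResponseMatrix,
    cal: Calibration,
    scores: PersonScores | None = None,
    *,
    method: str = "posterior",
) -> InfitReport:
    """Information-weighted mean-square residuals; near 1 under model fit.

    Item infit is ``sum_n (x_nj - E_nj)^2 / sum_n W_nj`` with E the model
    category mean and W the model variance; person infit is the analogous
    ratio over items.

    ``method="posterior"`` (default) integrates both numerator and
    denominator over each person's trait posterior, which keeps the
    statistic centred at 1 regardless of subscale length.
    ``method="point"`` evaluates both at the EAP point estimate; with few
    items that convention runs systematically below 1 because the point
    estimate is fitted to the same responses.
    """
    sub = m.subset_items(cal.item_ids)
    X = np.asarray(sub.responses, dtype=np.int64)
    n, p = X.shape
    num = np.empty((n, p))
    den = np.empty((n, p))
    if method == "point":
        if scores is None:
            scores = eap_scores(m, cal)
        theta = scores.theta_eap
        for j, item in enumerate(cal.params):
            P = grm_prob_table(item, theta)                   # (K, n)
            k = np.arange(item.n_categories, dtype=float)[:, None]
            Ej = np.sum(k * P, axis=0)
            num[:, j] = (X[:, j] - Ej) ** 2
            den[:, j] = np.sum(k**2 * P, axis=0) - Ej**2
    elif method == "posterior":
        post, _ = _posterior(X, cal.params, cal.grid)
        for j, item in enumerate(cal.params):
            P = grm_prob_table(item, cal.grid.nodes)          # (K, Q)
            k = np.arange(item.n_categories, dtype=float)[:, None]
            Ej = np.sum(k * P, axis=0)
            Wj = np.sum(k**2 * P, axis=0) - Ej**2
            num[:, j] = (post * (X[:, [j]] - Ej[None, :]) ** 2).sum(axis=1)
            den[:, j] = post @ Wj
    else:
        raise ValueError(f"unknown infit method {method!r}")
    if not np.all(den.sum(axis=0) > 0) or not np.all(den.sum(axis=1) > 0):
        raise CalibrationError("degenerate model variance in infit computation")
    return InfitReport(
        item_ids=list(cal.item_ids),
        item_infit=num.sum(axis=0) / den.sum(axis=0),
        person_infit=num.sum(axis=1) / den.sum(axis=1),
    )


def summed_score_posterior(cal: Calibration) -> SummedScorePosterior:
    """Summed-score distribution and E[theta | S = s] by recursive convolution.

    At each quadrature node the distribution of the crude sum is built item
    by item (Lord-Wingersky recursion); posterior weighting over nodes gives
    the marginal P(S = s) and the expected trait given each sum.
    """
    nodes, w = cal.grid.nodes, cal.grid.weights
    f = np.ones((1, nodes.size))
    for item in cal.params:
        P = grm_prob_table(item, nodes)                       # (K, Q)
        K = P.shape[0]
        g = np.zeros((f.shape[0] + K - 1, nodes.size))
        for k in range(K):
            g[k : k + f.shape[0]] += f * P[k][None, :]
        f = g
    probs = f @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_given_s = (f * nodes[None, :]) @ w / probs
    theta_given_s = np.where(probs > 0, theta_given_s, np.nan)
    return SummedScorePosterior(
        scores=np.arange(f.shape[0]),
        probs=probs,
        theta_given_s=theta_given_s,
        conditional=f,
    )
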