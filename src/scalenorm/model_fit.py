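"""Global fit for a subscale calibration: M2, derived indices, residuals.

Full-pattern chi-square tests are infeasible for ordinal questionnaires
(the contingency table is mostly empty), so global fit uses the
limited-information M2 statistic built from univariate and bivariate
margins of the item contingency table.  Writing ``pi`` for the vector of
model-implied margin probabilities, ``p`` for their sample analogues and
``Delta = d pi / d eta`` for the Jacobian with respect to the free item
parameters,

    M2 = n * e' C2 e,   e = p - pi(eta_hat),
    C2 = Xi^-1 - Xi^-1 Delta (Delta' Xi^-1 Delta)^-1 Delta' Xi^-1,

where Xi is the asymptotic covariance of the sample margins under the
model.  M2 is asymptotically chi-square with df = (#margins - #free
parameters).  RMSEA, CFI and TLI are derived from M2 against an
independence baseline fitted to the same margins; SRMR compares observed
and model-implied inter-item Pearson correlations.

Residual correlations (Q3-style, computed against EAP trait estimates)
probe local independence; pairs with |r| >= 0.2 are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import special, stats

from .instruments import ResponseMatrix
from .irt import (
    Calibration,
    CalibrationError,
    PersonScores,
    eap_scores,
    grm_prob_table,
)

__all__ = [
    "FitIndices",
    "LoadingSet",
    "ResidualCorrelations",
    "irt_to_loadings",
    "m2_statistic",
    "independence_baseline",
    "fit_indices_from_m2",
    "srmr",
    "residual_correlations",
    "fit_indices",
]

#: normal-ogive scaling constant used only for the loading conversion
OGIVE_SCALE = 1.702


@dataclass
class FitIndices:
    M2: float
    df: int
    p_value: float
    RMSEA: float | None = None
    SRMR: float | None = None
    CFI: float | None = None
    TLI: float | None = None


@dataclass
class LoadingSet:
    """Standardized one-factor loadings and uniquenesses per item."""

    item_ids: list[str]
    loadings: np.ndarray
    uniquenesses: np.ndarray


@dataclass
class ResidualCorrelations:
    """Item-pair residual correlations with a Q3 summary and flags."""

    item_ids: list[str]
    matrix: np.ndarray
    third_quartile: float
    min_r: float
    max_r: float
    flagged_pairs: list[tuple[str, str, float]]   # |r| >= threshold
    threshold: float = 0.2


def irt_to_loadings(cal: Calibration) -> LoadingSet:
    """Convert logistic discriminations to normal-ogive factor loadings.

    lambda_j = a*_j / sqrt(1 + a*_j^2) with a*_j = a_j / 1.702; the
    uniqueness is psi_j = 1 - lambda_j^2.
    """
    a_star = np.array([p.a for p in cal.params]) / OGIVE_SCALE
    lam = a_star / np.sqrt(1.0 + a_star**2)
    return LoadingSet(
        item_ids=list(cal.item_ids), loadings=lam, uniquenesses=1.0 - lam**2
    )


# ---------------------------------------------------------------------------
# margins machinery


def _margin_index(K_list: Sequence[int]):
    """Univariate then bivariate margins, one entry per (item, category>=1)."""
    uni = [((j, k),) for j, K in enumerate(K_list) for k in range(1, K)]
    biv = [
        ((i, k), (j, l))
        for i in range(len(K_list))
        for j in range(i + 1, len(K_list))
        for k in range(1, K_list[i])
        for l in range(1, K_list[j])
    ]
    return uni + biv


def _margin_probs(margins, ptabs: list[np.ndarray], weights: np.ndarray):
    """Model margin probabilities pi and the node-wise table C (M x Q)."""
    Q = ptabs[0].shape[1]
    C = np.empty((len(margins), Q))
    for m, cells in enumerate(margins):
        row = np.ones(Q)
        for (j, k) in cells:
            row = row * ptabs[j][k]
        C[m] = row
    return C @ weights, C


def _observed_margins(X: np.ndarray, margins) -> np.ndarray:
    n = X.shape[0]
    out = np.empty(len(margins))
    for m, cells in enumerate(margins):
        ind = np.ones(n, dtype=bool)
        for (j, k) in cells:
            ind &= X[:, j] == k
        out[m] = ind.mean()
    return out


def _xi_matrix(margins, ptabs, weights, C, pi):
    """Asymptotic covariance of sample margins under the model.

    Base term treats margin pairs as item-disjoint (a single matrix
    product); pairs sharing items are then corrected exactly, including the
    diagonal: the joint probability divides out doubly counted item factors
    and is zero when the two margins demand different categories of the
    same item.
    """
    W = weights
    joint = (C * W[None, :]) @ C.T
    postings: dict[int, list[int]] = {}
    for m, cells in enumerate(margins):
        for (j, _k) in cells:
            postings.setdefault(j, []).append(m)
    seen = set()
    for j, ms in postings.items():
        for ai in range(len(ms)):
            for bi in range(ai, len(ms)):
                pair = (ms[ai], ms[bi])
                if pair in seen:
                    continue
                seen.add(pair)
                m1, m2 = pair
                d1 = dict(margins[m1])
                d2 = dict(margins[m2])
                shared = set(d1) & set(d2)
                if any(d1[s] != d2[s] for s in shared):
                    joint[m1, m2] = joint[m2, m1] = 0.0
                    continue
                denom = np.ones_like(W)
                for s in shared:
                    denom = denom * ptabs[s][d1[s]]
                val = float(np.sum(W * C[m1] * C[m2] / denom))
                joint[m1, m2] = joint[m2, m1] = val
    return joint - np.outer(pi, pi)


def _m2_from_parts(p_obs, pi, Xi, Delta, n, n_free):
    e = p_obs - pi
    # ridge for numerical stability; margins can be nearly collinear
    M = Xi.shape[0]
    Xi = Xi + 1e-10 * np.eye(M)
    try:
        Xi_inv_e = np.linalg.solve(Xi, e)
        Xi_inv_D = np.linalg.solve(Xi, Delta)
    except np.linalg.LinAlgError as exc:
        raise CalibrationError(
            "singular margin covariance; consider collapsing sparse categories"
        ) from exc
    A = Delta.T @ Xi_inv_D
    try:
        B = np.linalg.solve(A, Delta.T @ Xi_inv_e)
    except np.linalg.LinAlgError:
        B = np.linalg.lstsq(A, Delta.T @ Xi_inv_e, rcond=None)[0]
    quad = float(e @ Xi_inv_e - (Delta.T @ Xi_inv_e) @ B)
    m2 = max(n * quad, 0.0)
    df = M - n_free
    if df <= 0:
        raise CalibrationError("non-positive degrees of freedom for M2")
    return m2, df, float(stats.chi2.sf(m2, df))


def _grm_free_vector(cal: Calibration) -> np.ndarray:
    return np.concatenate([[p.a, *p.b] for p in cal.params])


def _grm_ptabs_from_vector(vec: np.ndarray, cal: Calibration) -> list[np.ndarray]:
    ptabs = []
    pos = 0
    for p in cal.params:
        K = p.n_categories
        a = vec[pos]
        b = vec[pos + 1 : pos + K]
        pos += K
        z = a * (cal.grid.nodes[None, :] - np.asarray(b)[:, None])
        pstar = special.expit(z)
        upper = np.vstack([np.ones((1, z.shape[1])), pstar])
        lower = np.vstack([pstar, np.zeros((1, z.shape[1]))])
        ptabs.append(np.clip(upper - lower, 1e-300, 1.0))
    return ptabs


def _jacobian(margins, vec, ptab_fn, weights, h: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of margin probabilities wrt parameters."""
    cols = []
    for i in range(vec.size):
        up, dn = vec.copy(), vec.copy()
        up[i] += h
        dn[i] -= h
        pi_up, _ = _margin_probs(margins, ptab_fn(up), weights)
        pi_dn, _ = _margin_probs(margins, ptab_fn(dn), weights)
        cols.append((pi_up - pi_dn) / (2 * h))
    return np.column_stack(cols)


def m2_statistic(m: ResponseMatrix, cal: Calibration) -> FitIndices:
    """Limited-information M2 fit statistic for a fitted GRM/GRSM subscale."""
    sub = m.subset_items(cal.item_ids)
    X = np.asarray(sub.responses, dtype=np.int64)
    n = X.shape[0]
    K_list = [p.n_categories for p in cal.params]
    margins = _margin_index(K_list)
    ptabs = [grm_prob_table(p, cal.grid.nodes) for p in cal.params]
    pi, C = _margin_probs(margins, ptabs, cal.grid.weights)
    p_obs = _observed_margins(X, margins)
    Xi = _xi_matrix(margins, ptabs, cal.grid.weights, C, pi)
    vec = _grm_free_vector(cal)
    Delta = _jacobian(margins, vec, lambda v: _grm_ptabs_from_vector(v, cal),
                      cal.grid.weights)
    m2, df, pval = _m2_from_parts(p_obs, pi, Xi, Delta, n, vec.size)
    return FitIndices(M2=m2, df=df, p_value=pval)


def independence_baseline(m: ResponseMatrix, cal: Calibration) -> FitIndices:
    """M2 of the no-association model with the same univariate margins.

    The baseline keeps each item's marginal category distribution free
    (cumulative-logit parameters, ML = observed proportions) and sets every
    inter-item association to zero; it anchors the incremental CFI/TLI.
    """
    sub = m.subset_items(cal.item_ids)
    X = np.asarray(sub.responses, dtype=np.int64)
    n = X.shape[0]
    K_list = [p.n_categories for p in cal.params]
    margins = _margin_index(K_list)
    # ML thresholds: cumulative logits of observed P(X >= k)
    cvec = []
    for j, K in enumerate(K_list):
        for k in range(1, K):
            prop = np.clip((X[:, j] >= k).mean(), 1e-6, 1 - 1e-6)
            cvec.append(special.logit(prop))
    cvec = np.asarray(cvec)

    def ptab_fn(vec: np.ndarray) -> list[np.ndarray]:
        ptabs = []
        pos = 0
        for K in K_list:
            c = vec[pos : pos + K - 1]
            pos += K - 1
            pstar = special.expit(c)[:, None] * np.ones((1, 1))
            upper = np.vstack([np.ones((1, 1)), pstar])
            lower = np.vstack([pstar, np.zeros((1, 1))])
            ptabs.append(np.clip(upper - lower, 1e-300, 1.0))
        return ptabs

    weights = np.ones(1)
    ptabs = ptab_fn(cvec)
    pi, C = _margin_probs(margins, ptabs, weights)
    p_obs = _observed_margins(X, margins)
    Xi = _xi_matrix(margins, ptabs, weights, C, pi)
    Delta = _jacobian(margins, cvec, ptab_fn, weights)
    m2, df, pval = _m2_from_parts(p_obs, pi, Xi, Delta, n, cvec.size)
    return FitIndices(M2=m2, df=df, p_value=pval)


def fit_indices_from_m2(
    M2: float, df: int, n: int, M2_b: float, df_b: int
) -> FitIndices:
    """RMSEA/CFI/TLI from the target and independence-baseline statistics."""
    if df_b <= 1:
        raise ValueError("baseline degrees of freedom must exceed 1")
    rmsea = float(np.sqrt(max(0.0, (M2 - df) / (df * (n - 1)))))
    num = max(0.0, M2 - df)
    den = max(M2 - df, M2_b - df_b, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    ratio_b = M2_b / df_b
    tli = ((ratio_b - M2 / df) / (ratio_b - 1.0)) if ratio_b > 1.0 else 1.0
    return FitIndices(
        M2=M2,
        df=df,
        p_value=float(stats.chi2.sf(M2, df)),
        RMSEA=rmsea,
        CFI=float(np.clip(cfi, 0.0, 1.0)),
        TLI=float(min(tli, 1.0)),
    )


def _model_implied_corr(cal: Calibration) -> np.ndarray:
    nodes, w = cal.grid.nodes, cal.grid.weights
    p = len(cal.params)
    E = np.empty((p, nodes.size))
    E2 = np.empty((p, nodes.size))
    for j, item in enumerate(cal.params):
        P = grm_prob_table(item, nodes)
        k = np.arange(item.n_categories, dtype=float)[:, None]
        E[j] = np.sum(k * P, axis=0)
        E2[j] = np.sum(k**2 * P, axis=0)
    mean = E @ w
    cov = (E * w[None, :]) @ E.T - np.outer(mean, mean)
    var = E2 @ w - mean**2
    np.fill_diagonal(cov, var)
    sd = np.sqrt(var)
    return cov / np.outer(sd, sd)


def srmr(m: ResponseMatrix, cal: Calibration) -> float:
    """Root mean square of observed-minus-implied inter-item correlations."""
    sub = m.subset_items(cal.item_ids)
    X = np.asarray(sub.responses, dtype=float)
    obs = np.corrcoef(X, rowvar=False)
    mod = _model_implied_corr(cal)
    iu = np.triu_indices(X.shape[1], k=1)
    return float(np.sqrt(np.mean((obs[iu] - mod[iu]) ** 2)))


def residual_correlations(
    m: ResponseMatrix,
    cal: Calibration,
    scores: PersonScores | None = None,
    *,
    method: str = "marginal",
    threshold: float = 0.2,
) -> ResidualCorrelations:
    """Pairwise local-dependence residuals; near zero under the model.

    ``method="marginal"`` (default) takes the difference between observed
    and model-implied inter-item Pearson correlations; under local
    independence each entry is O(n^-1/2).  ``method="q3"`` correlates
    item residuals against the EAP trait estimate (Yen's Q3); note Q3
    carries a built-in negative bias of about -1/(p-1) on short subscales
    because the trait estimate consumes the shared variance of both items.
    """
    sub = m.subset_items(cal.item_ids)
    X = np.asarray(sub.responses, dtype=float)
    if method == "marginal":
        R = np.corrcoef(X, rowvar=False) - _model_implied_corr(cal)
        np.fill_diagonal(R, 0.0)
    elif method == "q3":
        if scores is None:
            scores = eap_scores(m, cal)
        theta = scores.theta_eap
        resid = np.empty_like(X)
        for j, item in enumerate(cal.params):
            P = grm_prob_table(item, theta)
            k = np.arange(item.n_categories, dtype=float)[:, None]
            resid[:, j] = X[:, j] - np.sum(k * P, axis=0)
        R = np.corrcoef(resid, rowvar=False)
    else:
        raise ValueError(f"unknown residual method {method!r}")
    iu = np.triu_indices(X.shape[1], k=1)
    vals = R[iu]
    flagged = [
        (cal.item_ids[i], cal.item_ids[j], float(R[i, j]))
        for i, j in zip(*iu)
        if abs(R[i, j]) >= threshold
    ]
    return ResidualCorrelations(
        item_ids=list(cal.item_ids),
        matrix=R,
        third_quartile=float(np.percentile(vals, 75)),
        min_r=float(vals.min()),
        max_r=float(vals.max()),
        flagged_pairs=flagged,
        threshold=threshold,
    )


def fit_indices(m: ResponseMatrix, cal: Calibration) -> FitIndices:
    """Convenience wrapper: M2, baseline, derived indices, and SRMR."""
    target = m2_statistic(m, cal)
    base = independence_baseline(m, cal)
    out = fit_indices_from_m2(target.M2, target.df, m.n_persons, base.M2, base.df)
    out.SRMR = srmr(m, cal)
    return out
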