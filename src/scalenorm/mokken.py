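"""Nonparametric (Mokken-style) scalability and monotonicity checks.

Loevinger's H compares observed item-pair covariances with the maximum
covariance attainable given the item marginals (equivalently, one minus
the ratio of observed to expected-under-independence Guttman errors).
Perfect Guttman data gives H = 1; independent items give H near 0.  Items
with H_i <= 0.3 scale too weakly to support a cumulative-scale reading.

Manifest monotonicity is checked per item against rest-score groups:
persons are grouped by their summed score on the remaining items and each
item-step probability P(X >= k) must be nondecreasing across groups.
Decreases larger than ``minvi`` are recorded as violations with a
criticality score; the conventional reading treats crit < 40 as
negligible, 40-90 as borderline, and > 90 as serious.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .instruments import ResponseMatrix, sum_scores

__all__ = [
    "MokkenReport",
    "MonotonicityViolation",
    "scalability_coefficients",
    "monotonicity_check",
    "default_minsize",
]


@dataclass
class MonotonicityViolation:
    """One observed decrease of an item-step probability across rest groups."""

    item_id: str
    step: int                 # boundary k in P(X >= k)
    group_low: int            # earlier (lower rest-score) group index
    group_high: int
    magnitude: float          # probability drop, > minvi
    z: float                  # drop / pooled binomial standard error


@dataclass
class MokkenReport:
    item_ids: list[str]
    H_i: np.ndarray
    H: float
    violations: list[MonotonicityViolation] = field(default_factory=list)
    crit: dict[str, int] = field(default_factory=dict)
    skipped_items: list[str] = field(default_factory=list)


def _max_covariance(x: np.ndarray, y: np.ndarray) -> float:
    """Largest covariance attainable with the observed marginals.

    Attained by the comonotone coupling: covariance of the two sorted
    vectors (Frechet upper bound for fixed margins).
    """
    return float(np.cov(np.sort(x), np.sort(y), ddof=1)[0, 1])


def scalability_coefficients(m: ResponseMatrix, subscale: Sequence[str]) -> MokkenReport:
    """Loevinger H_i per item and the overall scale H."""
    if len(subscale) < 2:
        raise ValueError("need at least 2 items")
    sub = m.subset_items(list(subscale))
    X = np.asarray(sub.responses, dtype=float)
    p = X.shape[1]
    cov = np.cov(X, rowvar=False, ddof=1)
    skipped = [sub.item_ids[j] for j in range(p) if cov[j, j] <= 0]
    if skipped:
        warnings.warn(
            f"items with zero variance skipped in scalability: {skipped}",
            stacklevel=2,
        )
    covmax = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            covmax[i, j] = covmax[j, i] = _max_covariance(X[:, i], X[:, j])
    H_i = np.full(p, np.nan)
    for i in range(p):
        if sub.item_ids[i] in skipped:
            continue
        ok = [j for j in range(p) if j != i and sub.item_ids[j] not in skipped]
        num = sum(cov[i, j] for j in ok)
        den = sum(covmax[i, j] for j in ok)
        if den > 0:
            H_i[i] = num / den
    iu = [
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if sub.item_ids[i] not in skipped and sub.item_ids[j] not in skipped
    ]
    den = sum(covmax[i, j] for i, j in iu)
    H = float(sum(cov[i, j] for i, j in iu) / den) if den > 0 else float("nan")
    return MokkenReport(item_ids=list(sub.item_ids), H_i=H_i, H=H,
                        skipped_items=skipped)


def default_minsize(n: int) -> int:
    """Rest-score group size heuristic: n/10 (floor 50) for n >= 500, else n/5 (floor 10)."""
    if n >= 500:
        return max(n // 10, 50)
    return max(n // 5, 10)


def _rest_score_groups(rest: np.ndarray, minsize: int) -> list[np.ndarray]:
    """Partition persons into ordered rest-score groups of >= minsize.

    Adjacent rest-score values are merged left-to-right until each group
    reaches ``minsize``; a trailing short group is merged backwards.
    """
    groups: list[np.ndarray] = []
    current: list[int] = []
    for s in np.unique(rest):
        current.extend(np.nonzero(rest == s)[0])
        if len(current) >= minsize:
            groups.append(np.array(current))
            current = []
    if current:
        if groups:
            groups[-1] = np.concatenate([groups[-1], np.array(current)])
        else:
            groups.append(np.array(current))
    return groups


def monotonicity_check(
    m: ResponseMatrix,
    subscale: Sequence[str],
    *,
    minsize: int | None = None,
    minvi: float = 0.03,
) -> tuple[list[MonotonicityViolation], dict[str, int]]:
    """Manifest-monotonicity violations and per-item criticality scores.

    For every item and item step, the step probability is estimated in each
    rest-score group; every ordered group pair whose probability drops by
    more than ``minvi`` is a violation.  The per-item criticality score
    aggregates the violations,

        crit_i = round( 10 * sum_v z_v * d_v / minvi ),

    where d_v is the drop and z_v its pooled binomial z-statistic, so a
    single borderline drop scores ~10-15 while systematic reversals score
    in the hundreds.
    """
    sub = m.subset_items(list(subscale))
    X = np.asarray(sub.responses, dtype=np.int64)
    n, p = X.shape
    if minsize is None:
        minsize = default_minsize(n)
    if n < 2 * minsize:
        raise ValueError(
            f"too few persons ({n}) to form two rest-score groups of {minsize}"
        )
    total = X.sum(axis=1)
    violations: list[MonotonicityViolation] = []
    crit: dict[str, int] = {}
    for j in range(p):
        rest = total - X[:, j]
        groups = _rest_score_groups(rest, minsize)
        K = int(X[:, j].max()) + 1
        score = 0.0
        for k in range(1, K):
            probs = np.array([(X[g, j] >= k).mean() for g in groups])
            sizes = np.array([g.size for g in groups])
            for gl in range(len(groups)):
                for gh in range(gl + 1, len(groups)):
                    drop = probs[gl] - probs[gh]
                    if drop > minvi:
                        pool = (
                            probs[gl] * sizes[gl] + probs[gh] * sizes[gh]
                        ) / (sizes[gl] + sizes[gh])
                        se = np.sqrt(
                            max(pool * (1 - pool), 1e-12)
                            * (1 / sizes[gl] + 1 / sizes[gh])
                        )
                        z = drop / se
                        violations.append(
                            MonotonicityViolation(
                                item_id=sub.item_ids[j],
                                step=k,
                                group_low=gl,
                                group_high=gh,
                                magnitude=float(drop),
                                z=float(z),
                            )
                        )
                        score += max(z, 0.0) * drop / minvi
        crit[sub.item_ids[j]] = int(round(10.0 * score))
    return violations, crit


def mokken_report(
    m: ResponseMatrix,
    subscale: Sequence[str],
    *,
    minsize: int | None = None,
    minvi: float = 0.03,
) -> MokkenReport:
    """Scalability coefficients plus monotonicity violations in one report."""
    rep = scalability_coefficients(m, subscale)
    rep.violations, rep.crit = monotonicity_check(
        m, subscale, minsize=minsize, minvi=minvi
    )
    return rep
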