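"""Internal-consistency estimation: Cronbach's alpha and McDonald's omega.

Alpha is computed from Pearson covariances of the raw integer item scores
(sample covariances, ddof=1).  Omega-total uses the standardized one-factor
solution implied by the IRT calibration (loadings from the normal-ogive
conversion of the discriminations):

    omega_t = (sum lambda)^2 / ((sum lambda)^2 + sum psi).

Rating thresholds follow the evaluation rubric and are strict: a value of
exactly 0.7 is *not* positive ("exceeded 0.7"), 0.8 and 0.9 mark good and
excellent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .instruments import ResponseMatrix
from .irt import fit_grm
from .model_fit import LoadingSet, irt_to_loadings

__all__ = [
    "ReliabilityReport",
    "cronbach_alpha",
    "mcdonald_omega_total",
    "reliability_rating",
    "reliability_report",
]

#: floor applied to uniquenesses in Heywood cases
PSI_EPS = 1e-6


@dataclass
class ReliabilityReport:
    alpha: float
    omega_total: float | None
    rating: str


def cronbach_alpha(m: ResponseMatrix, subscale: Sequence[str]) -> float:
    """Cronbach's alpha: (p/(p-1)) * (1 - sum var_i / var_total)."""
    if len(subscale) < 2:
        raise ValueError("need at least 2 items")
    sub = m.subset_items(list(subscale))
    X = np.asarray(sub.responses, dtype=float)
    total_var = np.var(X.sum(axis=1), ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    p = X.shape[1]
    return float(p / (p - 1) * (1.0 - np.var(X, axis=0, ddof=1).sum() / total_var))


def mcdonald_omega_total(
    m: ResponseMatrix,
    subscale: Sequence[str],
    *,
    loadings: LoadingSet | None = None,
) -> float:
    """Omega-total from a standardized one-factor solution.

    When no :class:`LoadingSet` is supplied, a GRM is calibrated on the
    subscale and its discriminations are converted to loadings.  Heywood
    uniquenesses (psi <= 0) are floored at a small epsilon with a warning.
    """
    if loadings is None:
        cal = fit_grm(m, list(subscale))
        loadings = irt_to_loadings(cal)
    lam = np.asarray(loadings.loadings, dtype=float)
    psi = np.asarray(loadings.uniquenesses, dtype=float)
    if (psi <= 0).any():
        warnings.warn("Heywood case: uniqueness floored at epsilon", stacklevel=2)
        psi = np.maximum(psi, PSI_EPS)
    s = lam.sum()
    return float(s**2 / (s**2 + psi.sum()))


def reliability_rating(alpha: float | None, omega_total: float | None = None) -> str:
    """Rubric rating from the better of alpha and omega-total (strict bounds)."""
    vals = [v for v in (alpha, omega_total) if v is not None]
    if not vals:
        raise ValueError("need alpha or omega_total")
    best = max(vals)
    if best > 0.9:
        return "excellent"
    if best > 0.8:
        return "good"
    if best > 0.7:
        return "positive"
    return "inadequate"


def reliability_report(
    m: ResponseMatrix,
    subscale: Sequence[str],
    *,
    loadings: LoadingSet | None = None,
) -> ReliabilityReport:
    alpha = cronbach_alpha(m, subscale)
    omega = mcdonald_omega_total(m, subscale, loadings=loadings)
    return ReliabilityReport(
        alpha=alpha, omega_total=omega, rating=reliability_rating(alpha, omega)
    )
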