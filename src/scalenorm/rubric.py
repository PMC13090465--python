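"""COSMIN-style evaluation rubric applied to the computed statistics.

Four structural criteria are assessed per subscale, with the operators
taken literally from the rubric:

1. unidimensionality — at least two of {RMSEA <= 0.06 (values in
   (0.06, 0.08] still count but are labelled "acceptable"), SRMR <= 0.08,
   TLI and CFI jointly >= 0.95};
2. local independence — all |residual r| < 0.2 OR third quartile < 0.37;
3. monotonicity — every item H_i > 0.3 AND no violation with crit > 90
   (crit in [40, 90] is annotated acceptable); the "adequate looking
   graphs" escape is a manual override, never automatic;
4. global fit — unidimensionality passed AND every item infit in
   [0.5, 1.5].

Reliability is rated positive/good/excellent above 0.7/0.8/0.9 (strict).
Verdicts are pure functions of the inputs; every fail carries a reason
code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .irt import InfitReport
from .mokken import MokkenReport
from .model_fit import FitIndices, LoadingSet, ResidualCorrelations

__all__ = [
    "CriterionResult",
    "CosminVerdict",
    "evaluate_unidimensionality",
    "evaluate_local_independence",
    "evaluate_monotonicity",
    "evaluate_global_fit",
    "loading_flags",
    "compile_verdict",
]


@dataclass
class CriterionResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)


@dataclass
class CosminVerdict:
    unidimensionality: CriterionResult
    local_independence: CriterionResult
    monotonicity: CriterionResult
    global_fit: CriterionResult
    reliability_rating: str | None
    loading_flags: dict[str, str]
    status: str                      # supported | not_supported | incomplete
    failed_criteria: list[str] = field(default_factory=list)


def evaluate_unidimensionality(f: FitIndices) -> CriterionResult:
    """Two-of-three rule over RMSEA, SRMR, and joint TLI/CFI."""
    met: list[str] = []
    reasons: list[str] = []
    skipped: list[str] = []
    if f.RMSEA is None:
        skipped.append("RMSEA")
    elif f.RMSEA <= 0.06:
        met.append("RMSEA<=0.06")
    elif f.RMSEA <= 0.08:
        met.append("RMSEA<=0.08 (acceptable)")
    else:
        reasons.append(f"RMSEA={f.RMSEA:.3f}>0.08")
    if f.SRMR is None:
        skipped.append("SRMR")
    elif f.SRMR <= 0.08:
        met.append("SRMR<=0.08")
    else:
        reasons.append(f"SRMR={f.SRMR:.3f}>0.08")
    if f.TLI is None or f.CFI is None:
        skipped.append("TLI/CFI")
    elif f.TLI >= 0.95 and f.CFI >= 0.95:
        met.append("TLI/CFI>=0.95")
    else:
        reasons.append(f"TLI={f.TLI:.3f} or CFI={f.CFI:.3f} below 0.95")
    return CriterionResult(
        passed=len(met) >= 2,
        reasons=reasons if len(met) < 2 else [],
        evidence={"met": met, "skipped": skipped},
    )


def evaluate_local_independence(r: ResidualCorrelations) -> CriterionResult:
    all_small = max(abs(r.min_r), abs(r.max_r)) < 0.2
    q3_ok = r.third_quartile < 0.37
    passed = all_small or q3_ok
    reasons = []
    if not passed:
        reasons.append(
            f"max |residual r|={max(abs(r.min_r), abs(r.max_r)):.3f}>=0.2 "
            f"and Q3={r.third_quartile:.3f}>=0.37"
        )
    return CriterionResult(
        passed=passed,
        reasons=reasons,
        evidence={
            "Q3": r.third_quartile,
            "min_r": r.min_r,
            "max_r": r.max_r,
            "flagged_pairs": r.flagged_pairs,
        },
    )


def evaluate_monotonicity(
    k: MokkenReport, *, graph_override: Sequence[str] = ()
) -> CriterionResult:
    """All H_i > 0.3 and no violation with crit > 90.

    ``graph_override`` lists item ids a human reviewer has judged adequate
    from the item-step plots despite H_i <= 0.3; the waiver is recorded in
    the evidence and is never applied automatically.
    """
    weak = [
        iid
        for iid, h in zip(k.item_ids, k.H_i)
        if not np.isnan(h) and h <= 0.3 and iid not in set(graph_override)
    ]
    serious = [iid for iid, c in k.crit.items() if c > 90]
    acceptable = [iid for iid, c in k.crit.items() if 40 <= c <= 90]
    reasons = []
    if weak:
        reasons.append(f"{len(weak)} item(s) with scalability H_i <= 0.3: {weak}")
    if serious:
        reasons.append(f"violations with crit > 90 on item(s): {serious}")
    return CriterionResult(
        passed=not weak and not serious,
        reasons=reasons,
        evidence={
            "n_weak_items": len(weak),
            "weak_items": weak,
            "n_violations": len(k.violations),
            "crit": dict(k.crit),
            "acceptable_band_items": acceptable,
            "graph_override": list(graph_override),
        },
    )


def evaluate_global_fit(
    uni: CriterionResult, infits: InfitReport
) -> CriterionResult:
    out_of_range = [
        iid
        for iid, v in zip(infits.item_ids, infits.item_infit)
        if not (0.5 <= v <= 1.5)
    ]
    reasons = []
    if not uni.passed:
        reasons.append("unidimensionality not met")
    if out_of_range:
        reasons.append(f"item infit outside [0.5, 1.5]: {out_of_range}")
    return CriterionResult(
        passed=uni.passed and not out_of_range,
        reasons=reasons,
        evidence={
            "infit_min": float(np.min(infits.item_infit)),
            "infit_max": float(np.max(infits.item_infit)),
            "out_of_range": out_of_range,
        },
    )


def loading_flags(l: LoadingSet) -> dict[str, str]:
    """below (<=0.3), positive (0.3, 0.5], very_positive (>0.5) per item."""
    out = {}
    for iid, lam in zip(l.item_ids, l.loadings):
        if lam > 0.5:
            out[iid] = "very_positive"
        elif lam > 0.3:
            out[iid] = "positive"
        else:
            out[iid] = "below"
    return out


def compile_verdict(
    *,
    fit: FitIndices | None,
    residuals: ResidualCorrelations | None,
    mokken: MokkenReport | None,
    infits: InfitReport | None,
    reliability_rating: str | None,
    loadings: LoadingSet | None,
    require_reliability: bool = True,
) -> CosminVerdict:
    """Combine the per-criterion evaluations into one structured verdict.

    Status is "supported" iff all four structural criteria pass and (when
    ``require_reliability``) the reliability rating is at least positive;
    any missing component yields "incomplete", never a silent pass.
    """
    if fit is None or residuals is None or mokken is None or infits is None:
        missing = [
            name
            for name, v in (
                ("fit", fit),
                ("residuals", residuals),
                ("mokken", mokken),
                ("infits", infits),
            )
            if v is None
        ]
        absent = CriterionResult(passed=False, reasons=["not computed"])
        return CosminVerdict(
            unidimensionality=absent,
            local_independence=absent,
            monotonicity=absent,
            global_fit=absent,
            reliability_rating=reliability_rating,
            loading_flags=loading_flags(loadings) if loadings else {},
            status="incomplete",
            failed_criteria=[f"missing:{m}" for m in missing],
        )
    uni = evaluate_unidimensionality(fit)
    li = evaluate_local_independence(residuals)
    mono = evaluate_monotonicity(mokken)
    gfit = evaluate_global_fit(uni, infits)
    failed = [
        name
        for name, res in (
            ("unidimensionality", uni),
            ("local_independence", li),
            ("monotonicity", mono),
            ("global_fit", gfit),
        )
        if not res.passed
    ]
    reliab_ok = (not require_reliability) or (
        reliability_rating in ("positive", "good", "excellent")
    )
    if not reliab_ok:
        failed.append("reliability")
    return CosminVerdict(
        unidimensionality=uni,
        local_independence=li,
        monotonicity=mono,
        global_fit=gfit,
        reliability_rating=reliability_rating,
        loading_flags=loading_flags(loadings) if loadings else {},
        status="supported" if not failed else "not_supported",
        failed_criteria=failed,
    )
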