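"""Normative reference tables: crude score -> Z, T, percentile, severity band.

Within each norm group (age band x gender by default), trait scores are
standardized to Z and to the T metric (mean 50, SD 10 in the reference
group).  Severity bands follow the PROMIS interpretive convention:
minimal T < 55, mild 55-59, moderate 60-69, severe T >= 70.  These are
interpretive conventions, not clinical cutoffs.

Crude (summed) scores are linked to the trait metric through the
model-based summed-score posterior E[theta | S = s] (Lord-Wingersky
recursion), which is defined for every attainable sum including those not
observed in the sample; percentiles are mid-probability empirical
percentiles of the group's observed sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .instruments import ResponseMatrix, sum_scores
from .irt import Calibration, PersonScores, eap_scores, summed_score_posterior

__all__ = [
    "SeverityBandSpec",
    "NormRow",
    "NormTable",
    "standardize_scores",
    "promis_band",
    "band_rescale",
    "link_summed_scores",
    "build_norm_table",
]


@dataclass(frozen=True)
class SeverityBandSpec:
    """PROMIS-style T-score severity partition with display colors."""

    minimal_upper: float = 55.0      # minimal: T < 55
    mild_upper: float = 60.0         # mild:    55 <= T < 60  (printed 55-59)
    moderate_upper: float = 70.0     # moderate:60 <= T < 70  (printed 60-69)
    display_floor: float = 20.0
    display_ceiling: float = 80.0
    colors: dict = field(
        default_factory=lambda: {
            "minimal": "#9fd89f",
            "mild": "#ffe08a",
            "moderate": "#f5a55f",
            "severe": "#e06666",
        }
    )


def promis_band(T: float, spec: SeverityBandSpec | None = None) -> str:
    """Unique severity band for a (raw) T-score."""
    spec = spec or SeverityBandSpec()
    if not np.isfinite(T):
        raise ValueError("T must be finite")
    if T < spec.minimal_upper:
        return "minimal"
    if T < spec.mild_upper:
        return "mild"
    if T < spec.moderate_upper:
        return "moderate"
    return "severe"


def band_rescale(T: float, spec: SeverityBandSpec | None = None) -> float:
    """Display T: truncated into its band's nominal range.

    Band membership is decided on the raw T and never changed by the
    rescaling; within each band the map is monotone with unit slope, and
    values beyond the band's display endpoints are truncated (minimal
    scores floor at ``display_floor``, severe scores cap at
    ``display_ceiling``).  Raw T values are retained in machine output.
    """
    spec = spec or SeverityBandSpec()
    band = promis_band(T, spec)
    lo, hi = {
        "minimal": (spec.display_floor, np.nextafter(spec.minimal_upper, -np.inf)),
        "mild": (spec.minimal_upper, np.nextafter(spec.mild_upper, -np.inf)),
        "moderate": (spec.mild_upper, np.nextafter(spec.moderate_upper, -np.inf)),
        "severe": (spec.moderate_upper, spec.display_ceiling),
    }[band]
    return float(np.clip(T, lo, hi))


def standardize_scores(
    theta: np.ndarray,
    groups: Sequence[tuple[str, str]],
    *,
    min_group_size: int = 30,
) -> pd.DataFrame:
    """Per-person Z and T within each (age_group, gender) norm group."""
    theta = np.asarray(theta, dtype=float)
    df = pd.DataFrame(
        {
            "age_group": [g[0] for g in groups],
            "gender": [g[1] for g in groups],
            "theta": theta,
        }
    )
    df["Z"] = np.nan
    for key, grp in df.groupby(["age_group", "gender"], sort=False):
        if len(grp) < 2:
            raise ValueError(f"group {key}: needs >= 2 persons (sd undefined)")
        sd = grp["theta"].std(ddof=1)
        if sd <= 0:
            raise ValueError(f"group {key}: zero trait variance")
        if len(grp) < min_group_size:
            warnings.warn(
                f"group {key}: only {len(grp)} persons; norms unstable",
                stacklevel=2,
            )
        df.loc[grp.index, "Z"] = (grp["theta"] - grp["theta"].mean()) / sd
    df["T"] = 50 + 10 * df["Z"]
    return df.set_index(["age_group", "gender"])


@dataclass
class NormRow:
    group: tuple[str, str]
    crude_score: int
    theta: float
    Z: float
    T: float
    T_display: float
    percentile: float
    band: str
    unstable: bool = False


@dataclass
class NormTable:
    instrument: str
    subscale: str
    rows: list[NormRow]
    band_spec: SeverityBandSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "instrument": self.instrument,
                "subscale": self.subscale,
                "age_group": r.group[0],
                "gender": r.group[1],
                "crude": r.crude_score,
                "theta": r.theta,
                "Z": r.Z,
                "T": r.T,
                "T_display": r.T_display,
                "percentile": r.percentile,
                "band": r.band,
                "unstable": r.unstable,
            }
            for r in self.rows
        )


def link_summed_scores(
    cal: Calibration,
    group_theta: np.ndarray,
    group_sums: np.ndarray,
    *,
    band_spec: SeverityBandSpec | None = None,
    method: str = "model",
) -> pd.DataFrame:
    """Crude -> (theta, Z, T, percentile, band) for one norm group.

    With ``method="model"`` (default), theta(s) = E[theta | S = s] from the
    pooled calibration — defined for every attainable sum, observed or not.
    ``method="empirical"`` instead averages the group's observed trait
    scores at each observed sum, for comparison.  Z and T are taken against
    the group's trait distribution; the percentile is the mid-probability
    empirical percentile 100*(P(S<s) + P(S=s)/2) of the group's observed
    sums.  Unattainable (or, empirically, unobserved) sums are excluded.
    """
    band_spec = band_spec or SeverityBandSpec()
    mu = float(np.mean(group_theta))
    sd = float(np.std(group_theta, ddof=1))
    if sd <= 0:
        raise ValueError("zero trait variance in norm group")
    group_sums = np.asarray(group_sums)
    n = group_sums.size
    if method == "model":
        ssp = summed_score_posterior(cal)
        pairs = zip(ssp.scores, ssp.probs, ssp.theta_given_s)
    elif method == "empirical":
        group_theta = np.asarray(group_theta, dtype=float)
        uniq = np.unique(group_sums)
        pairs = (
            (s, (group_sums == s).mean(), group_theta[group_sums == s].mean())
            for s in uniq
        )
    else:
        raise ValueError(f"unknown linking method {method!r}")
    rows = []
    for s, prob, th in pairs:
        if prob <= 0 or not np.isfinite(th):
            continue
        z = (th - mu) / sd
        T = 50 + 10 * z
        pct = 100.0 * ((group_sums < s).sum() + 0.5 * (group_sums == s).sum()) / n
        rows.append(
            {
                "crude": int(s),
                "theta": float(th),
                "Z": float(z),
                "T": float(T),
                "T_display": band_rescale(T, band_spec),
                "percentile": float(pct),
                "band": promis_band(T, band_spec),
            }
        )
    return pd.DataFrame(rows)


def build_norm_table(
    instrument: str,
    subscale: str,
    cal: Calibration,
    cohort: ResponseMatrix,
    *,
    band_spec: SeverityBandSpec | None = None,
    min_group_size: int = 30,
    pool_gender_below_min: bool = True,
) -> NormTable:
    """Complete per-group norm table for one calibrated subscale.

    Norm groups default to age_group x gender; when a cell falls below
    ``min_group_size`` and pooling is enabled, genders are pooled within
    the age band (logged via warning), otherwise the rows are flagged
    unstable.
    """
    band_spec = band_spec or SeverityBandSpec()
    scores = eap_scores(cohort, cal)
    sums = sum_scores(cohort, cal.item_ids)
    groups = pd.DataFrame(
        {
            "age_group": cohort.age_group,
            "gender": cohort.gender,
            "theta": scores.theta_eap,
            "sum": sums,
        }
    )
    rows: list[NormRow] = []
    for age, age_df in groups.groupby("age_group", sort=False):
        cells: list[tuple[str, pd.DataFrame]] = [
            (g, gdf) for g, gdf in age_df.groupby("gender", sort=False)
        ]
        if pool_gender_below_min and any(len(gdf) < min_group_size for _, gdf in cells):
            warnings.warn(
                f"age group {age}: a gender cell is below {min_group_size}; "
                "pooling genders",
                stacklevel=2,
            )
            cells = [("all", age_df)]
        for gender, gdf in cells:
            unstable = len(gdf) < min_group_size
            linked = link_summed_scores(
                cal,
                gdf["theta"].to_numpy(),
                gdf["sum"].to_numpy(),
                band_spec=band_spec,
            )
            for rec in linked.itertuples(index=False):
                rows.append(
                    NormRow(
                        group=(str(age), str(gender)),
                        crude_score=int(rec.crude),
                        theta=float(rec.theta),
                        Z=float(rec.Z),
                        T=float(rec.T),
                        T_display=float(rec.T_display),
                        percentile=float(rec.percentile),
                        band=str(rec.band),
                        unstable=unstable,
                    )
                )
    return NormTable(
        instrument=instrument, subscale=subscale, rows=rows, band_spec=band_spec
    )
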