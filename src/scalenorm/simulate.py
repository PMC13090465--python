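"""Synthetic cohorts with the statistical structure the pipeline assumes.

Responses are drawn from a graded response model: each stratum (age band x
gender) gets a standard-normal latent trait, optionally mean-shifted, and
every item response is sampled from its GRM category distribution at the
person's trait value.  There is no item-level missingness, matching the
survey data the analysis targets.

Bundled presets emulate the study cohorts: sample sizes and age/gender
strata follow the survey margins (e.g. 1,356 caregivers for the school-age
PSC-17; 137 adolescents for the self-report CATS-2), discriminations fall
in [0.8, 2.5] and thresholds in [-2.5, 2.5] so that fitted loadings land in
the realistic 0.3-0.95 range.  The autism-screener presets deliberately
include weakly discriminating items to reproduce the known failure mode of
those instruments in community samples.

A single root seed expands into independent substreams (one for the trait
vector, one per item), so adding items to a design does not perturb draws
made earlier in the stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .instruments import InstrumentSpec, ResponseMatrix, load_bundled_spec
from .irt import GRMItemParams

__all__ = [
    "SimulationDesign",
    "simulate_theta",
    "simulate_responses",
    "simulate_cohort",
    "make_fixture_cohort",
    "random_item_params",
    "PRESETS",
]

Stratum = tuple[str, str]  # (age_group, gender)


@dataclass
class SimulationDesign:
    """Cohort layout and generating parameters for one latent dimension."""

    n_per_stratum: Mapping[Stratum, int]
    item_params: list[GRMItemParams]
    trait_mean_shift: Mapping[Stratum, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for stratum, n in self.n_per_stratum.items():
            if n < 0:
                raise ValueError(f"stratum {stratum}: negative count")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_stratum.values())


def simulate_theta(design: SimulationDesign) -> tuple[np.ndarray, list[str], list[str]]:
    """Draw the latent trait per person: N(shift_stratum, 1) within stratum.

    Returns the trait vector plus parallel age-group and gender labels,
    ordered stratum by stratum (dict order), reproducible under the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(1)[0])
    theta, ages, genders = [], [], []
    for (age, gender), n in design.n_per_stratum.items():
        shift = design.trait_mean_shift.get((age, gender), 0.0)
        theta.append(rng.standard_normal(n) + shift)
        ages.extend([age] * n)
        genders.extend([gender] * n)
    return np.concatenate(theta) if theta else np.empty(0), ages, genders


def simulate_responses(
    theta: np.ndarray,
    params: Sequence[GRMItemParams],
    seed: int,
    *,
    age_group: Sequence[str] | None = None,
    gender: Sequence[str] | None = None,
) -> ResponseMatrix:
    """Sample GRM responses for every person/item; no missing cells.

    A single uniform draw per cell is compared against the item's boundary
    curves, so responses are monotonically coupled to the latent trait.
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(params) + 1)
    X = np.empty((n, len(params)), dtype=np.int64)
    for j, item in enumerate(params):
        b = np.asarray(item.b)
        if b.size >= 2 and not np.all(np.diff(b) > 0):
            raise ValueError(f"item {item.item_id}: unordered thresholds")
        rng = np.random.default_rng(streams[j + 1])
        u = rng.random(n)
        pstar = 1.0 / (1.0 + np.exp(-item.a * (theta[:, None] - b[None, :])))
        X[:, j] = (u[:, None] < pstar).sum(axis=1)
    return ResponseMatrix(
        person_ids=[f"p{i:05d}" for i in range(n)],
        item_ids=[it.item_id for it in params],
        responses=X,
        age_group=list(age_group) if age_group is not None else ["unknown"] * n,
        gender=list(gender) if gender is not None else ["unknown"] * n,
    ).validate()


def simulate_cohort(design: SimulationDesign) -> tuple[ResponseMatrix, np.ndarray]:
    """Trait draw plus response draw in one call; returns (matrix, theta)."""
    theta, ages, genders = simulate_theta(design)
    m = simulate_responses(
        theta, design.item_params, design.seed + 1, age_group=ages, gender=genders
    )
    return m, theta


def random_item_params(
    rng: np.random.Generator,
    item_ids: Sequence[str],
    n_categories: int,
    *,
    a_range: tuple[float, float] = (0.8, 2.5),
    b1_range: tuple[float, float] = (-2.5, 0.5),
    step_range: tuple[float, float] = (0.6, 1.4),
) -> list[GRMItemParams]:
    """Draw well-conditioned GRM item parameters in documented ranges."""
    out = []
    for iid in item_ids:
        a = float(rng.uniform(*a_range))
        b1 = float(rng.uniform(*b1_range))
        steps = rng.uniform(*step_range, size=n_categories - 2)
        b = b1 + np.concatenate([[0.0], np.cumsum(steps)])
        out.append(GRMItemParams(item_id=str(iid), a=a, b=tuple(b)))
    return out


# ---------------------------------------------------------------------------
# presets


def _split_strata(counts: Mapping[str, int], female_share: float) -> dict[Stratum, int]:
    out: dict[Stratum, int] = {}
    for age, n in counts.items():
        nf = int(round(n * female_share))
        out[(age, "female")] = nf
        out[(age, "male")] = n - nf
    return out


#: preset name -> (instrument, strata counts, default seed, weak-item ids)
PRESETS: dict[str, dict] = {
    "psc17-like": {
        "instrument": "psc17",
        "strata": {"6-9": 416, "10-13": 415, "14-18": 525},
        "female_share": 0.47,
        "seed": 20220917,
        "weak_items": (),
        # reproduces the scalability/reliability band observed for the
        # well-behaved school-age instruments (H_i ~ 0.4-0.6)
        "a_range": (1.3, 2.5),
    },
    "rcads25-like": {
        "instrument": "rcads25",
        "strata": {"6-9": 143, "10-13": 119, "14-18": 190},
        "female_share": 0.46,
        "seed": 20220925,
        "weak_items": (),
        "a_range": (1.3, 2.5),
    },
    "snap4-like": {
        "instrument": "snap4",
        "strata": {"6-9": 143, "10-13": 119, "14-18": 190},
        "female_share": 0.46,
        "seed": 20220926,
        "weak_items": (),
        "a_range": (1.3, 2.5),
    },
    "mchat-like": {
        "instrument": "mchat",
        "strata": {"toddler": 200},
        "female_share": 0.50,
        "seed": 20220920,
        # eight weakly scaling items, mirroring the community-sample failure
        "weak_items": ("1", "2", "3", "5", "12", "14", "17", "19"),
        "a_range": (1.6, 2.8),
    },
    "cast-like": {
        "instrument": "cast",
        "strata": {"under-6": 200},
        "female_share": 0.48,
        "seed": 20220928,
        # most social-contact items discriminate poorly in community samples
        "weak_items": ("1", "2", "5", "8", "10", "11", "13", "16", "21",
                        "23", "24", "27", "31", "35"),
    },
    "cats2-self-like": {
        "instrument": "cats2",
        "strata": {"6-9": 19, "10-13": 52, "14-18": 66},
        "female_share": 0.45,
        "seed": 20220902,
        "weak_items": (),
        "a_range": (1.3, 2.5),
    },
}


def make_fixture_cohort(
    preset: str, seed: int | None = None
) -> tuple[ResponseMatrix, dict]:
    """Generate a named fixture cohort and its generating-parameter record.

    The truth record maps each subscale to its generating
    :class:`GRMItemParams` so downstream recovery tests can compare fitted
    parameters against the values that produced the data.
    """
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    seed = cfg["seed"] if seed is None else seed
    spec: InstrumentSpec = load_bundled_spec(cfg["instrument"])
    strata = _split_strata(cfg["strata"], cfg["female_share"])
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])

    truth: dict = {"preset": preset, "instrument": spec.name, "seed": seed,
                   "subscales": {}}
    blocks: list[ResponseMatrix] = []
    ages = genders = None
    for si, (sub_name, members) in enumerate(spec.subscales.items()):
        k = spec.n_categories(members[0])
        params = random_item_params(
            rng, members, k, a_range=cfg.get("a_range", (0.8, 2.5))
        )
        weak = [
            GRMItemParams(
                item_id=p.item_id,
                a=float(rng.uniform(0.2, 0.4)),
                b=tuple(np.asarray(p.b) + rng.uniform(-1.0, 2.5)),
            )
            if p.item_id in cfg["weak_items"]
            else p
            for p in params
        ]
        design = SimulationDesign(
            n_per_stratum=strata, item_params=weak, seed=seed + 101 * si
        )
        m, theta = simulate_cohort(design)
        ages, genders = m.age_group, m.gender
        truth["subscales"][sub_name] = {
            "item_params": weak,
            "theta": theta,
        }
        blocks.append(m)

    # assemble instrument-wide matrix in spec item order
    col: dict[str, np.ndarray] = {}
    for block in blocks:
        for j, iid in enumerate(block.item_ids):
            col[iid] = block.responses[:, j]
    X = np.column_stack([col[iid] for iid in spec.item_ids if iid in col])
    item_ids = [iid for iid in spec.item_ids if iid in col]
    n = X.shape[0]
    m_all = ResponseMatrix(
        person_ids=[f"p{i:05d}" for i in range(n)],
        item_ids=item_ids,
        responses=X,
        age_group=list(ages),
        gender=list(genders),
    ).validate()
    return m_all, truth
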