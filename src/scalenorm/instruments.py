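"""Instrument definitions and ordinal response-data I/O.

An :class:`InstrumentSpec` describes a screening questionnaire: its items,
the number of ordered response categories per item, and the partition of
items into subscales that are calibrated one at a time downstream.  Six
specs are bundled (PSC-17, RCADS-25, SNAP-IV, MCHAT-R/F, CAST, CATS-2);
user-supplied YAML or JSON files with the same schema load the same way.

Responses are 0-based integer category codes: an item with K categories
admits values 0..K-1.  Sources coded 1..K must be shifted at ingest with
``origin=1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ItemDef",
    "InstrumentSpec",
    "ResponseMatrix",
    "SpecFormatError",
    "SpecValidationError",
    "ResponseDataError",
    "load_instrument_spec",
    "bundled_instruments",
    "load_bundled_spec",
    "read_responses",
    "write_responses",
    "sum_scores",
]

#: covariate columns recognised in response files
COVARIATE_COLUMNS = ("person_id", "age_group", "gender")

AGE_GROUPS = ("toddler", "under-6", "6-9", "10-13", "14-18")


class SpecFormatError(ValueError):
    """Raised when an instrument spec file cannot be parsed."""


class SpecValidationError(ValueError):
    """Raised when a parsed spec violates structural invariants."""


class ResponseDataError(ValueError):
    """Raised when a response file violates the instrument's constraints."""


@dataclass(frozen=True)
class ItemDef:
    """One questionnaire item: an id and its number of ordered categories."""

    item_id: str
    n_categories: int

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise SpecValidationError(
                f"item {self.item_id!r}: n_categories must be >= 2, "
                f"got {self.n_categories}"
            )


@dataclass(frozen=True)
class InstrumentSpec:
    """Structure of one instrument: items, categories, subscale partition."""

    name: str
    rater: str
    age_range: tuple[float, float]
    items: tuple[ItemDef, ...]
    subscales: Mapping[str, tuple[str, ...]]
    title: str = ""

    def __post_init__(self) -> None:
        if self.rater not in ("caregiver", "self"):
            raise SpecValidationError(
                f"{self.name}: rater must be 'caregiver' or 'self', got {self.rater!r}"
            )
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise SpecValidationError(f"{self.name}: duplicate item ids")
        known = set(ids)
        for sub, members in self.subscales.items():
            if len(members) < 2:
                raise SpecValidationError(
                    f"{self.name}: subscale {sub!r} has fewer than 2 items"
                )
            if len(set(members)) != len(members):
                raise SpecValidationError(
                    f"{self.name}: subscale {sub!r} repeats an item"
                )
            unknown = [m for m in members if m not in known]
            if unknown:
                raise SpecValidationError(
                    f"{self.name}: subscale {sub!r} references unknown item(s) "
                    f"{unknown}"
                )

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def item(self, item_id: str) -> ItemDef:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def n_categories(self, item_id: str) -> int:
        return self.item(item_id).n_categories


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with grouping covariates.

    Invariants (enforced by :meth:`validate`): every cell is an integer in
    ``[0, K_j - 1]`` for its item, there are no missing cells, and the
    covariate vectors have one entry per person.
    """

    person_ids: list[str]
    item_ids: list[str]
    responses: np.ndarray
    age_group: list[str]
    gender: list[str]

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def validate(self, spec: InstrumentSpec | None = None) -> "ResponseMatrix":
        r = self.responses
        if r.ndim != 2:
            raise ResponseDataError("responses must be a 2-D matrix")
        n, p = r.shape
        if n < 1:
            raise ResponseDataError("need at least one person")
        if p != len(self.item_ids):
            raise ResponseDataError("item_ids length does not match matrix width")
        for vec, name in (
            (self.person_ids, "person_ids"),
            (self.age_group, "age_group"),
            (self.gender, "gender"),
        ):
            if len(vec) != n:
                raise ResponseDataError(f"{name} length does not match n_persons")
        if not np.issubdtype(r.dtype, np.integer):
            if np.isnan(r.astype(float)).any():
                raise ResponseDataError("missing cells present")
            if not np.array_equal(r, np.round(r)):
                raise ResponseDataError("non-integer response values")
            self.responses = r = r.astype(np.int64)
        if (r < 0).any():
            i, j = np.argwhere(r < 0)[0]
            raise ResponseDataError(
                f"negative response at row {i}, item {self.item_ids[j]}"
            )
        if spec is not None:
            for j, iid in enumerate(self.item_ids):
                k = spec.n_categories(iid)
                bad = np.nonzero(r[:, j] > k - 1)[0]
                if bad.size:
                    raise ResponseDataError(
                        f"response {r[bad[0], j]} out of range [0, {k - 1}] at "
                        f"row {bad[0]}, item {iid}"
                    )
        return self

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(
            person_ids=list(self.person_ids),
            item_ids=list(item_ids),
            responses=self.responses[:, idx].copy(),
            age_group=list(self.age_group),
            gender=list(self.gender),
        )

    def subset_persons(self, mask: np.ndarray) -> "ResponseMatrix":
        mask = np.asarray(mask)
        keep = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return ResponseMatrix(
            person_ids=[self.person_ids[i] for i in keep],
            item_ids=list(self.item_ids),
            responses=self.responses[keep].copy(),
            age_group=[self.age_group[i] for i in keep],
            gender=[self.gender[i] for i in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_ids)
        df.insert(0, "person_id", self.person_ids)
        df["age_group"] = self.age_group
        df["gender"] = self.gender
        return df


# ---------------------------------------------------------------------------
# spec files


def _parse_spec_dict(raw: dict, source: str) -> InstrumentSpec:
    for key in ("name", "rater", "age_range", "items", "subscales"):
        if key not in raw:
            raise SpecFormatError(f"{source}: missing required field {key!r}")
    default_k = raw.get("n_categories")
    items = []
    for entry in raw["items"]:
        if isinstance(entry, Mapping):
            if "id" not in entry:
                raise SpecFormatError(f"{source}: item entry without 'id'")
            k = entry.get("n_categories", default_k)
            iid = str(entry["id"])
        else:
            iid, k = str(entry), default_k
        if k is None:
            raise SpecFormatError(
                f"{source}: item {iid!r} has no n_categories and no default set"
            )
        try:
            items.append(ItemDef(item_id=iid, n_categories=int(k)))
        except (TypeError, ValueError) as exc:
            raise SpecFormatError(f"{source}: item {iid!r}: {exc}") from exc
    ar = raw["age_range"]
    if not (isinstance(ar, Sequence) and len(ar) == 2):
        raise SpecFormatError(f"{source}: age_range must be [min, max]")
    subs = {
        str(name): tuple(str(m) for m in members)
        for name, members in raw["subscales"].items()
    }
    return InstrumentSpec(
        name=str(raw["name"]),
        rater=str(raw["rater"]),
        age_range=(float(ar[0]), float(ar[1])),
        items=tuple(items),
        subscales=subs,
        title=str(raw.get("title", "")),
    )


def load_instrument_spec(path: str | Path) -> InstrumentSpec:
    """Load and validate an instrument spec from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise SpecFormatError(f"{path}: cannot parse: {exc}") from exc
    if not isinstance(raw, dict):
        raise SpecFormatError(f"{path}: top level must be a mapping")
    return _parse_spec_dict(raw, str(path))


def bundled_instruments() -> list[str]:
    """Names of the instrument specs shipped with the package."""
    pkg = resources.files("scalenorm") / "data" / "instruments"
    return sorted(p.name[: -len(".yaml")] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_bundled_spec(name: str) -> InstrumentSpec:
    """Load one of the bundled instrument specs by short name (e.g. ``psc17``)."""
    pkg = resources.files("scalenorm") / "data" / "instruments" / f"{name}.yaml"
    try:
        text = pkg.read_text(encoding="utf-8")
    except FileNotFoundError as exc:
        raise KeyError(
            f"no bundled instrument {name!r}; available: {bundled_instruments()}"
        ) from exc
    raw = yaml.safe_load(text)
    return _parse_spec_dict(raw, f"bundled:{name}")


# ---------------------------------------------------------------------------
# response I/O


def read_responses(
    path: str | Path,
    spec: InstrumentSpec,
    *,
    missing: str = "error",
    origin: int = 0,
    logger=None,
) -> ResponseMatrix:
    """Read a delimited response file and validate it against ``spec``.

    Parameters
    ----------
    missing:
        ``"error"`` (default) rejects any blank cell; ``"listwise"`` drops
        persons with any blank cell and logs the count.
    origin:
        Integer subtracted from every response at ingest, for sources coded
        e.g. 1..K instead of 0..K-1.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"person_id": str})
    missing_items = [i for i in spec.item_ids if i not in df.columns]
    if missing_items:
        raise ResponseDataError(f"{path}: missing item columns {missing_items}")
    item_block = df[spec.item_ids]
    na_rows = item_block.isna().any(axis=1)
    if na_rows.any():
        if missing == "listwise":
            n_drop = int(na_rows.sum())
            if logger is not None:
                logger.warning("listwise deletion dropped %d person(s)", n_drop)
            df = df.loc[~na_rows].reset_index(drop=True)
            item_block = df[spec.item_ids]
        else:
            row = int(np.nonzero(na_rows.to_numpy())[0][0])
            col = item_block.columns[item_block.iloc[row].isna()][0]
            raise ResponseDataError(
                f"{path}: missing cell at row {row}, item {col} "
                "(pass missing='listwise' to drop such persons)"
            )
    values = item_block.to_numpy()
    if not np.array_equal(values, np.round(values.astype(float))):
        raise ResponseDataError(f"{path}: non-integer response values")
    values = values.astype(np.int64) - int(origin)
    person_ids = (
        df["person_id"].astype(str).tolist()
        if "person_id" in df.columns
        else [str(i) for i in range(len(df))]
    )
    age_group = (
        df["age_group"].astype(str).tolist()
        if "age_group" in df.columns
        else ["unknown"] * len(df)
    )
    gender = (
        df["gender"].astype(str).tolist() if "gender" in df.columns else ["unknown"] * len(df)
    )
    m = ResponseMatrix(
        person_ids=person_ids,
        item_ids=list(spec.item_ids),
        responses=values,
        age_group=age_group,
        gender=gender,
    )
    try:
        return m.validate(spec)
    except ResponseDataError as exc:
        raise ResponseDataError(f"{path}: {exc}") from exc


def write_responses(m: ResponseMatrix, path: str | Path) -> None:
    """Write a ResponseMatrix as CSV/TSV; inverse of :func:`read_responses`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    m.to_frame().to_csv(path, sep=sep, index=False)


def sum_scores(m: ResponseMatrix, subscale: Sequence[str]) -> np.ndarray:
    """Per-person crude (summed) score over the given subscale items."""
    if len(subscale) == 0:
        raise ValueError("empty subscale")
    idx = []
    for iid in subscale:
        if iid not in m.item_ids:
            raise KeyError(f"item {iid!r} not in response matrix")
        idx.append(m.item_ids.index(iid))
    return m.responses[:, idx].sum(axis=1)
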