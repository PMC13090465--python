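import numpy as np
import pytest
import yaml

from scalenorm.instruments import (
    InstrumentSpec,
    ItemDef,
    ResponseDataError,
    ResponseMatrix,
    SpecFormatError,
    SpecValidationError,
    bundled_instruments,
    load_bundled_spec,
    load_instrument_spec,
    read_responses,
    sum_scores,
    write_responses,
)


def test_all_bundled_specs_load():
    names = bundled_instruments()
    assert set(names) == {"psc17", "rcads25", "snap4", "mchat", "cast", "cats2"}
    for name in names:
        spec = load_bundled_spec(name)
        assert len(spec.items) >= 17 or name in ("mchat", "cats2", "cast")


@pytest.mark.parametrize(
    "name, n_items, sizes",
    [
        ("psc17", 17, {"externalizing": 7, "internalizing": 5, "attention": 5}),
        ("rcads25", 25, {"anxiety": 15, "depression": 10}),
        ("snap4", 26, {"inattention": 9, "hyperactivity": 5, "impulsivity": 4,
                       "oppositional": 8}),
        ("mchat", 20, {"unidimensional": 20}),
        ("cast", 28, {"social_contact": 16, "inflexible_repetitive": 12}),
        ("cats2", 20, {"unidimensional": 20}),
    ],
)
def test_bundled_structure(name, n_items, sizes):
    spec = load_bundled_spec(name)
    assert len(spec.items) == n_items
    assert {k: len(v) for k, v in spec.subscales.items()} == sizes


def test_psc17_subscale_membership():
    spec = load_bundled_spec("psc17")
    assert spec.subscales["externalizing"] == tuple("4 5 8 10 12 14 16".split())
    assert spec.subscales["internalizing"] == tuple("2 6 9 11 15".split())
    assert spec.subscales["attention"] == tuple("1 3 7 13 17".split())
    assert all(it.n_categories == 3 for it in spec.items)


def test_binary_and_four_category_codings():
    assert all(it.n_categories == 2 for it in load_bundled_spec("mchat").items)
    assert all(it.n_categories == 2 for it in load_bundled_spec("cast").items)
    assert all(it.n_categories == 4 for it in load_bundled_spec("rcads25").items)


def test_subscale_referencing_unknown_item_rejected():
    items = tuple(ItemDef(str(i), 3) for i in range(1, 6))
    with pytest.raises(SpecValidationError, match="99"):
        InstrumentSpec(
            name="bad", rater="caregiver", age_range=(6, 18), items=items,
            subscales={"s": ("1", "2", "99")},
        )


def test_single_item_subscale_rejected():
    items = tuple(ItemDef(str(i), 3) for i in range(1, 6))
    with pytest.raises(SpecValidationError):
        InstrumentSpec(
            name="bad", rater="caregiver", age_range=(6, 18), items=items,
            subscales={"s": ("1",)},
        )


def test_malformed_spec_file(tmp_path):
    p = tmp_path / "broken.yaml"
    p.write_text("name: x\nrater: caregiver\nitems: [1, 2]\n")  # missing fields
    with pytest.raises(SpecFormatError, match="age_range|subscales"):
        load_instrument_spec(p)


def test_spec_yaml_json_equivalence(tmp_path):
    spec = load_bundled_spec("psc17")
    doc = {
        "name": "psc17", "rater": "caregiver", "age_range": [6, 18],
        "n_categories": 3, "items": [str(i) for i in range(1, 18)],
        "subscales": {k: list(v) for k, v in spec.subscales.items()},
    }
    import json

    (tmp_path / "s.yaml").write_text(yaml.safe_dump(doc))
    (tmp_path / "s.json").write_text(json.dumps(doc))
    a = load_instrument_spec(tmp_path / "s.yaml")
    b = load_instrument_spec(tmp_path / "s.json")
    assert a.items == b.items and a.subscales == b.subscales


@pytest.fixture()
def psc17_csv(tmp_path):
    spec = load_bundled_spec("psc17")
    rng = np.random.default_rng(1)
    rows = ["person_id," + ",".join(spec.item_ids) + ",age_group,gender"]
    for i in range(5):
        vals = rng.integers(0, 3, size=17)
        rows.append(f"p{i}," + ",".join(map(str, vals)) + ",6-9,female")
    path = tmp_path / "resp.csv"
    path.write_text("\n".join(rows) + "\n")
    return path, spec


def test_read_responses_shape_and_covariates(psc17_csv):
    path, spec = psc17_csv
    m = read_responses(path, spec)
    assert m.responses.shape == (5, 17)
    assert m.age_group == ["6-9"] * 5 and m.gender == ["female"] * 5


def test_write_read_roundtrip(tmp_path, psc17_csv):
    path, spec = psc17_csv
    m = read_responses(path, spec)
    out = tmp_path / "again.csv"
    write_responses(m, out)
    m2 = read_responses(out, spec)
    assert np.array_equal(m.responses, m2.responses)
    assert m.person_ids == m2.person_ids


def test_out_of_range_value_rejected(psc17_csv, tmp_path):
    path, spec = psc17_csv
    text = path.read_text().splitlines()
    parts = text[2].split(",")
    parts[3] = "3"  # K=3 item: max legal response is 2
    text[2] = ",".join(parts)
    bad = tmp_path / "bad.csv"
    bad.write_text("\n".join(text) + "\n")
    with pytest.raises(ResponseDataError, match="out of range"):
        read_responses(bad, spec)


def test_missing_cell_policies(psc17_csv, tmp_path):
    path, spec = psc17_csv
    text = path.read_text().splitlines()
    parts = text[3].split(",")
    parts[5] = ""
    text[3] = ",".join(parts)
    holed = tmp_path / "holed.csv"
    holed.write_text("\n".join(text) + "\n")
    with pytest.raises(ResponseDataError, match="missing cell"):
        read_responses(holed, spec)
    m = read_responses(holed, spec, missing="listwise")
    assert m.n_persons == 4


def test_origin_shift(tmp_path):
    spec = load_bundled_spec("mchat")
    rows = [",".join(spec.item_ids)] + [",".join(["1"] * 20), ",".join(["2"] * 20)]
    p = tmp_path / "oneb.csv"
    p.write_text("\n".join(rows) + "\n")
    m = read_responses(p, spec, origin=1)
    assert set(np.unique(m.responses)) == {0, 1}


def _matrix(values, item_ids=None):
    values = np.asarray(values)
    ids = item_ids or [str(j) for j in range(values.shape[1])]
    n = values.shape[0]
    return ResponseMatrix([f"p{i}" for i in range(n)], ids, values,
                          ["6-9"] * n, ["female"] * n)


def test_sum_scores_examples():
    m = _matrix(np.zeros((3, 5), dtype=int))
    assert (sum_scores(m, m.item_ids) == 0).all()
    m = _matrix(np.full((2, 5), 2))
    assert (sum_scores(m, m.item_ids) == 10).all()
    m = _matrix([[1, 0, 2, 1, 1]])
    assert sum_scores(m, m.item_ids)[0] == 5
    with pytest.raises(ValueError):
        sum_scores(m, [])


def test_sum_scores_permutation_and_additivity():
    rng = np.random.default_rng(2)
    m = _matrix(rng.integers(0, 3, size=(20, 6)))
    ids = m.item_ids
    full = sum_scores(m, ids)
    assert np.array_equal(full, sum_scores(m, ids[::-1]))
    assert np.array_equal(full, sum_scores(m, ids[:3]) + sum_scores(m, ids[3:]))
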