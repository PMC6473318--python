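"""Drug normalisation, ontology completeness, cohort IO and flag round trips."""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popiuk.engine import Flag
from popiuk.records import (
    RecordError,
    drug_in_class,
    is_unknown_drug,
    normalize_drug,
    read_cohort,
    read_flags,
    write_cohort,
    write_flags,
)
from tests.conftest import make_record


@pytest.mark.parametrize(
    ("raw", "generic"),
    [
        ("Ascabiol", "benzyl_benzoate"),
        ("IBUPROFEN ", "ibuprofen"),
        ("penicillin V", "phenoxymethylpenicillin"),
        ("  Calpol ", "paracetamol"),
        ("chlorpheniramine", "chlorphenamine"),
    ],
)
def test_normalize_resolves_brand_and_case(ontology, raw, generic):
    assert normalize_drug(raw, ontology) == generic


def test_unresolvable_name_returns_marker_not_silence(ontology):
    marker = normalize_drug("floopramide", ontology)
    assert is_unknown_drug(marker)
    assert "floopramide" in marker


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(min_size=0, max_size=30))
def test_normalize_is_idempotent(ontology, raw):
    once = normalize_drug(raw, ontology)
    assert normalize_drug(once, ontology) == once


@pytest.mark.parametrize(
    ("generic", "cls", "expected"),
    [
        ("ibuprofen", "nsaid", True),
        ("paracetamol", "nsaid", False),
        ("paracetamol", "antipyretic", True),
        ("ranitidine", "acid_suppressing", True),
    ],
)
def test_drug_in_class(ontology, generic, cls, expected):
    assert drug_in_class(generic, cls, ontology) is expected


def test_unknown_drug_is_in_no_class(ontology):
    marker = normalize_drug("floopramide", ontology)
    assert drug_in_class(marker, "nsaid", ontology) is False


def test_unknown_class_name_is_a_configuration_error(ontology):
    with pytest.raises(RecordError, match="unknown drug class"):
        drug_in_class("ibuprofen", "frobnicator", ontology)


def _all_condition_dicts(node):
    if isinstance(node, dict):
        yield node
        for v in node.values():
            yield from _all_condition_dicts(v)
    elif isinstance(node, list):
        for item in node:
            yield from _all_condition_dicts(item)


def test_every_catalogue_drug_and_class_resolves(catalog, ontology):
    """Completeness: the packaged ontology covers everything the rules name."""
    classes = ontology.known_classes()
    for criterion in catalog.criteria:
        if not criterion.condition:
            continue
        for node in _all_condition_dicts(criterion.condition):
            for key in ("drug", "drug_not"):
                for name in node.get(key, []):
                    assert normalize_drug(name, ontology) == name, (criterion.id, name)
            for key in ("class_any", "class_not"):
                for cls in node.get(key, []):
                    assert cls in classes, (criterion.id, cls)


def test_every_catalogue_condition_code_is_in_vocabulary(catalog):
    from popiuk.records import load_vocabulary

    vocab = load_vocabulary()
    codes = set(vocab["conditions"])
    quals = set(vocab["qualifiers"])
    keys_codes = ("active_condition_any", "condition_any", "co_condition_any", "indication_any")
    keys_quals = ("qualifier_any", "qualifier_all", "qualifier_none",
                  "condition_qualifier_any")
    for criterion in catalog.criteria:
        if not criterion.condition:
            continue
        for node in _all_condition_dicts(criterion.condition):
            for key in keys_codes:
                for code in node.get(key, []):
                    assert code in codes, (criterion.id, code)
            for key in keys_quals:
                for q in node.get(key, []):
                    assert q in quals, (criterion.id, q)


# ---------------------------------------------------------------------------
# Cohort file IO
# ---------------------------------------------------------------------------

def _write_cohort_files(tmp_path, patients, conditions, prescriptions):
    p = tmp_path / "patients.csv"
    c = tmp_path / "conditions.csv"
    rx = tmp_path / "prescriptions.csv"
    p.write_text("patient_id,date_of_birth,sex,pregnant,weight_kg,weight_date,formula_ml_per_day\n"
                 + "".join(patients))
    c.write_text("patient_id,code,onset,end,qualifiers\n" + "".join(conditions))
    rx.write_text("patient_id,rx_id,drug,dose_amount,dose_unit,doses_per_day,route,"
                  "formulation,start,end,indication_code,device,site\n" + "".join(prescriptions))
    return p, c, rx


def test_read_cohort_joins_two_patients(tmp_path, ontology):
    p, c, rx = _write_cohort_files(
        tmp_path,
        ["pa,2015-03-01,female,false,22.5,2023-01-01,\n",
         "pb,2020-07-15,male,false,12.0,2023-01-01,\n"],
        ["pa,asthma,2022-01-01,,\n"],
        ["pa,r1,salbutamol,100,mg,2,inhaled,,2023-01-02,,asthma,pmdi_spacer,\n",
         "pb,r2,paracetamol,120,mg,3,oral,,2023-02-01,2023-02-04,,,\n"],
    )
    records = {r.patient_id: r for r in read_cohort(p, c, rx, ontology=ontology)}
    assert set(records) == {"pa", "pb"}
    assert records["pa"].prescriptions[0].drug_norm == "salbutamol"
    assert records["pa"].prescriptions[0].line_of_therapy == 1
    assert records["pb"].conditions == []


def test_empty_prescriptions_file_gives_rx_free_records(tmp_path, ontology):
    p, c, rx = _write_cohort_files(
        tmp_path, ["pa,2015-03-01,female,false,22.5,2023-01-01,\n"], [], [])
    (rec,) = read_cohort(p, c, rx, ontology=ontology)
    assert rec.prescriptions == []


def test_orphan_prescription_is_a_join_error(tmp_path):
    p, c, rx = _write_cohort_files(
        tmp_path, ["pa,2015-03-01,female,false,22.5,2023-01-01,\n"], [],
        ["ghost,r9,paracetamol,120,mg,3,oral,,2023-02-01,,,,\n"])
    with pytest.raises(RecordError, match="r9"):
        read_cohort(p, c, rx)


def test_unparseable_date_names_the_row(tmp_path):
    p, c, rx = _write_cohort_files(
        tmp_path, ["pa,01/03/2015,female,false,22.5,2023-01-01,\n"], [], [])
    with pytest.raises(RecordError, match="row 2"):
        read_cohort(p, c, rx)


def test_missing_required_column_is_a_schema_error(tmp_path):
    (tmp_path / "patients.csv").write_text("patient_id,sex\npa,female\n")
    (tmp_path / "conditions.csv").write_text("patient_id,code,onset,end,qualifiers\n")
    (tmp_path / "prescriptions.csv").write_text(
        "patient_id,rx_id,drug,dose_amount,dose_unit,doses_per_day,route,"
        "formulation,start,end,indication_code,device,site\n")
    with pytest.raises(RecordError, match="date_of_birth"):
        read_cohort(tmp_path / "patients.csv", tmp_path / "conditions.csv",
                    tmp_path / "prescriptions.csv")


def test_dangling_indication_link_warns_but_keeps_row(tmp_path, ontology):
    p, c, rx = _write_cohort_files(
        tmp_path, ["pa,2015-03-01,female,false,22.5,2023-01-01,\n"], [],
        ["pa,r1,paracetamol,120,mg,3,oral,,2023-02-01,,migraine,,\n"])
    with pytest.warns(UserWarning, match="dangling"):
        (rec,) = read_cohort(p, c, rx, ontology=ontology)
    assert rec.prescriptions[0].indication == "migraine"


def test_cohort_write_read_round_trip(tmp_path, ontology):
    rec = make_record(
        ontology, age_years=6, sex="female",
        conditions=[("asthma", 100, None, ("severe",))],
        prescriptions=[dict(drug="salbutamol", route="inhaled", device="pmdi_spacer",
                            dose_amount=100, dose_unit="mg", doses_per_day=2,
                            start_back=30, end_back=None, indication="asthma")],
    )
    paths = write_cohort([rec], tmp_path)
    (again,) = read_cohort(paths["patients"], paths["conditions"],
                           paths["prescriptions"], ontology=ontology)
    assert again.model_dump(exclude={"meta"}) == rec.model_dump(exclude={"meta"})


@pytest.mark.parametrize("suffix", ["csv", "json"])
@pytest.mark.parametrize("n_flags", [0, 1, 3])
def test_flag_file_round_trip(tmp_path, suffix, n_flags):
    flags = [
        Flag(criterion_id=f"DIA-IP-0{i + 1}", patient_id=f"p{i}",
             kind="inappropriate_prescription", evidence=[f"rx{i}", "diarrhoea"],
             evaluation_date=date(2023, 6, 30))
        for i in range(n_flags)
    ]
    path = write_flags(flags, tmp_path / f"flags.{suffix}")
    assert read_flags(path) == flags
    if n_flags == 0 and suffix == "csv":
        assert path.read_text().strip() == (
            "patient_id,criterion_id,kind,evidence,evaluation_date,note")
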