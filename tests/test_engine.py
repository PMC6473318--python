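"""Engine arithmetic, boundary semantics, evaluation routing, determinism."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from popiuk.engine import (
    EngineError,
    NotEvaluable,
    age_years,
    co_prescribed,
    daily_dose_per_kg,
    duration_days,
    evaluate_criterion,
    screen_cohort,
    screen_record,
)
from popiuk.records import Prescription
from tests.conftest import AS_OF, make_record


def _flag_ids(result):
    return {f.criterion_id for f in result.flags}


# ---------------------------------------------------------------------------
# Elementary arithmetic
# ---------------------------------------------------------------------------

def test_age_is_day_count_over_julian_year():
    # 2010-01-01 -> 2014-01-01 spans 1461 days (2012 is a leap year)
    assert age_years(date(2010, 1, 1), date(2014, 1, 1)) == pytest.approx(1461 / 365.25)
    # the day before that is still "before four years" under the strict bound
    assert age_years(date(2010, 1, 1), date(2013, 12, 31)) < 4.0
    assert age_years(date(2010, 1, 1), date(2010, 1, 1)) == 0.0


def test_age_before_birth_is_a_domain_error():
    with pytest.raises(EngineError):
        age_years(date(2010, 1, 1), date(2009, 12, 31))


@pytest.mark.parametrize(
    ("dose", "per_day", "weight", "expected"),
    [(100, 3, 10, 30.0), (120, 3, 10, 36.0), (0, 3, 10, 0.0)],
)
def test_daily_dose_per_kg_exact(dose, per_day, weight, expected):
    p = Prescription(rx_id="r", drug="ibuprofen", dose_amount=dose, dose_unit="mg",
                     doses_per_day=per_day, start=date(2023, 1, 1))
    assert daily_dose_per_kg(p, weight) == expected


def test_daily_dose_requires_mg():
    p = Prescription(rx_id="r", drug="ibuprofen", dose_amount=5, dose_unit="mL",
                     doses_per_day=3, start=date(2023, 1, 1))
    with pytest.raises(EngineError, match="not mg"):
        daily_dose_per_kg(p, 10)


@pytest.mark.parametrize(
    ("end_back", "as_of_back", "expected"),
    [(12, 0, 28), (40, 40, 0), (None, 0, 40)],
)
def test_duration_day_count(end_back, as_of_back, expected):
    start = date(2023, 1, 1)
    p = Prescription(
        rx_id="r", drug="ranitidine", dose_amount=75, doses_per_day=2, start=start,
        end=None if end_back is None else start + timedelta(days=40 - end_back),
    )
    assert duration_days(p, start + timedelta(days=40 - as_of_back)) == expected


def test_co_prescribed_overlap_symmetric_and_distinct_drug():
    d = date(2023, 1, 1)

    def rx(drug, s, e):
        return Prescription(rx_id=drug, drug=drug, drug_norm=drug, dose_amount=1,
                            doses_per_day=1, start=d + timedelta(days=s),
                            end=d + timedelta(days=e))

    a, b = rx("ibuprofen", 1, 7), rx("naproxen", 5, 10)
    assert co_prescribed(a, b) and co_prescribed(b, a)
    assert not co_prescribed(rx("ibuprofen", 1, 7), rx("ibuprofen", 5, 10))
    assert not co_prescribed(rx("ibuprofen", 1, 4), rx("naproxen", 5, 8))


# ---------------------------------------------------------------------------
# Threshold boundary behaviour (two-sided at each printed threshold)
# ---------------------------------------------------------------------------

def _ibuprofen_record(ontology, dose_mg, per_day=3, weight=10.0):
    return make_record(ontology, age_years=6, weight_kg=weight, prescriptions=[
        dict(drug="ibuprofen", dose_amount=dose_mg, dose_unit="mg",
             doses_per_day=per_day, start_back=5, end_back=1)])


def test_ibuprofen_30_mg_per_kg_boundary(catalog, ontology):
    at = screen_record(_ibuprofen_record(ontology, 100), catalog, AS_OF, ontology)
    above = screen_record(_ibuprofen_record(ontology, 101), catalog, AS_OF, ontology)
    assert "PAF-IP-04" not in _flag_ids(at)       # exactly 30 mg/kg/day
    assert "PAF-IP-04" in _flag_ids(above)        # 30.3 mg/kg/day


def test_ibuprofen_more_than_three_doses_boundary(catalog, ontology):
    three = screen_record(_ibuprofen_record(ontology, 50, per_day=3), catalog, AS_OF, ontology)
    four = screen_record(_ibuprofen_record(ontology, 50, per_day=4), catalog, AS_OF, ontology)
    assert "PAF-IP-04" not in _flag_ids(three)
    assert "PAF-IP-04" in _flag_ids(four)


def _loperamide_record(ontology, age):
    return make_record(ontology, age_years=age, prescriptions=[
        dict(drug="loperamide", dose_amount=2, doses_per_day=3, start_back=0, end_back=0)])


def test_loperamide_fourth_birthday_boundary(catalog, ontology):
    under = make_record(ontology, prescriptions=[
        dict(drug="loperamide", dose_amount=2, doses_per_day=3, start_back=0, end_back=0)])
    under.date_of_birth = AS_OF - timedelta(days=1460)   # the day before turning 4
    at = make_record(ontology, prescriptions=[
        dict(drug="loperamide", dose_amount=2, doses_per_day=3, start_back=0, end_back=0)])
    at.date_of_birth = AS_OF - timedelta(days=1461)      # the fourth birthday
    assert "DIA-IP-01" in _flag_ids(screen_record(under, catalog, AS_OF, ontology))
    assert "DIA-IP-01" not in _flag_ids(screen_record(at, catalog, AS_OF, ontology))


def _h2ra_record(ontology, days):
    return make_record(ontology, prescriptions=[
        dict(drug="ranitidine", dose_amount=75, doses_per_day=2,
             start_back=60, end_back=60 - days)])


def test_h2ra_four_week_boundary(catalog, ontology):
    at = screen_record(_h2ra_record(ontology, 28), catalog, AS_OF, ontology)
    above = screen_record(_h2ra_record(ontology, 29), catalog, AS_OF, ontology)
    assert "NVG-IP-06" not in _flag_ids(at)      # exactly four weeks
    assert "NVG-IP-06" in _flag_ids(above)


def _morphine_record(ontology, days, with_laxative=False):
    rxs = [dict(drug="morphine", dose_amount=10, doses_per_day=4,
                start_back=days, end_back=0)]
    if with_laxative:
        rxs.append(dict(drug="lactulose", dose_amount=10, dose_unit="mL",
                        doses_per_day=2, start_back=days - 2, end_back=0))
    return make_record(ontology, prescriptions=rxs)


def test_morphine_laxative_48_h_boundary(catalog, ontology):
    at = screen_record(_morphine_record(ontology, 2), catalog, AS_OF, ontology)
    above = screen_record(_morphine_record(ontology, 3), catalog, AS_OF, ontology)
    covered = screen_record(_morphine_record(ontology, 5, with_laxative=True),
                            catalog, AS_OF, ontology)
    assert "PAF-OM-01" not in _flag_ids(at)      # exactly 48 h
    assert "PAF-OM-01" in _flag_ids(above)
    assert "PAF-OM-01" not in _flag_ids(covered)


def test_dose_rule_monotone_in_dose(catalog, ontology):
    """If dose d flags, every d' > d flags (fixed weight and frequency)."""
    flagged = [
        "PAF-IP-04" in _flag_ids(
            screen_record(_ibuprofen_record(ontology, d), catalog, AS_OF, ontology))
        for d in range(80, 140, 5)
    ]
    assert flagged == sorted(flagged)  # False ... False True ... True


# ---------------------------------------------------------------------------
# evaluate_criterion routing
# ---------------------------------------------------------------------------

def test_loperamide_age_flag_carries_evidence(catalog, ontology):
    rec = _loperamide_record(ontology, 3)
    (flag,) = evaluate_criterion(catalog.criterion("DIA-IP-01"), rec, AS_OF, ontology)
    assert flag.kind == "inappropriate_prescription"
    assert flag.evidence == ["r1"]


def test_morphine_omission_fires_without_laxative(catalog, ontology):
    rec = _morphine_record(ontology, 4)
    (flag,) = evaluate_criterion(catalog.criterion("PAF-OM-01"), rec, AS_OF, ontology)
    assert flag.kind == "omission"
    assert flag.evidence  # anchor prescription identifies the episode


def test_sickle_cell_prophylaxis_at_banded_dose_is_silent(catalog, ontology):
    rec = make_record(
        ontology, age_years=3,
        conditions=[("sickle_cell_anaemia", 900, None, ())],
        prescriptions=[dict(drug="penicillin V", dose_amount=125, dose_unit="mg",
                            doses_per_day=2, start_back=600, end_back=None)])
    assert evaluate_criterion(catalog.criterion("VIT-OM-02"), rec, AS_OF, ontology) == []


def test_sickle_cell_wrong_dose_is_an_omission(catalog, ontology):
    rec = make_record(
        ontology, age_years=3,
        conditions=[("sickle_cell_anaemia", 900, None, ())],
        prescriptions=[dict(drug="penicillin V", dose_amount=250, dose_unit="mg",
                            doses_per_day=2, start_back=600, end_back=None)])
    (flag,) = evaluate_criterion(catalog.criterion("VIT-OM-02"), rec, AS_OF, ontology)
    assert "sickle_cell_anaemia" in flag.evidence


def test_manual_criterion_routes_to_manual_tier(catalog, ontology):
    rec = make_record(ontology)
    out = evaluate_criterion(catalog.criterion("RIN-OM-02"), rec, AS_OF, ontology)
    assert isinstance(out, NotEvaluable) and out.reason == "manual_tier"


def test_missing_weight_routes_dose_rule(catalog, ontology):
    rec = make_record(ontology, weight_kg=None, prescriptions=[
        dict(drug="ibuprofen", dose_amount=100, doses_per_day=3, start_back=5, end_back=1)])
    out = evaluate_criterion(catalog.criterion("PAF-IP-04"), rec, AS_OF, ontology)
    assert isinstance(out, NotEvaluable) and out.reason == "missing_weight"


def test_missing_indication_routes_first_line_rule(catalog, ontology):
    rec = make_record(ontology, conditions=[("depression", 100, None, ())],
                      prescriptions=[dict(drug="sertraline", dose_amount=50,
                                          doses_per_day=1, start_back=30, end_back=None)])
    out = evaluate_criterion(catalog.criterion("DEP-IP-01"), rec, AS_OF, ontology)
    assert isinstance(out, NotEvaluable) and out.reason == "missing_indication"


def test_exception_qualifier_suppresses_flag(catalog, ontology):
    fired = make_record(ontology, conditions=[("sore_throat", 10, None, ())],
                        prescriptions=[dict(drug="penicillin V", dose_amount=250,
                                            doses_per_day=4, start_back=5, end_back=None)])
    excused = make_record(ontology,
                          conditions=[("sore_throat", 10, None,
                                       ("clinical_concern_documented",))],
                          prescriptions=[dict(drug="penicillin V", dose_amount=250,
                                              doses_per_day=4, start_back=5, end_back=None)])
    assert "ENT-IP-02" in _flag_ids(screen_record(fired, catalog, AS_OF, ontology))
    assert "ENT-IP-02" not in _flag_ids(screen_record(excused, catalog, AS_OF, ontology))


def test_erythromycin_for_infection_never_fires_prokinetic_rule(catalog, ontology):
    rec = make_record(ontology, conditions=[("impetigo", 10, None, ())],
                      prescriptions=[dict(drug="erythromycin", dose_amount=250,
                                          doses_per_day=4, start_back=8, end_back=1,
                                          indication="impetigo")])
    assert evaluate_criterion(catalog.criterion("NVG-IP-07"), rec, AS_OF, ontology) == []


def test_unknown_drug_never_fires_class_rules_but_is_noted(catalog, ontology):
    rec = make_record(ontology, age_years=1, prescriptions=[
        dict(drug="floopramide", dose_amount=5, doses_per_day=2, start_back=5, end_back=1)])
    result = screen_record(rec, catalog, AS_OF, ontology)
    assert not result.flags
    assert any("floopramide" in n for n in result.notes)


# ---------------------------------------------------------------------------
# screen_record / screen_cohort
# ---------------------------------------------------------------------------

def test_empty_record_yields_zero_flags(catalog, ontology):
    result = screen_record(make_record(ontology), catalog, AS_OF, ontology)
    assert result.flags == []
    reasons = {r for _c, r in result.not_evaluable}
    assert reasons <= {"manual_tier"}


def test_criterion_appears_once_per_patient(catalog, ontology):
    # two loperamide orders -> one flag with both orders as evidence
    rec = make_record(ontology, age_years=2, prescriptions=[
        dict(drug="loperamide", dose_amount=2, doses_per_day=2, start_back=10, end_back=6),
        dict(drug="Imodium", dose_amount=2, doses_per_day=2, start_back=4, end_back=1)])
    result = screen_record(rec, catalog, AS_OF, ontology)
    dia = [f for f in result.flags if f.criterion_id == "DIA-IP-01"]
    assert len(dia) == 1
    assert set(dia[0].evidence) == {"r1", "r2"}


def test_screening_is_deterministic(catalog, ontology):
    rec = make_record(ontology, age_years=2, prescriptions=[
        dict(drug="loperamide", dose_amount=2, doses_per_day=2, start_back=4, end_back=1)])
    r1 = screen_record(rec, catalog, AS_OF, ontology)
    r2 = screen_record(rec, catalog, AS_OF, ontology)
    assert r1 == r2


def test_cohort_prevalence_counts_and_denominators(catalog, ontology):
    records = []
    for i in range(10):
        rec = make_record(ontology, age_years=3 if i < 3 else 8)
        rec.patient_id = f"p{i:02d}"
        if i < 3:
            rec.prescriptions.append(Prescription(
                rx_id="rl", drug="loperamide", drug_norm="loperamide",
                dose_amount=2, doses_per_day=2, start=AS_OF - timedelta(days=3)))
        records.append(rec)
    flags, prevalence = screen_cohort(records, catalog, AS_OF, ontology)
    row = prevalence.set_index("criterion_id").loc["DIA-IP-01"]
    assert row["n_flagged"] == 3
    assert row["n_evaluable"] == 10
    assert row["prevalence"] == pytest.approx(0.3)


def test_all_weightless_cohort_reports_undefined_dose_prevalence(catalog, ontology):
    records = []
    for i in range(3):
        rec = make_record(ontology, weight_kg=None, prescriptions=[
            dict(drug="ibuprofen", dose_amount=100, doses_per_day=3,
                 start_back=5, end_back=1)])
        rec.patient_id = f"p{i}"
        records.append(rec)
    _flags, prevalence = screen_cohort(records, catalog, AS_OF, ontology)
    row = prevalence.set_index("criterion_id").loc["PAF-IP-04"]
    assert row["n_evaluable"] == 0
    assert row["prevalence"] != row["prevalence"]  # NaN: undefined, reported as such


def test_empty_cohort_warns_and_returns_empty(catalog, ontology):
    with pytest.warns(UserWarning, match="empty cohort"):
        flags, prevalence = screen_cohort([], catalog, AS_OF, ontology)
    assert flags == [] and prevalence.empty
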