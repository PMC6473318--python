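from __future__ import annotations

from datetime import date, timedelta

import pytest

from popiuk.catalog import load_catalog
from popiuk.records import PatientRecord, Prescription, load_ontology, normalize_record

AS_OF = date(2023, 6, 30)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def ontology():
    return load_ontology()


def make_record(
    ontology,
    age_years: float = 8.0,
    weight_kg: float | None = 25.0,
    sex: str = "unknown",
    pregnant: bool = False,
    conditions=(),
    prescriptions=(),
    as_of: date = AS_OF,
) -> PatientRecord:
    """Small record builder used across the engine tests.

    ``conditions`` are (code, onset_days_before, end_days_before|None,
    qualifiers) tuples; ``prescriptions`` are dicts passed to
    :class:`Prescription` with ``start``/``end`` given in days before
    ``as_of`` (end None = ongoing).
    """
    from popiuk.records import Condition

    rec = PatientRecord(
        patient_id="t001",
        date_of_birth=as_of - timedelta(days=round(age_years * 365.25)),
        sex=sex,
        pregnant=pregnant,
        weight_kg=weight_kg,
        weight_date=as_of if weight_kg is not None else None,
    )
    for code, onset_back, end_back, quals in conditions:
        rec.conditions.append(Condition(
            code=code,
            onset=as_of - timedelta(days=onset_back),
            end=None if end_back is None else as_of - timedelta(days=end_back),
            qualifiers=frozenset(quals),
        ))
    for i, spec in enumerate(prescriptions, start=1):
        spec = dict(spec)
        start_back = spec.pop("start_back")
        end_back = spec.pop("end_back", 0)
        spec.setdefault("rx_id", f"r{i}")
        spec.setdefault("dose_amount", 1.0)
        spec.setdefault("doses_per_day", 1)
        rec.prescriptions.append(Prescription(
            start=as_of - timedelta(days=start_back),
            end=None if end_back is None else as_of - timedelta(days=end_back),
            **spec,
        ))
    normalize_record(rec, ontology)
    return rec
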