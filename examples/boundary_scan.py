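"""Recover the ibuprofen dosing threshold by scanning the engine.

Screens a 10 kg six-year-old on three daily ibuprofen doses while sweeping
the per-dose amount.  The first flagged dose reveals the encoded maximum:
30 mg/kg/day exactly passes, anything above flags.
"""

from datetime import date, timedelta

from popiuk import load_catalog, load_ontology
from popiuk.engine import screen_record
from popiuk.records import PatientRecord, Prescription, normalize_record

catalog = load_catalog()
ontology = load_ontology()
as_of = date(2023, 6, 30)

def flagged(dose_mg: float) -> bool:
    rec = PatientRecord(
        patient_id="probe", date_of_birth=as_of - timedelta(days=6 * 365),
        weight_kg=10.0, weight_date=as_of)
    rec.prescriptions.append(Prescription(
        rx_id="r1", drug="ibuprofen", dose_amount=dose_mg, dose_unit="mg",
        doses_per_day=3, start=as_of - timedelta(days=5), end=as_of - timedelta(days=1)))
    normalize_record(rec, ontology)
    result = screen_record(rec, catalog, as_of=as_of, ontology=ontology)
    return "PAF-IP-04" in {f.criterion_id for f in result.flags}

last_clean = max(d for d in range(50, 150) if not flagged(d))
print(f"largest non-flagged dose: {last_clean} mg x3/day on 10 kg "
      f"= {last_clean * 3 / 10:.1f} mg/kg/day")
print(f"{last_clean + 1} mg x3/day flags ({(last_clean + 1) * 3 / 10:.1f} mg/kg/day)")
# The scan recovers the criterion's 30 mg/kg/day maximum without reading the
# rule's parameters — the same method scripts/acceptance.py uses for every
# encoded threshold.
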