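"""Screen a single child's record against all 80 POPI(UK) criteria.

Builds a small record by hand — a dehydrated 2¾-year-old with diarrhoea on
a brand-name loperamide product — and prints every flag with its evidence.
Expect two findings: loperamide under four years of age (inappropriate
prescription) and no oral rehydration solution for a dehydrated child
(omission).
"""

from datetime import date

from popiuk import load_catalog, load_ontology
from popiuk.engine import screen_record
from popiuk.records import Condition, PatientRecord, Prescription, normalize_record

catalog = load_catalog()
ontology = load_ontology()

rec = PatientRecord(
    patient_id="child-042",
    date_of_birth=date(2020, 9, 12),
    weight_kg=14.0,
    weight_date=date(2023, 6, 1),
)
rec.conditions.append(Condition(code="diarrhoea", onset=date(2023, 6, 24)))
rec.conditions.append(Condition(code="dehydration", onset=date(2023, 6, 26)))
rec.prescriptions.append(Prescription(
    rx_id="rx1", drug="Imodium", dose_amount=2, dose_unit="mg",
    doses_per_day=3, route="oral", start=date(2023, 6, 26), indication="diarrhoea"))
normalize_record(rec, ontology)  # brand -> generic, derive lines of therapy

result = screen_record(rec, catalog, as_of=date(2023, 6, 30), ontology=ontology)
for flag in result.flags:
    print(f"{flag.criterion_id} [{flag.kind}] evidence={flag.evidence}")
    print(f"  {catalog.criterion(flag.criterion_id).text}")
print(f"not evaluable: {len(result.not_evaluable)} criteria")
# Each flag names the criterion, the kind of problem, and the prescriptions
# or conditions that fired it; not-evaluable criteria (manual-review tier or
# missing optional data) are excluded from any prevalence denominator.
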