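# popiuk

An executable implementation of **POPI(UK)** — the UK modification of the
*Pediatrics: Omission of Prescriptions and Inappropriate Prescriptions*
screening tool — for pharmacists, prescribing-safety researchers and audit
teams who want to screen structured paediatric prescription records against
explicit criteria, in hospital or outpatient settings.

The tool comprises **80 explicit criteria** across five clinical groups
(diverse illnesses, digestive, ENT–pulmonary, dermatological,
neuropsychiatric): 60 indicators of potentially inappropriate prescriptions
(e.g. *"Loperamide before four years of age"*, *"The combined use of two
NSAIDs"*, *"Doses of ibuprofen … exceeding maximum dose of 30 mg/kg daily"*)
and 20 potentially inappropriate omissions (e.g. *"Failure to give an
osmotic laxative to patients being treated with morphine for a period of
more than 48 h"*).  The 80 criteria derive from the 105 propositions of the
original French POPI tool by comparison against UK guidance (NICE, SIGN,
cBNF): 49 unchanged, 29 amended, 4 combined into 2, and 23 omitted (12 with
no relevant UK guideline, 4 conflicting with UK guidance, and the entire
7-proposition mosquito category).  The package ships both the criteria and
this full modification provenance as validated data, an evaluation engine,
and a seeded synthetic-cohort generator so every rule is testable without
patient data.

For a cohort, the engine reports per-criterion **prevalence** = flagged
patients / evaluable patients; patients whose records cannot decide a
criterion (missing weight for mg/kg arithmetic, no indication link for
"first-line" rules, manual-review criteria) leave the denominator and are
reported by reason.

## Worked example

```python
from datetime import date
from popiuk import load_catalog, load_ontology
from popiuk.engine import screen_record
from popiuk.records import PatientRecord, Condition, Prescription, normalize_record

catalog = load_catalog()
ontology = load_ontology()

rec = PatientRecord(
    patient_id="child-042",
    date_of_birth=date(2020, 9, 12),          # 2 years 9 months old
    weight_kg=14.0, weight_date=date(2023, 6, 1),
)
rec.conditions.append(Condition(code="diarrhoea", onset=date(2023, 6, 24)))
rec.conditions.append(Condition(code="dehydration", onset=date(2023, 6, 26)))
rec.prescriptions.append(Prescription(
    rx_id="rx1", drug="Imodium", dose_amount=2, dose_unit="mg",
    doses_per_day=3, route="oral", start=date(2023, 6, 26), indication="diarrhoea"))
normalize_record(rec, ontology)                # brand -> generic, lines of therapy

result = screen_record(rec, catalog, as_of=date(2023, 6, 30), ontology=ontology)
for flag in result.flags:
    print(f"{flag.criterion_id} [{flag.kind}] evidence={flag.evidence}")
    print(f"  {catalog.criterion(flag.criterion_id).text}")
print(f"not evaluable: {len(result.not_evaluable)} criteria")
```

prints

```
DIA-IP-01 [inappropriate_prescription] evidence=['rx1']
  Loperamide before four years of age.
DIA-OM-01 [omission] evidence=['dehydration', 'diarrhoea']
  Oral rehydration solution (ORS) for dehydrated children unless IV fluid therapy is indicated (shock, red flag symptoms despite ORS, persist vomiting of ORS).
not evaluable: 5 criteria
```

Two findings: the brand name *Imodium* resolved to loperamide, which is
inappropriate under four years of age (the child is 2¾, and the rule's
boundary is the fourth birthday itself); and the dehydrated child has no
oral rehydration solution prescribed — an omission, with the qualifying
conditions as evidence.  Five criteria were not evaluable from this record
(the four manual-review criteria plus one needing an optional field).

## Command line

```bash
popiuk catalog                       # 80/49/29/4->2/23 arithmetic + per-category counts
popiuk simulate --spec spec.yaml --out cohort/   # seeded cohort + truth table
popiuk screen --patients cohort/patients.csv \
              --conditions cohort/conditions.csv \
              --prescriptions cohort/prescriptions.csv \
              --as-of 2023-06-30 --out results/
# -> results/flags.csv, results/prevalence.csv, results/run.log
```

Input file schemas (CSV or JSON with identical field names) are documented
in `popiuk.records`; the run log records the catalogue version/checksum,
not-evaluable counts by reason, and unknown-drug suppressions.

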