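# Methods

## What the package computes

POPI(UK) — *Pediatrics: Omission of Prescriptions and Inappropriate
Prescriptions*, UK modification — is an explicit-criteria screening tool for
the quality of prescribing for children in hospital and outpatient settings.
This package turns the tool into an executable rule engine with three parts:

1. **Catalogue** — the 80 criteria as data, each with a verbatim text, a
   clinical category in one of five groups (diverse illnesses, digestive,
   ENT–pulmonary, dermatological, neuropsychiatric), a kind (inappropriate
   prescription vs omission), a machine-readable condition tree, and an
   automatability tier.  Alongside sits the provenance ledger for the 105
   propositions of the original French tool: 49 unchanged, 29 amended to
   follow UK guidance, 4 combined into 2, and 23 omitted (12 with no relevant
   UK guideline, 4 conflicting with UK guidance, 7 because the entire
   mosquito category is inapplicable in the UK).  Validation closes this
   arithmetic exactly: 49+29+4+23 = 105 and 49+29+2 = 80.
2. **Engine** — evaluates every criterion against structured patient records
   (demographics, a dated weight, coded conditions with boolean qualifiers,
   dated prescriptions), producing per-patient flags with evidence and
   per-criterion cohort prevalence.
3. **Synthetic cohorts** — a seeded generator of clean-by-construction
   records plus per-criterion violation injection, so every engine behaviour
   is testable end to end without any patient data.

Note on sources: the published account of the tool's modification states in
its discussion that 22 propositions lacked relevant UK guidelines, which does
not reconcile with its own tables (12 omitted for no guideline + 7 removed
with the mosquito category).  The catalogue follows the tables and the
results counts (12 + 4 + 7 = 23 omitted); the discrepancy is documented here
rather than resolved.

## Boundary conventions

The criteria quote thresholds without stating boundary semantics; the engine
fixes them once, and the tests assert them two-sidedly:

- **Age.** `age_years = days / 365.25`.  "Before *N* years" is strict: the
  *N*th birthday itself no longer satisfies it.  Age bands written as ranges
  ("up to five years of age") are closed below, open above.  Ages in
  prescription rules are taken at the prescription start date; omission
  contexts use the age at the evaluation date.
- **Dose.** `mg/kg/day = dose_amount x doses_per_day / weight_kg`, exact
  arithmetic, no rounding before comparison.  30 mg/kg/day exactly does not
  flag the ibuprofen rule; "more than three doses per day" means
  `doses_per_day >= 4`.
- **Duration.** Days elapsed from start to `min(end, as_of)`; an open end
  runs to the evaluation date.  "More than four weeks" excludes exactly 28
  days; "more than 48 h" excludes exactly 2 days.
- **Co-prescription.** Two orders of different generic drugs whose closed
  date intervals share at least one day.
- **Intervals.** Prescriptions are closed at both ends; conditions are
  active from onset to end (open end = ongoing).

## The condition-tree grammar

Each executable criterion carries a small predicate tree (JSON) interpreted
by the engine: `prescription` (selector + exception clauses),
`co_prescription`, `companion_omission` (anchor therapy lacking a required
companion, e.g. morphine beyond 48 h without an osmotic laxative),
`context_omission` (a patient context lacking a required therapy, optionally
at an age-banded dose — e.g. sickle-cell penicillin-V prophylaxis at
125/250/500 mg twice daily by age band), `repeat_omission` (a parasiticide
application not repeated 6–8 days later), `monitoring_omission`
(methylphenidate beyond 180 days with no weight measurement dated inside the
episode), and `any_of`.  Selectors combine drug identity and ontology class,
route, formulation, dose unit, mg/kg/day bounds, daily frequency, duration,
age at start, overlap with active coded conditions, indication links and
line of therapy.  Exception clauses express the criteria's "except ..."
conditions as qualifiers on the implicated condition (e.g. documented
clinical concern for sore throat, severe lichenification for eczema),
indication links (anaphylaxis), or age bounds (bilateral otitis under two).

## Automatability tiers and not-evaluable routing

Each criterion is assigned one of three tiers by a fixed rubric:

- **full** (59 criteria): decidable from drug, dose, dates, route,
  formulation, age, weight and coded conditions.  Qualifiers may appear only
  in exception clauses, where absence-by-default lets the rule fire.
- **conditional** (17): firing itself requires optional structured data — an
  indication link (all "first-line" rules, the prokinetic-erythromycin rule),
  a qualifier that must be *present* (palivizumab risk groups, severe
  gingivostomatitis, daytime enuresis symptoms, menstruating status), an
  inhaler device field, a topical application site, or recorded formula
  intake (Healthy Start vitamins: children on >= 500 mL/day of fortified
  formula are exempt, so intake must be known).
- **manual** (4): needs information outside the structured record —
  griseofulvin with a fatty meal, household decontamination for scabies,
  mg-per-mL labelling of oral-solution orders, and whether medication is the
  sole or primary anorexia treatment.

Evaluation routes undecidable cases rather than guessing: a dose rule with
no weight reports `missing_weight` (a non-mg unit reports `unit_mismatch`);
a conditional criterion whose candidate prescriptions or conditions are
present but lack the needed optional field reports `missing_indication` or
`missing_qualifier`; manual criteria always report `manual_tier`.  These
patients leave the prevalence denominator for that criterion, and both the
flagged and evaluable counts are reported so rates can be recomputed.

Scoping choice: category-bound drug rules (e.g. minocycline under acne,
antihistamines under asthma) require the coded category condition to be
active and overlapping the prescription; a handful of criteria are
unconditional where the inappropriateness is intrinsic in UK paediatrics
(pholcodine, decongestants, benzyl benzoate, metoclopramide, domperidone,
the tacrolimus and topical-aciclovir age limits, the ibuprofen dose cap,
loperamide under four).  Identically worded ORS omission criteria in the
vomiting and diarrhoea categories are scoped by their accompanying coded
context so each can fire independently.  Erythromycin as a prokinetic is
scoped to orders linked to a reflux/regurgitation indication; erythromycin
for infection never fires it.

## Drug ontology and vocabulary

The packaged ontology covers exactly the generics, brand synonyms and
pharmacological classes the criteria name (~115 entries); the synonym map is
case- and whitespace-insensitive and normalisation is idempotent.  Unknown
drug names become explicit markers that never satisfy class predicates; their
presence is surfaced in the screening notes so audits can quantify
suppression.  Condition codes and qualifiers form a deliberately minimal
controlled vocabulary (not SNOMED/dm+d): one code per clinical context the
criteria name, with boolean qualifiers for the exception clauses.  How such
conditions would be captured in real data is site-specific; the vocabulary is
an artifact convention.

## Synthetic cohorts

`CohortSpec` fixes the study conditions: number of patients, seed, uniform
age range (default 0.25–16 years), an age-linear weight model (~3.5 + 6·age
kg in infancy, 2·(age+4) kg thereafter) with ±10% noise, per-criterion
violation probabilities, and the evaluation date.  Clean records draw one or
two indication-linked episode templates (fever, otitis media treated after
observation with co-prescribed paracetamol, allergic rhinitis, asthma,
eczema), are screened internally, and are regenerated if any fully
automatable criterion fires — generation fails loudly rather than emit a
contaminated record.

`inject_violation` holds one recipe per fully automatable criterion.  Where
a recipe needs demographics the base record lacks (an age band, sex,
pregnancy), the returned record carries adjusted demographics and only the
injected content; injected entities are marked in record metadata.  Every
injection is verified to fire exactly the named criterion.  One criterion is
on the documented exclusion list: antibiotic monotherapy for acne logically
entails the missing-topical-treatment omission, so an isolated injection is
impossible; tests consume the list rather than special-case it.  In cohort
generation each patient receives each violation independently with its
configured probability; when two sampled violations cannot coexist on one
patient, the later-sampled one is skipped for that patient, so the returned
truth table always reflects exactly what was injected.

The generator emulates structure (plausible ages, weights, episodes,
indication links), not epidemiology: prevalences, seasonality, dosing error
distributions and coding noise of real prescribing data are out of scope.
Passing tests therefore demonstrate that the rules fire exactly when their
conditions hold in well-coded data — not what the tool would find in a real
service, where coding completeness drives the conditional tier.

## Verification

- Unit tests cover the elementary arithmetic, each boundary two-sidedly
  (30 mg/kg/day, the fourth birthday, 28 days, 48 h), evaluation routing,
  IO round trips, and the catalogue invariants (mutations are detected).
- An independent brute-force oracle re-derives flags for a representative
  criterion subset from first principles on random cohorts of <= 5 patients
  and <= 6 prescriptions; the engine agrees flag-for-flag.
- Inject-and-detect: on a seeded 100-patient cohort with every injectable
  criterion at rate 0.04, screening recovers the truth table exactly
  (sensitivity and specificity 1.0 on the full tier).
- Determinism: identical seeds produce byte-identical cohorts and flag
  files; the catalogue serialisation round-trips with an unchanged content
  checksum (SHA-256 over the canonical JSON).

Problem sizes (100-patient acceptance cohorts, 1 mg dose-scan steps,
day-resolution scans) keep the whole suite and the acceptance script within
a few seconds while exercising every criterion.

## Known limitations

- The tool's criteria bind to free-text clinical nuance ("first-line",
  "severe", "appropriate inhaler") that structured records only capture via
  the optional fields; in their absence the engine reports not-evaluable
  rather than guessing, which on sparse real data will shrink denominators.
- The cBNF per-age absolute ibuprofen maxima are retained as commentary
  only; the executable rule is the 30 mg/kg/day and >3 doses/day criterion.
- The provenance ledger records the original French texts only where the
  modification study printed them; the seven mosquito-category texts are
  placeholders marked as not reproduced.
- Weight is a single dated measurement; mg/kg arithmetic uses it regardless
  of distance from the evaluation date (the growth-monitoring rule is the
  only one that inspects the measurement date).
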