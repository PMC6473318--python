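"""Seeded synthetic paediatric prescribing cohorts with violation injection.

The generator produces clean-by-construction records (verified by screening
before emission) built from a small set of plausible indication-linked
episode templates, and can inject, per criterion, a configuration that fires
exactly that criterion.  Cohort generation returns a truth table of injected
(patient, criterion) pairs, so screening sensitivity and specificity on the
fully-automatable tier can be asserted exactly.

The generator aims at plausibility, not epidemiological calibration: ages are
uniform over the requested range and weight follows a simple age-linear model
with bounded noise, which is all the rule logic needs.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from popiuk.catalog import CriteriaCatalog, load_catalog
from popiuk.engine import screen_record
from popiuk.records import Condition, DrugOntology, PatientRecord, Prescription, load_ontology, normalize_record

#: Full-tier criteria whose violating configuration necessarily fires a
#: second full-tier criterion, so exactly-one-flag injection is impossible.
#: (Antibiotic monotherapy for acne logically entails the absence of the
#: topical treatment that the companion omission criterion requires.)
INJECTION_EXCLUSIONS: dict[str, str] = {
    "ACN-IP-03": "an antibiotic-monotherapy violation always also fires the "
                 "missing-topical-treatment omission ACN-OM-02",
}

DEFAULT_AS_OF = date(2023, 6, 30)


class SynthError(RuntimeError):
    pass


class CohortSpec(BaseModel):
    """Parameters of a synthetic cohort."""

    n_patients: int = Field(ge=0)
    seed: int = 0
    age_range: tuple[float, float] = (0.25, 16.0)
    weight_noise_frac: float = Field(default=0.1, ge=0, le=0.5)
    violation_rates: dict[str, float] = Field(default_factory=dict)
    as_of: date = DEFAULT_AS_OF

    @model_validator(mode="after")
    def _ranges(self) -> "CohortSpec":
        lo, hi = self.age_range
        if not (0 <= lo <= hi <= 18):
            raise ValueError("age_range must lie within 0-18 years")
        bad = {k: v for k, v in self.violation_rates.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"violation rates outside [0, 1]: {bad}")
        return self


def _mean_weight_kg(age_years: float) -> float:
    # rough paediatric rule of thumb: ~4 kg + 2 kg/year in infancy, 2(age+4) later
    if age_years < 1:
        return 3.5 + 6.0 * age_years
    return 2.0 * (age_years + 4.0)


def _d(as_of: date, days_before: float) -> date:
    return as_of - timedelta(days=int(days_before))


# ---------------------------------------------------------------------------
# Clean episode templates
# ---------------------------------------------------------------------------

def _max_back(rec: PatientRecord, as_of: date) -> int:
    """Longest permissible look-back (days) for an episode, given the age."""
    return max((as_of - rec.date_of_birth).days - 21, 15)


def _template_fever(rec: PatientRecord, as_of: date, rng: np.random.Generator, n: int) -> None:
    onset = min(int(rng.integers(120, 360)), _max_back(rec, as_of))
    rec.conditions.append(Condition(code="fever", onset=_d(as_of, onset), end=_d(as_of, onset - 4)))
    rec.prescriptions.append(Prescription(
        rx_id=f"rx{n}", drug="paracetamol", dose_amount=240, dose_unit="mg",
        doses_per_day=3, route="oral", start=_d(as_of, onset), end=_d(as_of, onset - 3),
        indication="fever",
    ))


def _template_aom(rec: PatientRecord, as_of: date, rng: np.random.Generator, n: int) -> None:
    # antibiotic deferred >=4 days from onset, paracetamol co-prescribed
    onset = min(int(rng.integers(150, 400)), _max_back(rec, as_of))
    rec.conditions.append(Condition(code="acute_otitis_media", onset=_d(as_of, onset),
                                    end=_d(as_of, onset - 12)))
    rec.prescriptions.append(Prescription(
        rx_id=f"rx{n}", drug="amoxicillin", dose_amount=250, dose_unit="mg",
        doses_per_day=3, route="oral", start=_d(as_of, onset - 5), end=_d(as_of, onset - 10),
        indication="acute_otitis_media",
    ))
    rec.prescriptions.append(Prescription(
        rx_id=f"rx{n + 1}", drug="paracetamol", dose_amount=240, dose_unit="mg",
        doses_per_day=3, route="oral", start=_d(as_of, onset - 4), end=_d(as_of, onset - 10),
        indication="acute_otitis_media",
    ))


def _template_rhinitis(rec: PatientRecord, as_of: date, rng: np.random.Generator, n: int) -> None:
    onset = min(int(rng.integers(30, 200)), _max_back(rec, as_of))
    rec.conditions.append(Condition(code="allergic_rhinitis", onset=_d(as_of, onset)))
    rec.prescriptions.append(Prescription(
        rx_id=f"rx{n}", drug="cetirizine", dose_amount=5, dose_unit="mg",
        doses_per_day=1, route="oral", start=_d(as_of, onset - 2),
        indication="allergic_rhinitis",
    ))


def _template_asthma(rec: PatientRecord, as_of: date, rng: np.random.Generator, n: int) -> None:
    onset = min(int(rng.integers(200, 600)), _max_back(rec, as_of))
    rec.conditions.append(Condition(code="asthma", onset=_d(as_of, onset)))
    rec.prescriptions.append(Prescription(
        rx_id=f"rx{n}", drug="salbutamol", dose_amount=100, dose_unit="mg",
        doses_per_day=2, route="inhaled", device="pmdi_spacer",
        start=_d(as_of, onset - 3), indication="asthma",
    ))


def _template_eczema(rec: PatientRecord, as_of: date, rng: np.random.Generator, n: int) -> None:
    onset = min(int(rng.integers(200, 600)), _max_back(rec, as_of))
    rec.conditions.append(Condition(code="atopic_eczema", onset=_d(as_of, onset)))
    rec.prescriptions.append(Prescription(
        rx_id=f"rx{n}", drug="emollient", dose_amount=1, dose_unit="applications",
        doses_per_day=2, route="topical", start=_d(as_of, onset - 2),
        indication="atopic_eczema",
    ))


_TEMPLATES = [
    ("fever", _template_fever, 0.0),
    ("aom", _template_aom, 0.0),
    ("rhinitis", _template_rhinitis, 2.0),   # min age: cetirizine licensing
    ("asthma", _template_asthma, 5.0),
    ("eczema", _template_eczema, 0.5),
]


def generate_clean_record(
    spec: CohortSpec,
    rng: np.random.Generator,
    patient_id: str = "p0001",
    catalog: Optional[CriteriaCatalog] = None,
    ontology: Optional[DrugOntology] = None,
    max_attempts: int = 10,
) -> PatientRecord:
    """One plausible record that triggers zero fully-automatable criteria.

    Each candidate is screened before emission; a record that flags is
    regenerated, and repeated failure raises loudly rather than emitting a
    contaminated "clean" record.
    """
    catalog = catalog or load_catalog()
    ontology = ontology or load_ontology()
    for _ in range(max_attempts):
        age = float(rng.uniform(*spec.age_range))
        dob = spec.as_of - timedelta(days=int(age * 365.25))
        weight = _mean_weight_kg(age) * float(1 + rng.uniform(-spec.weight_noise_frac, spec.weight_noise_frac))
        rec = PatientRecord(
            patient_id=patient_id,
            date_of_birth=dob,
            sex="female" if rng.random() < 0.5 else "male",
            weight_kg=round(weight, 1),
            weight_date=_d(spec.as_of, int(rng.integers(0, 60))),
        )
        eligible = [t for t in _TEMPLATES if age >= t[2]]
        k = int(rng.integers(1, 3))
        picks = rng.choice(len(eligible), size=min(k, len(eligible)), replace=False)
        n = 1
        for idx in sorted(int(i) for i in picks):
            eligible[idx][1](rec, spec.as_of, rng, n)
            n += 2
        normalize_record(rec, ontology)
        result = screen_record(rec, catalog, as_of=spec.as_of, ontology=ontology)
        full_flags = [f for f in result.flags
                      if catalog.criterion(f.criterion_id).automatability == "full"]
        if not full_flags:
            return rec
    raise SynthError(f"could not generate a clean record for {patient_id} "
                     f"after {max_attempts} attempts")


# ---------------------------------------------------------------------------
# Violation injection recipes
# ---------------------------------------------------------------------------
# Each recipe: optional demographic requirements and the conditions /
# prescriptions that constitute the violating configuration.  Prescription
# times are expressed in days before the evaluation date.

def _rx(drug, dose, unit="mg", per_day=1, route="oral", formulation=None,
        start=30, end=20, indication=None, device=None, site=None):
    return dict(drug=drug, dose=dose, unit=unit, per_day=per_day, route=route,
                formulation=formulation, start=start, end=end,
                indication=indication, device=device, site=site)


def _cond(code, onset=40, end=None, qualifiers=()):
    return dict(code=code, onset=onset, end=end, qualifiers=tuple(qualifiers))


# age: (min, max) in years the recipe is valid for; None = any paediatric age.
RECIPES: dict[str, dict] = {
    "PAF-IP-03": dict(age=(6.0, 16.0),
                      rxs=[_rx("ibuprofen", 100, per_day=3, start=10, end=3),
                           _rx("naproxen", 125, per_day=2, start=8, end=2)]),
    "PAF-IP-04": dict(rxs=[_rx("ibuprofen", 200, per_day=4, start=6, end=2)]),
    "PAF-OM-01": dict(rxs=[_rx("morphine", 10, per_day=4, start=6, end=None)]),
    "VIT-OM-02": dict(age=(0.5, 4.5),
                      conds=[_cond("sickle_cell_anaemia", onset=300)]),
    "NVG-IP-01": dict(rxs=[_rx("metoclopramide", 5, per_day=3)]),
    "NVG-IP-02": dict(rxs=[_rx("domperidone", 5, per_day=3)]),
    "NVG-IP-03": dict(rxs=[_rx("omeprazole", 10, per_day=1, route="oral",
                               formulation="intravenous_preparation")]),
    "NVG-IP-05": dict(age=(6.0, 16.0),
                      rxs=[_rx("omeprazole", 10, per_day=1, start=12, end=2),
                           _rx("ibuprofen", 100, per_day=3, start=12, end=2)]),
    "NVG-IP-06": dict(rxs=[_rx("ranitidine", 75, per_day=2, start=40, end=None)]),
    "NVG-OM-01": dict(conds=[_cond("dehydration", onset=2), _cond("vomiting", onset=3)]),
    "DIA-IP-01": dict(age=(0.5, 3.9), rxs=[_rx("loperamide", 2, per_day=3, start=5, end=2)]),
    "DIA-IP-02": dict(age=(4.5, 16.0),
                      conds=[_cond("diarrhoea_invasive", onset=6)],
                      rxs=[_rx("loperamide", 2, per_day=3, start=5, end=2)]),
    "DIA-OM-01": dict(conds=[_cond("dehydration", onset=2), _cond("diarrhoea", onset=4)]),
    "COU-IP-01": dict(rxs=[_rx("pholcodine", 5, per_day=3, start=6, end=1)]),
    "COU-OM-01": dict(age=(14.0, 17.9), sex="female", pregnant=True),
    "BRO-IP-01": dict(age=(0.1, 1.5), conds=[_cond("bronchiolitis", onset=5)],
                      rxs=[_rx("salbutamol", 100, per_day=4, route="inhaled",
                               start=4, end=None, device="nebuliser")]),
    "BRO-IP-02": dict(age=(0.1, 1.5), conds=[_cond("bronchiolitis", onset=5)],
                      rxs=[_rx("carbocisteine", 100, per_day=3, start=4, end=None)]),
    "ENT-IP-01": dict(conds=[_cond("acute_otitis_media", onset=2)],
                      rxs=[_rx("amoxicillin", 250, per_day=3, start=1, end=None,
                               indication="acute_otitis_media"),
                           _rx("paracetamol", 240, per_day=3, start=1, end=None,
                               indication="acute_otitis_media")]),
    "ENT-IP-02": dict(conds=[_cond("sore_throat", onset=10)],
                      rxs=[_rx("phenoxymethylpenicillin", 250, per_day=4,
                               start=5, end=None, indication="sore_throat")]),
    "ENT-IP-03": dict(conds=[_cond("otitis_media_with_effusion", onset=30)],
                      rxs=[_rx("amoxicillin", 250, per_day=3, start=20, end=13,
                               indication="otitis_media_with_effusion")]),
    "ENT-IP-04": dict(conds=[_cond("nasopharyngitis", onset=6)],
                      rxs=[_rx("prednisolone", 20, per_day=1, start=5, end=1)]),
    "ENT-IP-05": dict(rxs=[_rx("pseudoephedrine", 30, per_day=3, start=6, end=2)]),
    "ENT-IP-06": dict(age=(0.2, 1.9), rxs=[_rx("chlorphenamine", 1, per_day=2, start=6, end=2)]),
    "ENT-IP-07": dict(conds=[_cond("acute_otitis_media", onset=6)],
                      rxs=[_rx("olive_oil_eardrops", 2, unit="applications",
                               per_day=2, route="eardrops", start=5, end=None)]),
    "ENT-OM-01": dict(rxs=[_rx("amoxicillin", 5, unit="mL", per_day=3,
                               formulation="drinkable_solution", start=6, end=1)]),
    "ENT-OM-02": dict(conds=[_cond("acute_otitis_media", onset=10)],
                      rxs=[_rx("amoxicillin", 250, per_day=3, start=5, end=None,
                               indication="acute_otitis_media")]),
    "AST-IP-01": dict(age=(3.0, 16.0), conds=[_cond("asthma", onset=200)],
                      rxs=[_rx("loratadine", 5, per_day=1, start=10, end=None)]),
    "AST-IP-02": dict(age=(3.0, 16.0), conds=[_cond("asthma", onset=200)],
                      rxs=[_rx("dextromethorphan", 10, per_day=3, start=6, end=None)]),
    "AST-OM-02": dict(age=(2.0, 16.0), conds=[_cond("persistent_asthma", onset=200)],
                      rxs=[_rx("salbutamol", 100, per_day=2, route="inhaled",
                               start=60, end=None, device="pmdi_spacer")]),
    "ACN-IP-01": dict(age=(12.0, 17.5), conds=[_cond("acne_vulgaris", onset=120)],
                      rxs=[_rx("minocycline", 100, per_day=1, start=30, end=None,
                               indication="acne_vulgaris"),
                           _rx("benzoyl_peroxide", 1, unit="applications", per_day=1,
                               route="topical", start=30, end=None)]),
    "ACN-IP-02": dict(age=(12.0, 17.5), conds=[_cond("acne_vulgaris", onset=120)],
                      rxs=[_rx("lymecycline", 408, per_day=1, start=30, end=None),
                           _rx("clindamycin", 1, unit="applications", per_day=1,
                               route="topical", start=30, end=None),
                           _rx("benzoyl_peroxide", 1, unit="applications", per_day=1,
                               route="topical", start=30, end=None)]),
    "ACN-IP-04": dict(age=(13.0, 17.5), sex="female",
                      rxs=[_rx("co_cyprindiol", 1, unit="applications", per_day=1,
                               start=60, end=None),
                           _rx("isotretinoin", 20, per_day=1, start=50, end=None)]),
    "ACN-OM-02": dict(age=(12.0, 17.5), conds=[_cond("acne_vulgaris", onset=120)],
                      rxs=[_rx("lymecycline", 408, per_day=1, start=30, end=None),
                           _rx("azelaic_acid", 1, unit="applications", per_day=2,
                               route="topical", start=30, end=None)]),
    "SCA-IP-01": dict(conds=[_cond("scabies", onset=10)],
                      rxs=[_rx("benzyl_benzoate", 1, unit="applications", per_day=1,
                               route="topical", start=8, end=8)]),
    "SCA-OM-01": dict(conds=[_cond("scabies", onset=16)],
                      rxs=[_rx("permethrin", 1, unit="applications", per_day=1,
                               route="topical", start=14, end=14)]),
    "LIC-IP-01": dict(age=(0.2, 1.9), conds=[_cond("head_lice", onset=6)],
                      rxs=[_rx("malathion", 1, unit="applications", per_day=1,
                               route="topical", formulation="aerosol",
                               start=4, end=4)]),
    "RIN-IP-01": dict(conds=[_cond("ringworm_microsporum", onset=30)],
                      rxs=[_rx("terbinafine", 125, per_day=1, start=20, end=None),
                           _rx("clotrimazole", 1, unit="applications", per_day=2,
                               route="topical", start=20, end=None)]),
    "RIN-OM-01": dict(conds=[_cond("ringworm_microsporum", onset=30)],
                      rxs=[_rx("griseofulvin", 250, per_day=1, start=20, end=None)]),
    "IMP-IP-01": dict(conds=[_cond("impetigo", onset=10)],
                      rxs=[_rx("flucloxacillin", 250, per_day=4, start=8, end=1),
                           _rx("fusidic_acid", 1, unit="applications", per_day=3,
                               route="topical", start=8, end=1)]),
    "IMP-IP-02": dict(conds=[_cond("impetigo", onset=10)],
                      rxs=[_rx("fusidic_acid", 1, unit="applications", per_day=1,
                               route="topical", start=8, end=1)]),
    "HER-IP-01": dict(conds=[_cond("herpes_simplex", onset=8)],
                      rxs=[_rx("hydrocortisone_topical", 1, unit="applications",
                               per_day=1, route="topical", start=6, end=None),
                           _rx("paracetamol", 240, per_day=3, start=6, end=None)]),
    "HER-IP-02": dict(age=(1.0, 5.9),
                      rxs=[_rx("aciclovir", 1, unit="applications", per_day=5,
                               route="topical", start=6, end=1)]),
    "HER-OM-01": dict(conds=[_cond("herpetic_gingivostomatitis", onset=4)]),
    "ECZ-IP-02": dict(conds=[_cond("atopic_eczema", onset=200)],
                      rxs=[_rx("hydrocortisone_topical", 1, unit="applications",
                               per_day=2, route="topical", start=10, end=None)]),
    "ECZ-IP-03": dict(conds=[_cond("atopic_eczema", onset=200)],
                      rxs=[_rx("loratadine", 5, per_day=1, start=10, end=None)]),
    "ECZ-IP-04": dict(age=(0.2, 1.9),
                      rxs=[_rx("tacrolimus_0_03", 1, unit="applications", per_day=1,
                               route="topical", start=10, end=None)]),
    "ECZ-IP-05": dict(age=(2.5, 15.5),
                      rxs=[_rx("tacrolimus_0_1", 1, unit="applications", per_day=1,
                               route="topical", start=10, end=None)]),
    "ECZ-IP-06": dict(conds=[_cond("atopic_eczema", onset=200)],
                      rxs=[_rx("prednisolone", 20, per_day=1, start=8, end=2)]),
    "EPI-IP-01": dict(conds=[_cond("epilepsy_myoclonic", onset=300)],
                      rxs=[_rx("carbamazepine", 100, per_day=2, start=60, end=None)]),
    "EPI-IP-02": dict(conds=[_cond("epilepsy_absence", onset=300)],
                      rxs=[_rx("carbamazepine", 100, per_day=2, start=60, end=None)]),
    "DEP-IP-02": dict(age=(10.0, 17.5), conds=[_cond("depression", onset=120)],
                      rxs=[_rx("amitriptyline", 25, per_day=1, start=30, end=None)]),
    "ENU-IP-01": dict(age=(5.0, 15.0), conds=[_cond("nocturnal_enuresis", onset=200)],
                      rxs=[_rx("desmopressin", 10, unit="applications", per_day=1,
                               route="nasal", formulation="spray", start=30, end=None)]),
    "ENU-IP-03": dict(age=(5.0, 15.0), conds=[_cond("nocturnal_enuresis", onset=200)],
                      rxs=[_rx("oxybutynin", 5, per_day=2, start=30, end=None)]),
    "ENU-IP-04": dict(age=(5.0, 15.0), conds=[_cond("nocturnal_enuresis", onset=200)],
                      rxs=[_rx("imipramine", 25, per_day=1, start=30, end=None),
                           _rx("oxybutynin", 5, per_day=2, start=30, end=None)]),
    "ADH-IP-01": dict(age=(3.0, 5.9), conds=[_cond("adhd", onset=200)],
                      rxs=[_rx("methylphenidate", 5, per_day=1, start=30, end=None)]),
    "ADH-IP-02": dict(age=(6.0, 16.0), conds=[_cond("adhd", onset=300)],
                      rxs=[_rx("risperidone", 0.5, per_day=1, start=30, end=None)]),
    "ADH-IP-03": dict(age=(6.0, 16.0), conds=[_cond("adhd", onset=300)],
                      rxs=[_rx("methylphenidate", 18, per_day=2,
                               formulation="modified_release", start=30, end=None)]),
    "ADH-OM-01": dict(age=(6.0, 16.0), conds=[_cond("adhd", onset=400)],
                      rxs=[_rx("methylphenidate", 10, per_day=1, start=200, end=None)],
                      weight_days_before=250),
}


def injectable_criteria(catalog: Optional[CriteriaCatalog] = None) -> list[str]:
    """Full-tier criteria for which an isolated violation can be injected."""
    catalog = catalog or load_catalog()
    return sorted(c.id for c in catalog.by_tier("full") if c.id not in INJECTION_EXCLUSIONS)


def _apply_recipe(rec: PatientRecord, criterion_id: str, as_of: date) -> PatientRecord:
    recipe = RECIPES[criterion_id]
    payload = rec.model_dump()
    age_req = recipe.get("age")
    if age_req is not None:
        age_now = (as_of - rec.date_of_birth).days / 365.25
        if not (age_req[0] <= age_now < age_req[1]):
            mid = (age_req[0] + age_req[1]) / 2
            payload["date_of_birth"] = as_of - timedelta(days=int(mid * 365.25))
            # existing episodes may predate the new date of birth: rebuild bare
            payload["conditions"] = []
            payload["prescriptions"] = []
    if "sex" in recipe:
        payload["sex"] = recipe["sex"]
    if recipe.get("pregnant"):
        payload["pregnant"] = True
    if "weight_days_before" in recipe:
        payload["weight_date"] = _d(as_of, recipe["weight_days_before"])
    rec = PatientRecord.model_validate(payload)

    injected: list[str] = []
    for cspec in recipe.get("conds", []):
        rec.conditions.append(Condition(
            code=cspec["code"], onset=_d(as_of, cspec["onset"]),
            end=_d(as_of, cspec["end"]) if cspec["end"] is not None else None,
            qualifiers=frozenset(cspec["qualifiers"]),
        ))
        injected.append(f"cond:{cspec['code']}")
    seq = len(rec.prescriptions) + 1
    for rspec in recipe.get("rxs", []):
        rx_id = f"inj-{criterion_id}-{seq}"
        seq += 1
        rec.prescriptions.append(Prescription(
            rx_id=rx_id, drug=rspec["drug"], dose_amount=rspec["dose"],
            dose_unit=rspec["unit"], doses_per_day=rspec["per_day"],
            route=rspec["route"], formulation=rspec["formulation"],
            start=_d(as_of, rspec["start"]),
            end=_d(as_of, rspec["end"]) if rspec["end"] is not None else None,
            indication=rspec["indication"], device=rspec["device"],
            site=rspec["site"],
        ))
        injected.append(f"rx:{rx_id}")
    rec.meta.setdefault("injected", {})[criterion_id] = injected
    return rec


def inject_violation(
    record: PatientRecord,
    criterion_id: str,
    as_of: date = DEFAULT_AS_OF,
    catalog: Optional[CriteriaCatalog] = None,
    ontology: Optional[DrugOntology] = None,
    verify: bool = True,
) -> PatientRecord:
    """Return a copy of ``record`` that fires exactly ``criterion_id``.

    Only fully-automatable criteria outside :data:`INJECTION_EXCLUSIONS` are
    injectable.  When the recipe needs demographics the record does not have
    (age band, sex, pregnancy), the returned record carries adjusted
    demographics and only the injected clinical content.  The injected
    entities are listed under ``record.meta['injected']``.
    """
    catalog = catalog or load_catalog()
    ontology = ontology or load_ontology()
    criterion = catalog.criterion(criterion_id)
    if criterion.automatability != "full":
        raise SynthError(f"{criterion_id} is {criterion.automatability}-tier; only "
                         "fully-automatable criteria support injection")
    if criterion_id in INJECTION_EXCLUSIONS:
        raise SynthError(f"{criterion_id} is on the injection exclusion list: "
                         f"{INJECTION_EXCLUSIONS[criterion_id]}")
    if criterion_id not in RECIPES:
        raise SynthError(f"no injection recipe for {criterion_id}")

    candidate = _apply_recipe(record.model_copy(deep=True), criterion_id, as_of)
    normalize_record(candidate, ontology)
    if verify:
        fired = _full_tier_flags(candidate, catalog, as_of, ontology)
        if fired != {criterion_id}:
            # interference from the base record's own episodes: rebuild bare
            bare = PatientRecord(
                patient_id=record.patient_id, date_of_birth=record.date_of_birth,
                sex=record.sex, pregnant=record.pregnant,
                weight_kg=record.weight_kg, weight_date=record.weight_date,
                formula_ml_per_day=record.formula_ml_per_day,
            )
            candidate = _apply_recipe(bare, criterion_id, as_of)
            normalize_record(candidate, ontology)
            fired = _full_tier_flags(candidate, catalog, as_of, ontology)
            if fired != {criterion_id}:
                raise SynthError(
                    f"injection for {criterion_id} fired {sorted(fired)} instead")
    return candidate


def _full_tier_flags(rec: PatientRecord, catalog: CriteriaCatalog, as_of: date,
                     ontology: DrugOntology) -> set[str]:
    result = screen_record(rec, catalog, as_of=as_of, ontology=ontology)
    return {f.criterion_id for f in result.flags
            if catalog.criterion(f.criterion_id).automatability == "full"}


def generate_cohort(
    spec: CohortSpec,
    catalog: Optional[CriteriaCatalog] = None,
    ontology: Optional[DrugOntology] = None,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a cohort plus the exact truth table of injected violations.

    Each patient independently receives each configured violation with its
    probability.  Every record is verified after injection: the set of fired
    fully-automatable criteria equals the truth-table entries for that
    patient.  When two sampled violations cannot coexist on one patient
    (incompatible demographics or logical interference), the later-sampled
    one is skipped for that patient — the truth table always reflects what
    was actually injected.  Fully reproducible from the seed.
    """
    catalog = catalog or load_catalog()
    ontology = ontology or load_ontology()
    injectable = set(injectable_criteria(catalog))
    bad = sorted(set(spec.violation_rates) - injectable)
    if bad:
        raise SynthError(f"violation rates configured for non-injectable criteria: {bad}")

    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    truth_rows: list[dict] = []
    rate_items = sorted(spec.violation_rates.items())
    for i in range(spec.n_patients):
        pid = f"p{i + 1:04d}"
        rec = generate_clean_record(spec, rng, patient_id=pid,
                                    catalog=catalog, ontology=ontology)
        sampled = [cid for cid, rate in rate_items if rng.random() < rate]
        applied: list[str] = []
        for cid in sampled:
            candidate = inject_violation(rec, cid, as_of=spec.as_of,
                                         catalog=catalog, ontology=ontology,
                                         verify=False)
            normalize_record(candidate, ontology)
            fired = _full_tier_flags(candidate, catalog, spec.as_of, ontology)
            if fired == set(applied) | {cid}:
                rec = candidate
                applied.append(cid)
            elif not applied:
                # fall back to a bare rebuild for the first violation
                try:
                    rec2 = inject_violation(rec, cid, as_of=spec.as_of,
                                            catalog=catalog, ontology=ontology)
                    rec = rec2
                    applied.append(cid)
                except SynthError:
                    pass
        for cid in applied:
            truth_rows.append({"patient_id": pid, "criterion_id": cid})
        records.append(rec)
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "criterion_id"])
    return records, truth
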