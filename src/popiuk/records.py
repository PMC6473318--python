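"""Patient prescribing records, the minimal drug ontology, and file IO.

The data model is deliberately small: one child per :class:`PatientRecord`,
with demographics, a single dated weight measurement, coded clinical
conditions carrying boolean qualifiers, and dated prescriptions.  Condition
codes and qualifiers come from a packaged controlled vocabulary; drug names
resolve through a packaged ontology of generic names, brand synonyms, and
pharmacological classes.  The vocabulary covers exactly the clinical contexts
the criteria catalogue references — it is not a general terminology.

CSV schemas (UTF-8, comma-separated, header row mandatory)
----------------------------------------------------------
patients.csv
    patient_id, date_of_birth, sex, pregnant, weight_kg, weight_date,
    formula_ml_per_day
conditions.csv
    patient_id, code, onset, end, qualifiers  (semicolon-joined tokens)
prescriptions.csv
    patient_id, rx_id, drug, dose_amount, dose_unit, doses_per_day, route,
    formulation, start, end, indication_code, device, site

JSON equivalents use the same field names (one array per file).  All dates
are ISO-8601 calendar dates; an empty ``end`` means ongoing.
"""

from __future__ import annotations

import json
import warnings
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

UNKNOWN_DRUG_PREFIX = "unknown_drug:"

ROUTES = {"oral", "topical", "nasal", "rectal", "inhaled", "parenteral", "eardrops", "other"}
FORMULATIONS = {
    "standard",
    "modified_release",
    "drinkable_solution",
    "aerosol",
    "spray",
    "suppository",
    "intravenous_preparation",
}
DEVICES = {"pmdi_spacer", "pmdi_no_spacer", "nebuliser", "dpi"}
SITES = {"face", "axilla", "groin", "trunk", "limbs", "scalp", "nappy_area"}
SEXES = {"female", "male", "unknown"}


class RecordError(ValueError):
    """A patient record or cohort file violates the documented schema."""


class Condition(BaseModel):
    """A coded clinical condition with boolean qualifiers."""

    code: str
    onset: date
    end: Optional[date] = None
    qualifiers: frozenset[str] = frozenset()

    @model_validator(mode="after")
    def _order(self) -> "Condition":
        if self.end is not None and self.end < self.onset:
            raise ValueError(f"condition {self.code}: end {self.end} before onset {self.onset}")
        return self

    def active_on(self, day: date) -> bool:
        return self.onset <= day and (self.end is None or day <= self.end)


class Prescription(BaseModel):
    """A dated drug order.

    ``drug`` is the raw prescribed name; ``drug_norm`` is filled in by
    ontology normalisation.  The interval is closed at both ends; an open
    ``end`` means ongoing as of the evaluation date.  ``indication`` links
    the order to a condition *code* on the same record; ``line_of_therapy``
    is derived (1 = earliest order for that indication episode).
    """

    rx_id: str
    drug: str
    drug_norm: str = ""
    dose_amount: float = Field(ge=0)
    dose_unit: str = "mg"
    doses_per_day: int = Field(ge=1)
    route: str = "oral"
    formulation: Optional[str] = None
    start: date
    end: Optional[date] = None
    indication: Optional[str] = None
    device: Optional[str] = None
    site: Optional[str] = None
    line_of_therapy: Optional[int] = None

    @field_validator("route")
    @classmethod
    def _route(cls, v: str) -> str:
        if v not in ROUTES:
            raise ValueError(f"unknown route {v!r}; expected one of {sorted(ROUTES)}")
        return v

    @field_validator("formulation")
    @classmethod
    def _formulation(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in FORMULATIONS:
            raise ValueError(f"unknown formulation {v!r}")
        return v

    @field_validator("device")
    @classmethod
    def _device(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in DEVICES:
            raise ValueError(f"unknown device {v!r}")
        return v

    @field_validator("site")
    @classmethod
    def _site(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in SITES:
            raise ValueError(f"unknown application site {v!r}")
        return v

    @model_validator(mode="after")
    def _order(self) -> "Prescription":
        if self.end is not None and self.end < self.start:
            raise ValueError(f"prescription {self.rx_id}: end {self.end} before start {self.start}")
        return self

    def interval(self, as_of: date) -> tuple[date, date]:
        """Closed evaluation interval [start, min(end, as_of)]."""
        stop = self.end if self.end is not None and self.end < as_of else as_of
        return self.start, stop


class PatientRecord(BaseModel):
    """Demographics, weight, conditions, and prescriptions for one child."""

    patient_id: str
    date_of_birth: date
    sex: str = "unknown"
    pregnant: bool = False
    weight_kg: Optional[float] = Field(default=None, gt=0)
    weight_date: Optional[date] = None
    formula_ml_per_day: Optional[float] = Field(default=None, ge=0)
    conditions: list[Condition] = Field(default_factory=list)
    prescriptions: list[Prescription] = Field(default_factory=list)
    meta: dict = Field(default_factory=dict)

    @field_validator("sex")
    @classmethod
    def _sex(cls, v: str) -> str:
        if v not in SEXES:
            raise ValueError(f"unknown sex {v!r}")
        return v

    @model_validator(mode="after")
    def _chronology(self) -> "PatientRecord":
        for p in self.prescriptions:
            if p.start < self.date_of_birth:
                raise ValueError(
                    f"patient {self.patient_id}: prescription {p.rx_id} starts before date of birth"
                )
        return self

    def latest_date(self) -> date:
        """Latest calendar date present anywhere in the record."""
        days = [self.date_of_birth]
        for c in self.conditions:
            days.append(c.onset)
            if c.end:
                days.append(c.end)
        for p in self.prescriptions:
            days.append(p.start)
            if p.end:
                days.append(p.end)
        if self.weight_date:
            days.append(self.weight_date)
        return max(days)


def assign_lines_of_therapy(record: PatientRecord) -> None:
    """Derive ``line_of_therapy`` per indication episode, in place.

    The earliest prescription linked to a given indication code is line 1;
    ties on start date break by rx_id order (deterministic, reported as-is).
    Unlinked prescriptions keep ``line_of_therapy = None``.
    """
    by_indication: dict[str, list[Prescription]] = {}
    for p in record.prescriptions:
        if p.indication:
            by_indication.setdefault(p.indication, []).append(p)
    for group in by_indication.values():
        group.sort(key=lambda p: (p.start, p.rx_id))
        for i, p in enumerate(group, start=1):
            p.line_of_therapy = i


# ---------------------------------------------------------------------------
# Drug ontology
# ---------------------------------------------------------------------------

class DrugOntology(BaseModel):
    """Generic-name ontology: synonyms and pharmacological classes.

    The synonym map is flattened and case/whitespace-insensitive.  The
    packaged ontology covers exactly the drugs and classes the criteria
    catalogue names (plus the brand synonyms the source tables quote); a
    site can extend it with an overlay file of the same shape.
    """

    entries: dict[str, dict] = Field(default_factory=dict)

    _synonym_index: dict[str, str] = {}

    def model_post_init(self, __context) -> None:
        index: dict[str, str] = {}
        for generic, entry in self.entries.items():
            index[_clean(generic)] = generic
            for syn in entry.get("synonyms", []):
                key = _clean(syn)
                existing = index.get(key)
                if existing is not None and existing != generic:
                    raise RecordError(f"synonym {syn!r} maps to both {existing!r} and {generic!r}")
                index[key] = generic
        object.__setattr__(self, "_synonym_index", index)

    def classes_of(self, generic: str) -> frozenset[str]:
        entry = self.entries.get(generic)
        return frozenset(entry.get("classes", [])) if entry else frozenset()

    def known_classes(self) -> frozenset[str]:
        out: set[str] = set()
        for entry in self.entries.values():
            out.update(entry.get("classes", []))
        return frozenset(out)


def _clean(name: str) -> str:
    return " ".join(name.strip().lower().split())


def normalize_drug(raw_name: str, ontology: DrugOntology) -> str:
    """Resolve a raw drug name to its generic name through the synonym map.

    Unresolvable names return a marked ``unknown_drug:<cleaned>`` token so
    they are never silently dropped; the function is idempotent.
    """
    if raw_name.startswith(UNKNOWN_DRUG_PREFIX):
        return raw_name
    cleaned = _clean(raw_name)
    generic = ontology._synonym_index.get(cleaned)
    if generic is not None:
        return generic
    return UNKNOWN_DRUG_PREFIX + cleaned


def is_unknown_drug(name: str) -> bool:
    return name.startswith(UNKNOWN_DRUG_PREFIX)


def drug_in_class(generic: str, class_name: str, ontology: DrugOntology) -> bool:
    """True iff the ontology assigns ``class_name`` to ``generic``.

    Unknown-drug markers are never in any class.  An unrecognised class name
    is a configuration error, not a quiet False.
    """
    if class_name not in ontology.known_classes():
        raise RecordError(f"unknown drug class {class_name!r}")
    if is_unknown_drug(generic):
        return False
    return class_name in ontology.classes_of(generic)


def _data_path(name: str):
    return resources.files("popiuk").joinpath("data", name)


def load_ontology(path: Optional[str | Path] = None, overlay: Optional[str | Path] = None) -> DrugOntology:
    """Load the packaged drug ontology, optionally merged with an overlay.

    Overlay entries extend or replace packaged entries by generic name.
    """
    if path is None:
        payload = json.loads(_data_path("ontology.json").read_text())
    else:
        payload = json.loads(Path(path).read_text())
    entries = dict(payload["entries"])
    if overlay is not None:
        extra = json.loads(Path(overlay).read_text())
        for generic, entry in extra.get("entries", {}).items():
            entries[generic] = entry
    return DrugOntology(entries=entries)


def load_vocabulary() -> dict:
    """Packaged condition-code vocabulary and qualifier list."""
    return json.loads(_data_path("vocabulary.json").read_text())


def normalize_record(record: PatientRecord, ontology: DrugOntology) -> PatientRecord:
    """Fill in drug_norm and line_of_therapy on a record, in place."""
    for p in record.prescriptions:
        p.drug_norm = normalize_drug(p.drug, ontology)
    assign_lines_of_therapy(record)
    return record


# ---------------------------------------------------------------------------
# Cohort file IO
# ---------------------------------------------------------------------------

_PATIENT_COLS = ["patient_id", "date_of_birth", "sex", "pregnant", "weight_kg", "weight_date", "formula_ml_per_day"]
_CONDITION_COLS = ["patient_id", "code", "onset", "end", "qualifiers"]
_RX_COLS = [
    "patient_id", "rx_id", "drug", "dose_amount", "dose_unit", "doses_per_day",
    "route", "formulation", "start", "end", "indication_code", "device", "site",
]


def _read_table(path: str | Path, required: list[str]) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise RecordError(f"input file not found: {path}")
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if rows and not isinstance(rows, list):
            raise RecordError(f"{path}: expected a JSON array of row objects")
        for i, row in enumerate(rows):
            missing = [c for c in required[:2] if c not in row]
            if missing:
                raise RecordError(f"{path} row {i + 1}: missing required field(s) {missing}")
        return [dict(row) for row in rows]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordError(f"{path}: missing required column(s) {missing}")
    return df.to_dict(orient="records")


def _opt(row: dict, key: str) -> Optional[str]:
    v = row.get(key)
    if v is None:
        return None
    v = str(v).strip()
    return v or None


def _parse_date(value: str, where: str) -> date:
    try:
        return date.fromisoformat(value)
    except ValueError as exc:
        raise RecordError(f"{where}: unparseable date {value!r} (expected YYYY-MM-DD)") from exc


def read_cohort(
    patients_file: str | Path,
    conditions_file: str | Path,
    prescriptions_file: str | Path,
    ontology: Optional[DrugOntology] = None,
) -> list[PatientRecord]:
    """Assemble PatientRecords from the three cohort files.

    Rows failing the schema raise :class:`RecordError` naming the file and
    row; a prescription or condition referencing an unknown patient_id is a
    join error naming the identifier; a dangling indication link is reported
    as a warning and the link is kept (downstream it simply will not match a
    condition).  When an ontology is supplied, drug names are normalised and
    lines of therapy derived.
    """
    patients = _read_table(patients_file, _PATIENT_COLS)
    conditions = _read_table(conditions_file, _CONDITION_COLS)
    prescriptions = _read_table(prescriptions_file, _RX_COLS)

    records: dict[str, PatientRecord] = {}
    for i, row in enumerate(patients, start=2):
        where = f"{patients_file} row {i}"
        pid = _opt(row, "patient_id")
        if not pid:
            raise RecordError(f"{where}: empty patient_id")
        weight = _opt(row, "weight_kg")
        wdate = _opt(row, "weight_date")
        formula = _opt(row, "formula_ml_per_day")
        try:
            records[pid] = PatientRecord(
                patient_id=pid,
                date_of_birth=_parse_date(_opt(row, "date_of_birth") or "", where),
                sex=_opt(row, "sex") or "unknown",
                pregnant=str(row.get("pregnant", "")).strip().lower() in {"true", "1", "yes"},
                weight_kg=float(weight) if weight else None,
                weight_date=_parse_date(wdate, where) if wdate else None,
                formula_ml_per_day=float(formula) if formula else None,
            )
        except ValueError as exc:
            raise RecordError(f"{where}: {exc}") from exc

    for i, row in enumerate(conditions, start=2):
        where = f"{conditions_file} row {i}"
        pid = _opt(row, "patient_id") or ""
        if pid not in records:
            raise RecordError(f"{where}: condition references unknown patient_id {pid!r}")
        quals = _opt(row, "qualifiers")
        end = _opt(row, "end")
        try:
            records[pid].conditions.append(
                Condition(
                    code=_opt(row, "code") or "",
                    onset=_parse_date(_opt(row, "onset") or "", where),
                    end=_parse_date(end, where) if end else None,
                    qualifiers=frozenset(q.strip() for q in quals.split(";") if q.strip()) if quals else frozenset(),
                )
            )
        except ValueError as exc:
            raise RecordError(f"{where}: {exc}") from exc

    for i, row in enumerate(prescriptions, start=2):
        where = f"{prescriptions_file} row {i}"
        pid = _opt(row, "patient_id") or ""
        rx_id = _opt(row, "rx_id") or f"(row {i})"
        if pid not in records:
            raise RecordError(f"{where}: prescription {rx_id} references unknown patient_id {pid!r}")
        end = _opt(row, "end")
        indication = _opt(row, "indication_code")
        try:
            rx = Prescription(
                rx_id=rx_id,
                drug=_opt(row, "drug") or "",
                dose_amount=float(_opt(row, "dose_amount") or 0),
                dose_unit=_opt(row, "dose_unit") or "mg",
                doses_per_day=int(float(_opt(row, "doses_per_day") or 1)),
                route=_opt(row, "route") or "oral",
                formulation=_opt(row, "formulation"),
                start=_parse_date(_opt(row, "start") or "", where),
                end=_parse_date(end, where) if end else None,
                indication=indication,
                device=_opt(row, "device"),
                site=_opt(row, "site"),
            )
        except ValueError as exc:
            raise RecordError(f"{where}: {exc}") from exc
        if indication and indication not in {c.code for c in records[pid].conditions}:
            warnings.warn(
                f"{where}: prescription {rx_id} indication {indication!r} has no matching "
                f"condition on patient {pid} (dangling link)",
                stacklevel=2,
            )
        records[pid].prescriptions.append(rx)

    out = []
    for pid in records:
        rec = records[pid]
        # re-run cross-field validation now that children are attached
        rec = PatientRecord.model_validate(rec.model_dump())
        if ontology is not None:
            normalize_record(rec, ontology)
        out.append(rec)
    return out


def write_cohort(records: Iterable[PatientRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write patients/conditions/prescriptions CSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pats, conds, rxs = [], [], []
    for r in records:
        pats.append({
            "patient_id": r.patient_id,
            "date_of_birth": r.date_of_birth.isoformat(),
            "sex": r.sex,
            "pregnant": str(r.pregnant).lower(),
            "weight_kg": "" if r.weight_kg is None else r.weight_kg,
            "weight_date": r.weight_date.isoformat() if r.weight_date else "",
            "formula_ml_per_day": "" if r.formula_ml_per_day is None else r.formula_ml_per_day,
        })
        for c in r.conditions:
            conds.append({
                "patient_id": r.patient_id,
                "code": c.code,
                "onset": c.onset.isoformat(),
                "end": c.end.isoformat() if c.end else "",
                "qualifiers": ";".join(sorted(c.qualifiers)),
            })
        for p in r.prescriptions:
            rxs.append({
                "patient_id": r.patient_id,
                "rx_id": p.rx_id,
                "drug": p.drug,
                "dose_amount": p.dose_amount,
                "dose_unit": p.dose_unit,
                "doses_per_day": p.doses_per_day,
                "route": p.route,
                "formulation": p.formulation or "",
                "start": p.start.isoformat(),
                "end": p.end.isoformat() if p.end else "",
                "indication_code": p.indication or "",
                "device": p.device or "",
                "site": p.site or "",
            })
    paths = {
        "patients": out_dir / "patients.csv",
        "conditions": out_dir / "conditions.csv",
        "prescriptions": out_dir / "prescriptions.csv",
    }
    pd.DataFrame(pats, columns=_PATIENT_COLS).to_csv(paths["patients"], index=False)
    pd.DataFrame(conds, columns=_CONDITION_COLS).to_csv(paths["conditions"], index=False)
    pd.DataFrame(rxs, columns=_RX_COLS).to_csv(paths["prescriptions"], index=False)
    return paths


_FLAG_COLS = ["patient_id", "criterion_id", "kind", "evidence", "evaluation_date", "note"]


def write_flags(flags, destination: str | Path) -> Path:
    """Write flags to CSV (or JSON when the path ends in .json).

    One row per flag, stable column order; evidence identifiers are
    semicolon-joined in CSV.  Round trips loss-lessly via
    :func:`read_flags`.
    """
    destination = Path(destination)
    rows = [
        {
            "patient_id": f.patient_id,
            "criterion_id": f.criterion_id,
            "kind": f.kind,
            "evidence": ";".join(f.evidence),
            "evaluation_date": f.evaluation_date.isoformat(),
            "note": f.note or "",
        }
        for f in flags
    ]
    destination.parent.mkdir(parents=True, exist_ok=True)
    if destination.suffix.lower() == ".json":
        destination.write_text(json.dumps(rows, indent=1) + "\n")
    else:
        pd.DataFrame(rows, columns=_FLAG_COLS).to_csv(destination, index=False)
    return destination


def read_flags(path: str | Path) -> list:
    """Read a flag file written by :func:`write_flags`."""
    from popiuk.engine import Flag  # local import to avoid a cycle

    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path, dtype=str, keep_default_na=False).to_dict(orient="records")
    out = []
    for row in rows:
        ev = row["evidence"]
        evidence = ev.split(";") if isinstance(ev, str) and ev else list(ev) if isinstance(ev, list) else []
        out.append(
            Flag(
                patient_id=row["patient_id"],
                criterion_id=row["criterion_id"],
                kind=row["kind"],
                evidence=evidence,
                evaluation_date=date.fromisoformat(row["evaluation_date"]),
                note=row.get("note") or None,
            )
        )
    return out
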