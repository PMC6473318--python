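"""The POPI(UK) criteria catalogue and its modification provenance ledger.

The catalogue holds the 80 explicit prescribing-quality criteria of the UK
modification of the POPI tool, each with a verbatim text, a machine-readable
condition tree (see :mod:`popiuk.engine` for the predicate grammar), and an
automatability tier.  The provenance ledger records how each of the 105
original French propositions fared in the UK modification: unchanged,
amended, combined, or omitted (with the omission reason), and which modified
criteria it maps to.

The arithmetic the ledger must close exactly:

    49 unchanged + 29 amended + 4 combined + 23 omitted = 105 originals
    49 + 29 + 2 (from the 4 combined)                    = 80 criteria
    12 no-UK-guideline + 4 conflicting + 7 category-removed = 23 omitted
"""

from __future__ import annotations

import hashlib
import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, ValidationError

GROUPS = {"diverse", "digestive", "ent_pulmonary", "dermatological", "neuropsychiatric"}
KINDS = {"inappropriate_prescription", "omission"}
TIERS = {"full", "conditional", "manual"}
STATUSES = {"unchanged", "amended", "combined", "omitted"}
REASONS = {"not_applicable", "no_uk_guideline", "conflicting_uk_guideline", "category_removed"}

EXPECTED_CRITERIA = 80
EXPECTED_ORIGINALS = 105
EXPECTED_STATUS_COUNTS = {"unchanged": 49, "amended": 29, "combined": 4, "omitted": 23}
EXPECTED_OMITTED_REASONS = {"no_uk_guideline": 12, "conflicting_uk_guideline": 4, "category_removed": 7}
EXPECTED_COMBINED_RESULTS = 2


class CatalogError(ValueError):
    """The catalogue file is missing, corrupt, or schema-invalid."""


class Criterion(BaseModel):
    """One POPI(UK) rule.

    ``condition`` is a predicate tree over record fields (None for manual
    criteria); ``requires`` / ``candidate`` drive not-evaluable routing for
    conditional criteria; ``commentary`` preserves source remarks that are
    deliberately not encoded (e.g. the sore-throat "no more than 20% of
    cases" expectation).
    """

    id: str
    group: str
    category: str
    kind: Literal["inappropriate_prescription", "omission"]
    text: str
    condition: Optional[dict] = None
    automatability: Literal["full", "conditional", "manual"]
    requires: Optional[str] = None
    candidate: Optional[dict] = None
    commentary: Optional[str] = None
    aliases: list[str] = Field(default_factory=list)


class ProvenanceRecord(BaseModel):
    """One of the 105 original POPI propositions and its fate in the UK tool."""

    original_id: str
    original_text: str
    category: str
    status: Literal["unchanged", "amended", "combined", "omitted"]
    reason: Literal["not_applicable", "no_uk_guideline", "conflicting_uk_guideline", "category_removed"]
    modified_ids: list[str] = Field(default_factory=list)
    guideline_refs: list[str] = Field(default_factory=list)


class CriteriaCatalog(BaseModel):
    criteria: list[Criterion]
    provenance: list[ProvenanceRecord]
    version: str
    checksum: str

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise CatalogError(f"unknown criterion id {criterion_id!r}")

    def by_tier(self, tier: str) -> list[Criterion]:
        return [c for c in self.criteria if c.automatability == tier]


def compute_checksum(criteria: list[dict], provenance: list[dict], version: str) -> str:
    """Content hash over the canonical JSON form of the catalogue."""
    payload = json.dumps(
        {"version": version, "criteria": criteria, "provenance": provenance},
        sort_keys=True,
        separators=(",", ":"),
        ensure_ascii=False,
    )
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def _catalog_dict_to_model(payload: dict, where: str) -> CriteriaCatalog:
    for key in ("criteria", "provenance", "version", "checksum"):
        if key not in payload:
            raise CatalogError(f"{where}: missing top-level field {key!r}")
    try:
        catalog = CriteriaCatalog.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise CatalogError(f"{where}: schema violation at {loc}: {first['msg']}") from exc
    expected = compute_checksum(
        [c.model_dump(exclude_none=True, exclude_defaults=True) for c in catalog.criteria],
        [p.model_dump(exclude_none=True, exclude_defaults=True) for p in catalog.provenance],
        catalog.version,
    )
    if expected != catalog.checksum:
        raise CatalogError(f"{where}: checksum mismatch (content does not match the recorded hash)")
    return catalog


def load_catalog(path: Optional[str | Path] = None) -> CriteriaCatalog:
    """Load the packaged catalogue, or a combined catalogue JSON file.

    The combined file format is one JSON object with ``criteria``,
    ``provenance``, ``version`` and ``checksum``.  The packaged default is
    shipped as two data files (criteria + provenance) plus metadata, and is
    assembled into the same structure.  Loading validates the schema and the
    content checksum; :func:`validate_catalog` additionally checks the
    domain invariants.
    """
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise CatalogError(f"catalogue file not found: {path}")
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise CatalogError(f"corrupt catalogue file {path}: {exc}") from exc
        if not isinstance(payload, dict):
            raise CatalogError(f"corrupt catalogue file {path}: expected a JSON object")
        return _catalog_dict_to_model(payload, str(path))

    data = resources.files("popiuk").joinpath("data")
    meta = json.loads(data.joinpath("catalog_meta.json").read_text())
    payload = {
        "criteria": json.loads(data.joinpath("criteria.json").read_text()),
        "provenance": json.loads(data.joinpath("provenance.json").read_text()),
        "version": meta["version"],
        "checksum": meta["checksum"],
    }
    return _catalog_dict_to_model(payload, "packaged catalogue")


def save_catalog(catalog: CriteriaCatalog, path: str | Path) -> Path:
    """Write the combined single-file JSON form (round-trips loss-lessly)."""
    path = Path(path)
    payload = {
        "version": catalog.version,
        "checksum": catalog.checksum,
        "criteria": [c.model_dump(exclude_none=True, exclude_defaults=True) for c in catalog.criteria],
        "provenance": [p.model_dump(exclude_none=True, exclude_defaults=True) for p in catalog.provenance],
    }
    path.write_text(json.dumps(payload, indent=1, ensure_ascii=False) + "\n")
    return path


def validate_catalog(catalog: CriteriaCatalog) -> list[str]:
    """Check every catalogue invariant; violations are returned, not raised.

    An empty report means the catalogue is internally consistent and closes
    the 105 -> 80 modification arithmetic exactly.
    """
    v: list[str] = []
    crit_ids = [c.id for c in catalog.criteria]
    id_set = set(crit_ids)

    if len(catalog.criteria) != EXPECTED_CRITERIA:
        v.append(f"criterion count: expected {EXPECTED_CRITERIA}, found {len(catalog.criteria)}")
    dupes = {i for i in crit_ids if crit_ids.count(i) > 1}
    if dupes:
        v.append(f"duplicate criterion ids: {sorted(dupes)}")

    for c in catalog.criteria:
        if c.group not in GROUPS:
            v.append(f"{c.id}: unknown group {c.group!r}")
        if c.automatability in {"full", "conditional"} and not c.condition:
            v.append(f"{c.id}: automatability {c.automatability} requires a non-empty condition tree")
        if c.automatability == "manual" and c.condition is not None:
            v.append(f"{c.id}: manual criteria must have condition = none")
        if c.automatability == "conditional" and not c.requires:
            v.append(f"{c.id}: conditional criteria must declare the datum they require")
        expected_kind = "IP" if c.kind == "inappropriate_prescription" else "OM"
        if f"-{expected_kind}-" not in c.id:
            v.append(f"{c.id}: id does not agree with kind {c.kind}")

    if len(catalog.provenance) != EXPECTED_ORIGINALS:
        v.append(f"provenance count: expected {EXPECTED_ORIGINALS}, found {len(catalog.provenance)}")
    orig_ids = [p.original_id for p in catalog.provenance]
    dupes = {i for i in orig_ids if orig_ids.count(i) > 1}
    if dupes:
        v.append(f"duplicate provenance ids: {sorted(dupes)}")

    status_counts = {s: 0 for s in STATUSES}
    reason_counts = {r: 0 for r in REASONS}
    combined_targets: set[str] = set()
    mapped: list[str] = []
    for p in catalog.provenance:
        status_counts[p.status] += 1
        if p.status == "omitted":
            reason_counts[p.reason] += 1
            if p.modified_ids:
                v.append(f"{p.original_id}: omitted records must map to 0 criteria, found {p.modified_ids}")
            if p.reason == "not_applicable":
                v.append(f"{p.original_id}: omitted record needs an omission reason")
        else:
            if p.reason != "not_applicable":
                v.append(f"{p.original_id}: non-omitted record must have reason not_applicable")
            if len(p.modified_ids) != 1:
                v.append(
                    f"{p.original_id}: {p.status} record must map to exactly 1 criterion, "
                    f"found {len(p.modified_ids)}"
                )
            if p.status == "combined":
                combined_targets.update(p.modified_ids)
        mapped.extend(p.modified_ids)
        for mid in p.modified_ids:
            if mid not in id_set:
                v.append(f"{p.original_id}: maps to unknown criterion {mid!r}")

    for status, expected in EXPECTED_STATUS_COUNTS.items():
        if status_counts[status] != expected:
            v.append(f"status count {status}: expected {expected}, found {status_counts[status]}")
    for reason, expected in EXPECTED_OMITTED_REASONS.items():
        if reason_counts[reason] != expected:
            v.append(f"omitted reason {reason}: expected {expected}, found {reason_counts[reason]}")
    if len(combined_targets) != EXPECTED_COMBINED_RESULTS:
        v.append(
            f"combined records map onto {len(combined_targets)} distinct criteria, "
            f"expected {EXPECTED_COMBINED_RESULTS}"
        )
    if set(mapped) != id_set:
        missing = sorted(id_set - set(mapped))
        extra = sorted(set(mapped) - id_set)
        v.append(f"modified_ids union does not equal the catalogue ids (missing={missing}, extra={extra})")
    non_combined_mapped = [m for p in catalog.provenance if p.status != "combined" for m in p.modified_ids]
    dupes = {m for m in non_combined_mapped if non_combined_mapped.count(m) > 1}
    if dupes:
        v.append(f"criteria mapped by more than one unchanged/amended record: {sorted(dupes)}")
    return v


def provenance_summary(catalog: CriteriaCatalog) -> dict:
    """Counts by modification status, with the omitted-reason breakdown.

    Refuses an invalid catalogue; an entirely empty catalogue returns all
    zeros with a validity warning instead (the degenerate case is data, not
    an exception).
    """
    if not catalog.criteria and not catalog.provenance:
        warnings.warn("empty catalogue: all provenance counts are zero", stacklevel=2)
        return {
            "n_criteria": 0,
            "n_original": 0,
            "unchanged": 0,
            "amended": 0,
            "combined": 0,
            "omitted": 0,
            "omitted_reasons": {r: 0 for r in sorted(REASONS - {"not_applicable"})},
            "combined_resulting_criteria": 0,
        }
    violations = validate_catalog(catalog)
    if violations:
        raise CatalogError("invalid catalogue: " + "; ".join(violations[:3]))
    status = {s: sum(1 for p in catalog.provenance if p.status == s) for s in sorted(STATUSES)}
    reasons = {
        r: sum(1 for p in catalog.provenance if p.status == "omitted" and p.reason == r)
        for r in sorted(REASONS - {"not_applicable"})
    }
    combined_targets = {m for p in catalog.provenance if p.status == "combined" for m in p.modified_ids}
    return {
        "n_criteria": len(catalog.criteria),
        "n_original": len(catalog.provenance),
        "unchanged": status["unchanged"],
        "amended": status["amended"],
        "combined": status["combined"],
        "omitted": status["omitted"],
        "omitted_reasons": reasons,
        "combined_resulting_criteria": len(combined_targets),
    }
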