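"""Criterion evaluation: dose, age, duration, co-prescription and omission logic.

Each criterion's ``condition`` is a predicate tree interpreted here.  Node
types:

``prescription``
    Fires when any prescription matches the ``match`` selector and no
    ``except`` clause exempts it.
``co_prescription``
    Two selectors ``a`` and ``b`` matched by two distinct prescriptions whose
    date intervals overlap by at least one day (optionally requiring distinct
    generic drugs, a shared indication, or a patient-level ``context``).
``companion_omission``
    An ``anchor`` prescription without a required ``companion`` prescription
    overlapping the window starting ``companion_from_day`` days into the
    anchor course (e.g. morphine beyond 48 h with no osmotic laxative).
``context_omission``
    A patient context (active coded condition, qualifiers, age band,
    pregnancy) with none of the ``required_any`` prescriptions in place,
    optionally at an age-banded dose.
``repeat_omission``
    An anchor prescription not followed by a repeat of the same drug within
    ``repeat_days`` = [lo, hi] days (checked only once the window has passed).
``monitoring_omission``
    An anchor prescription running longer than ``anchor_duration_gt_days``
    with no weight measurement dated inside the treatment episode.
``any_of``
    Disjunction of sub-nodes.

Prescription selectors combine drug identity/class, route, formulation, dose
unit, mg/kg/day bounds, daily-frequency bounds, duration bounds, age at
start, overlap with active coded conditions, indication links, and
line-of-therapy.  Boundary semantics throughout: "before N years" is strictly
before the Nth birthday; "more than four weeks" excludes exactly 28 days;
"more than 48 h" excludes exactly 48 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Union

import pandas as pd
from pydantic import BaseModel, Field

from popiuk.catalog import CriteriaCatalog, Criterion
from popiuk.records import (
    Condition,
    DrugOntology,
    PatientRecord,
    Prescription,
    drug_in_class,
    is_unknown_drug,
)

DAYS_PER_YEAR = 365.25

NOT_EVALUABLE_REASONS = {
    "missing_weight",
    "missing_indication",
    "manual_tier",
    "missing_qualifier",
    "unit_mismatch",
}


class EngineError(ValueError):
    """Domain-precondition violation during evaluation."""


class Flag(BaseModel):
    """One triggered criterion for one patient, with its evidence."""

    criterion_id: str
    patient_id: str
    kind: str
    evidence: list[str]
    evaluation_date: date
    note: Optional[str] = None


@dataclass
class NotEvaluable:
    """A criterion that cannot be decided for this record."""

    criterion_id: str
    reason: str


class EvaluationResult(BaseModel):
    """Per-patient screening outcome: flags, not-evaluable criteria, notes."""

    patient_id: str
    flags: list[Flag] = Field(default_factory=list)
    not_evaluable: list[tuple[str, str]] = Field(default_factory=list)
    evaluated_at: date
    notes: list[str] = Field(default_factory=list)


# ---------------------------------------------------------------------------
# Elementary clinical arithmetic
# ---------------------------------------------------------------------------

def age_years(date_of_birth: date, at: date) -> float:
    """Decimal age in years: day count / 365.25.

    Used by every age-bounded predicate with strict-inequality semantics for
    "before N years" (the Nth birthday itself is no longer "before").
    """
    if at < date_of_birth:
        raise EngineError(f"evaluation date {at} precedes date of birth {date_of_birth}")
    return (at - date_of_birth).days / DAYS_PER_YEAR


def daily_dose_per_kg(p: Prescription, weight_kg: float) -> float:
    """Total daily dose in mg per kg: dose_amount x doses_per_day / weight.

    Exact arithmetic; callers compare against thresholds without rounding.
    """
    if p.dose_unit != "mg":
        raise EngineError(f"prescription {p.rx_id}: dose unit {p.dose_unit!r} is not mg")
    if weight_kg is None or weight_kg <= 0:
        raise EngineError(f"prescription {p.rx_id}: weight required for mg/kg arithmetic")
    return p.dose_amount * p.doses_per_day / weight_kg


def duration_days(p: Prescription, as_of: date) -> int:
    """Days elapsed from start to min(end, as_of); open-ended runs to as_of.

    A course started and stopped the same day has duration 0; "more than
    four weeks" predicates compare as ``duration > 28``, "more than 48 h" as
    ``duration > 2``.
    """
    if p.start > as_of:
        raise EngineError(f"prescription {p.rx_id}: starts after the evaluation date")
    stop = p.end if p.end is not None and p.end < as_of else as_of
    return (stop - p.start).days


def co_prescribed(a: Prescription, b: Prescription, as_of: Optional[date] = None) -> bool:
    """True iff the two orders are different generics with overlapping dates.

    Overlap means the closed date intervals share at least one day; the
    relation is symmetric.  Same-generic pairs are never "co-prescribed"
    (repeat or dose issues are handled by dose rules instead).
    """
    if a.drug_norm == b.drug_norm:
        return False
    return _intervals_overlap(a, b, as_of)


def _intervals_overlap(a: Prescription, b: Prescription, as_of: Optional[date]) -> bool:
    horizon = as_of or max(
        d for d in (a.start, a.end, b.start, b.end) if d is not None
    )
    a0, a1 = a.interval(horizon)
    b0, b1 = b.interval(horizon)
    return max(a0, b0) <= min(a1, b1)


# ---------------------------------------------------------------------------
# Selector matching
# ---------------------------------------------------------------------------

@dataclass
class _Match:
    matched: bool
    implicated: list[Condition] = field(default_factory=list)
    pending: set[str] = field(default_factory=set)


def _active_conditions(record: PatientRecord, on: date) -> list[Condition]:
    return [c for c in record.conditions if c.active_on(on)]


def _condition_overlaps_rx(c: Condition, p: Prescription, as_of: date) -> bool:
    r0, r1 = p.interval(as_of)
    c1 = c.end if c.end is not None and c.end < as_of else as_of
    return max(c.onset, r0) <= min(c1, r1)


def _rx_matches(
    sel: dict,
    p: Prescription,
    record: PatientRecord,
    as_of: date,
    ontology: DrugOntology,
) -> _Match:
    m = _Match(False)
    if p.start > as_of:
        return m

    drug = sel.get("drug")
    if drug is not None and p.drug_norm not in drug:
        return m
    if "drug_not" in sel and p.drug_norm in sel["drug_not"]:
        return m
    class_any = sel.get("class_any")
    if class_any is not None:
        if is_unknown_drug(p.drug_norm):
            return m
        if not any(drug_in_class(p.drug_norm, c, ontology) for c in class_any):
            return m
    if "class_not" in sel and not is_unknown_drug(p.drug_norm):
        if any(drug_in_class(p.drug_norm, c, ontology) for c in sel["class_not"]):
            return m
    if "route_any" in sel and p.route not in sel["route_any"]:
        return m
    if "route_not" in sel and p.route in sel["route_not"]:
        return m
    if "formulation_any" in sel and (p.formulation or "standard") not in sel["formulation_any"]:
        return m
    if "unit_any" in sel and p.dose_unit not in sel["unit_any"]:
        return m
    if "unit_not" in sel and p.dose_unit in sel["unit_not"]:
        return m
    if "device_not" in sel and (p.device is None or p.device in sel["device_not"]):
        return m
    if "site_any" in sel and (p.site is None or p.site not in sel["site_any"]):
        return m

    if "doses_per_day_eq" in sel and p.doses_per_day != sel["doses_per_day_eq"]:
        return m
    if "doses_per_day_gte" in sel and p.doses_per_day < sel["doses_per_day_gte"]:
        return m
    if "doses_per_day_lt" in sel and p.doses_per_day >= sel["doses_per_day_lt"]:
        return m
    if "dose_mg_eq" in sel and not (p.dose_unit == "mg" and p.dose_amount == sel["dose_mg_eq"]):
        return m

    if "duration_gt_days" in sel and duration_days(p, as_of) <= sel["duration_gt_days"]:
        return m
    if "duration_lte_days" in sel and duration_days(p, as_of) > sel["duration_lte_days"]:
        return m

    if "age_lt_years" in sel and not age_years(record.date_of_birth, p.start) < sel["age_lt_years"]:
        return m
    if "age_gte_years" in sel and not age_years(record.date_of_birth, p.start) >= sel["age_gte_years"]:
        return m

    if "mg_per_kg_day_gt" in sel:
        if p.dose_unit != "mg":
            m.pending.add("unit_mismatch")
            return m
        if record.weight_kg is None:
            m.pending.add("missing_weight")
            return m
        if not daily_dose_per_kg(p, record.weight_kg) > sel["mg_per_kg_day_gt"]:
            return m

    implicated: list[Condition] = []
    if "active_condition_any" in sel:
        hits = [
            c for c in record.conditions
            if c.code in sel["active_condition_any"] and _condition_overlaps_rx(c, p, as_of)
        ]
        if "started_within_days_of_onset" in sel:
            n = sel["started_within_days_of_onset"]
            hits = [c for c in hits if 0 <= (p.start - c.onset).days < n]
        if "condition_qualifier_any" in sel:
            hits = [c for c in hits if c.qualifiers & set(sel["condition_qualifier_any"])]
        if not hits:
            return m
        implicated.extend(hits)

    if "indication_any" in sel:
        if p.indication is None or p.indication not in sel["indication_any"]:
            return m
        implicated.extend(c for c in record.conditions if c.code == p.indication)
    if sel.get("first_line") and p.line_of_therapy != 1:
        return m

    m.matched = True
    m.implicated = implicated
    return m


def _exception_applies(
    clauses: list[dict],
    p: Optional[Prescription],
    implicated: list[Condition],
    record: PatientRecord,
    as_of: date,
) -> bool:
    scope = implicated if implicated else _active_conditions(record, as_of)
    for clause in clauses:
        ok = True
        if "qualifier_any" in clause:
            ok = ok and any(c.qualifiers & set(clause["qualifier_any"]) for c in scope)
        if "indication_any" in clause:
            ok = ok and p is not None and p.indication in clause["indication_any"]
        if "age_lt_years" in clause:
            at = p.start if p is not None else as_of
            ok = ok and age_years(record.date_of_birth, at) < clause["age_lt_years"]
        if "age_gte_years" in clause:
            at = p.start if p is not None else as_of
            ok = ok and age_years(record.date_of_birth, at) >= clause["age_gte_years"]
        if ok:
            return True
    return False


def _ctx_matches(ctx: dict, record: PatientRecord, as_of: date) -> tuple[bool, list[Condition]]:
    if ctx.get("pregnant") and not record.pregnant:
        return False, []
    if "sex" in ctx and record.sex != ctx["sex"]:
        return False, []
    age = age_years(record.date_of_birth, as_of)
    if "age_min_years" in ctx and age < ctx["age_min_years"]:
        return False, []
    if "age_max_years" in ctx and age >= ctx["age_max_years"]:
        return False, []
    if "formula_lt_ml_per_day" in ctx:
        if record.formula_ml_per_day is None or record.formula_ml_per_day >= ctx["formula_lt_ml_per_day"]:
            return False, []

    implicated: list[Condition] = []
    if "condition_any" in ctx:
        active = _active_conditions(record, as_of)
        hits = [c for c in active if c.code in ctx["condition_any"]]
        if "qualifier_any" in ctx:
            hits = [c for c in hits if c.qualifiers & set(ctx["qualifier_any"])]
        if "qualifier_all" in ctx:
            hits = [c for c in hits if set(ctx["qualifier_all"]) <= c.qualifiers]
        if "qualifier_none" in ctx:
            hits = [c for c in hits if not (c.qualifiers & set(ctx["qualifier_none"]))]
        if not hits:
            return False, []
        implicated.extend(hits)
        if "co_condition_any" in ctx:
            co = [c for c in active if c.code in ctx["co_condition_any"]]
            if not co:
                return False, []
            implicated.extend(co)
    return True, implicated


# ---------------------------------------------------------------------------
# Node evaluation
# ---------------------------------------------------------------------------

@dataclass
class _Outcome:
    fired: bool = False
    evidence: set[str] = field(default_factory=set)
    pending: set[str] = field(default_factory=set)


def _evidence_for(p: Prescription, implicated: list[Condition]) -> set[str]:
    return {p.rx_id} | {c.code for c in implicated}


def _dose_band_ok(p: Prescription, bands: list[dict], age: float) -> bool:
    for band in bands:
        lo = band.get("age_min_years", 0.0)
        hi = band.get("age_max_years", float("inf"))
        if lo <= age < hi:
            return p.dose_unit == "mg" and p.dose_amount == band["dose_mg"] and p.doses_per_day == band["per_day"]
    return False


def _eval_node(
    node: dict,
    record: PatientRecord,
    as_of: date,
    ontology: DrugOntology,
) -> _Outcome:
    ntype = node["type"]
    out = _Outcome()
    rxs = [p for p in record.prescriptions if p.start <= as_of]

    if ntype == "any_of":
        for sub in node["of"]:
            r = _eval_node(sub, record, as_of, ontology)
            out.pending |= r.pending
            if r.fired:
                out.fired = True
                out.evidence |= r.evidence
        return out

    if ntype == "prescription":
        sel = node["match"]
        for p in rxs:
            m = _rx_matches(sel, p, record, as_of, ontology)
            out.pending |= m.pending
            if not m.matched:
                continue
            if _exception_applies(node.get("except", []), p, m.implicated, record, as_of):
                continue
            out.fired = True
            out.evidence |= _evidence_for(p, m.implicated)
        return out

    if ntype == "co_prescription":
        ctx_ok, ctx_conditions = True, []
        if "context" in node:
            ctx_ok, ctx_conditions = _ctx_matches(node["context"], record, as_of)
        if not ctx_ok:
            return out
        distinct_drug = node.get("distinct_drug", True)
        for p in rxs:
            ma = _rx_matches(node["a"], p, record, as_of, ontology)
            out.pending |= ma.pending
            if not ma.matched:
                continue
            for q in rxs:
                if q.rx_id == p.rx_id:
                    continue
                mb = _rx_matches(node["b"], q, record, as_of, ontology)
                out.pending |= mb.pending
                if not mb.matched:
                    continue
                if distinct_drug and p.drug_norm == q.drug_norm:
                    continue
                if not _intervals_overlap(p, q, as_of):
                    continue
                if node.get("same_indication") and (p.indication is None or p.indication != q.indication):
                    continue
                implicated = ma.implicated + mb.implicated + ctx_conditions
                if _exception_applies(node.get("except", []), p, implicated, record, as_of):
                    continue
                out.fired = True
                out.evidence |= _evidence_for(p, implicated) | {q.rx_id}
        return out

    if ntype == "companion_omission":
        ctx_ok, ctx_conditions = True, []
        if "context" in node:
            ctx_ok, ctx_conditions = _ctx_matches(node["context"], record, as_of)
        if not ctx_ok:
            return out
        from_day = node.get("companion_from_day", 0)
        companion_sel = node["companion"]
        for p in rxs:
            m = _rx_matches(node["anchor"], p, record, as_of, ontology)
            out.pending |= m.pending
            if not m.matched:
                continue
            implicated = m.implicated + ctx_conditions
            if _exception_applies(node.get("except", []), p, implicated, record, as_of):
                continue
            w0 = p.start + timedelta(days=from_day)
            _, w1 = p.interval(as_of)
            covered = False
            for q in rxs:
                if q.rx_id == p.rx_id:
                    continue
                if companion_sel.get("other_than_anchor"):
                    if q.drug_norm == p.drug_norm:
                        continue
                else:
                    mq = _rx_matches(companion_sel, q, record, as_of, ontology)
                    out.pending |= mq.pending
                    if not mq.matched:
                        continue
                q0, q1 = q.interval(as_of)
                if max(q0, w0) <= min(q1, w1):
                    covered = True
                    break
            if not covered:
                out.fired = True
                out.evidence |= _evidence_for(p, implicated)
        return out

    if ntype == "context_omission":
        ctx_ok, ctx_conditions = _ctx_matches(node["context"], record, as_of)
        if not ctx_ok:
            return out
        age = age_years(record.date_of_birth, as_of)
        for option in node["required_any"]:
            coverage = option.get("coverage", "current")
            for q in rxs:
                m = _rx_matches({k: v for k, v in option.items() if k not in {"coverage", "dose_bands"}},
                                q, record, as_of, ontology)
                out.pending |= m.pending
                if not m.matched:
                    continue
                if coverage == "current":
                    q0, q1 = q.interval(as_of)
                    if not (q0 <= as_of <= q1):
                        continue
                if "dose_bands" in option and not _dose_band_ok(q, option["dose_bands"], age):
                    continue
                return out  # requirement satisfied: no omission
        out.fired = True
        evidence = {c.code for c in ctx_conditions}
        if node["context"].get("pregnant"):
            evidence.add("pregnant")
        out.evidence = evidence
        return out

    if ntype == "repeat_omission":
        ctx_ok, ctx_conditions = True, []
        if "context" in node:
            ctx_ok, ctx_conditions = _ctx_matches(node["context"], record, as_of)
        if not ctx_ok:
            return out
        lo, hi = node["repeat_days"]
        for p in rxs:
            m = _rx_matches(node["anchor"], p, record, as_of, ontology)
            out.pending |= m.pending
            if not m.matched:
                continue
            if (as_of - p.start).days < hi:
                continue  # repeat window still open; cannot yet be an omission
            repeated = any(
                q.rx_id != p.rx_id
                and q.drug_norm == p.drug_norm
                and lo <= (q.start - p.start).days <= hi
                for q in rxs
            )
            if not repeated:
                out.fired = True
                out.evidence |= _evidence_for(p, m.implicated + ctx_conditions)
        return out

    if ntype == "monitoring_omission":
        for p in rxs:
            m = _rx_matches(node["anchor"], p, record, as_of, ontology)
            out.pending |= m.pending
            if not m.matched:
                continue
            if duration_days(p, as_of) <= node["anchor_duration_gt_days"]:
                continue
            if record.weight_date is not None and p.start <= record.weight_date <= as_of:
                continue
            out.fired = True
            out.evidence |= _evidence_for(p, m.implicated)
        return out

    raise EngineError(f"unknown condition node type {ntype!r}")


# ---------------------------------------------------------------------------
# Conditional-tier candidate routing
# ---------------------------------------------------------------------------

_REQUIRES_REASON = {
    "indication": "missing_indication",
    "qualifier": "missing_qualifier",
    "device": "missing_qualifier",
    "site": "missing_qualifier",
    "formula_intake": "missing_qualifier",
}


def _conditional_not_evaluable(
    c: Criterion,
    record: PatientRecord,
    as_of: date,
    ontology: DrugOntology,
) -> Optional[str]:
    """If the criterion is in play but its optional datum is absent, say why."""
    cand = c.candidate or {}
    rx_sel = cand.get("rx")
    ctx_sel = cand.get("ctx")
    candidates: list[Prescription] = []
    if rx_sel is not None:
        candidates = [
            p for p in record.prescriptions
            if p.start <= as_of and _rx_matches(rx_sel, p, record, as_of, ontology).matched
        ]
        if not candidates:
            return None
    ctx_conditions: list[Condition] = []
    if ctx_sel is not None:
        active = _active_conditions(record, as_of)
        ctx_conditions = [c_ for c_ in active if c_.code in ctx_sel.get("condition_any", [])]
        if "condition_any" in ctx_sel and not ctx_conditions:
            return None
        ok, _ = _ctx_matches({k: v for k, v in ctx_sel.items() if k != "condition_any"}, record, as_of)
        if not ok:
            return None

    reason = _REQUIRES_REASON[c.requires]
    if c.requires == "indication":
        if any(p.indication is None for p in candidates) or not candidates:
            return reason
        return None
    if c.requires == "device":
        if any(p.device is None for p in candidates):
            return reason
        return None
    if c.requires == "site":
        if any(p.site is None for p in candidates):
            return reason
        return None
    if c.requires == "formula_intake":
        if record.formula_ml_per_day is None:
            return reason
        return None
    # qualifier: the implicated context condition carries no qualifier data
    scope = ctx_conditions or _active_conditions(record, as_of)
    if scope and all(not c_.qualifiers for c_ in scope):
        return reason
    if not scope and candidates:
        return reason
    return None


# ---------------------------------------------------------------------------
# Public evaluation API
# ---------------------------------------------------------------------------

def evaluate_criterion(
    criterion: Criterion,
    record: PatientRecord,
    as_of: date,
    ontology: DrugOntology,
) -> Union[list[Flag], NotEvaluable]:
    """Evaluate one criterion against one record.

    Returns at most one flag (multiple violations of the same criterion are
    merged into one flag carrying all evidence), or a :class:`NotEvaluable`
    with the routing reason.
    """
    if criterion.automatability == "manual":
        return NotEvaluable(criterion.id, "manual_tier")
    outcome = _eval_node(criterion.condition, record, as_of, ontology)
    if outcome.fired:
        return [
            Flag(
                criterion_id=criterion.id,
                patient_id=record.patient_id,
                kind=criterion.kind,
                evidence=sorted(outcome.evidence),
                evaluation_date=as_of,
            )
        ]
    if outcome.pending:
        # a prescription was a candidate but weight/unit data blocked the decision
        reason = "missing_weight" if "missing_weight" in outcome.pending else sorted(outcome.pending)[0]
        return NotEvaluable(criterion.id, reason)
    if criterion.automatability == "conditional":
        reason = _conditional_not_evaluable(criterion, record, as_of, ontology)
        if reason is not None:
            return NotEvaluable(criterion.id, reason)
    return []


def screen_record(
    record: PatientRecord,
    catalog: CriteriaCatalog,
    as_of: Optional[date] = None,
    ontology: Optional[DrugOntology] = None,
) -> EvaluationResult:
    """Evaluate all 80 criteria against one record.

    ``as_of`` defaults to the latest date present in the record.  The result
    partitions criteria into flags, not-evaluable (with reason), and silent
    passes; evaluation is deterministic for identical inputs.
    """
    from popiuk.records import load_ontology

    if ontology is None:
        ontology = load_ontology()
    if as_of is None:
        as_of = record.latest_date()
    flags: list[Flag] = []
    not_evaluable: list[tuple[str, str]] = []
    for criterion in sorted(catalog.criteria, key=lambda c: c.id):
        result = evaluate_criterion(criterion, record, as_of, ontology)
        if isinstance(result, NotEvaluable):
            not_evaluable.append((result.criterion_id, result.reason))
        else:
            flags.extend(result)
    notes = sorted(
        {p.drug_norm for p in record.prescriptions if is_unknown_drug(p.drug_norm)}
    )
    return EvaluationResult(
        patient_id=record.patient_id,
        flags=flags,
        not_evaluable=not_evaluable,
        evaluated_at=as_of,
        notes=[f"unknown drug suppressed from class rules: {n}" for n in notes],
    )


def screen_cohort(
    records: list[PatientRecord],
    catalog: CriteriaCatalog,
    as_of: Optional[date] = None,
    ontology: Optional[DrugOntology] = None,
) -> tuple[list[Flag], pd.DataFrame]:
    """Screen a cohort; returns (all flags, per-criterion prevalence table).

    Prevalence per criterion = flagged patients / evaluable patients; the
    denominator excludes patients for whom the criterion was not evaluable,
    and both counts are reported so rates can be recomputed downstream.  An
    empty cohort returns empty results with a warning.
    """
    import warnings

    from popiuk.records import load_ontology

    if ontology is None:
        ontology = load_ontology()
    if not records:
        warnings.warn("empty cohort: no patients to screen", stacklevel=2)
        empty = pd.DataFrame(columns=["criterion_id", "n_flagged", "n_evaluable", "prevalence"])
        return [], empty

    all_flags: list[Flag] = []
    flagged: dict[str, int] = {c.id: 0 for c in catalog.criteria}
    not_eval: dict[str, int] = {c.id: 0 for c in catalog.criteria}
    for record in sorted(records, key=lambda r: r.patient_id):
        result = screen_record(record, catalog, as_of=as_of, ontology=ontology)
        all_flags.extend(result.flags)
        for f in result.flags:
            flagged[f.criterion_id] += 1
        for cid, _reason in result.not_evaluable:
            not_eval[cid] += 1

    n = len(records)
    rows = []
    for cid in sorted(flagged):
        n_eval = n - not_eval[cid]
        rows.append({
            "criterion_id": cid,
            "n_flagged": flagged[cid],
            "n_evaluable": n_eval,
            "prevalence": flagged[cid] / n_eval if n_eval > 0 else float("nan"),
        })
    return all_flags, pd.DataFrame(rows, columns=["criterion_id", "n_flagged", "n_evaluable", "prevalence"])
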