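"""Clinical event projection and the four temporal ADE patterns.

Adverse-drug-event queries pair medication orders with laboratory results
under a temporal condition.  Four basic patterns cover the use cases:

1. all orders of the resolved drugs, no temporal condition;
2. qualifying laboratory events inside each estimated medication period —
   the closed day interval ``[order_date, order_date + days_prescribed - 1]``
   (the order day counts as day 1);
3. qualifying events between a patient's initial and final order dates of
   the resolved drugs (closed; a single order gives a one-day period) —
   appropriate for slow-moving measures such as HbA1c;
4. a pure filter over pattern-3 cases that drops every patient who already
   had a qualifying event in the window immediately before the initial
   order (``[initial - window_days, initial - 1]``), raising the odds that
   the event is drug-related rather than pre-existing.

Events are projected from the converted RDF corpus, so each record carries
the URI of the RDF resource it came from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from decimal import Decimal
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml
from rdflib import Graph, RDF

from .linked_drug_data import DrugKnowledgeGraph
from .query_expansion import ByAde, ByClass, ByClassAndTarget, CodeSet, DrugExpression, resolve
from .rdf_conversion import DEFAULT_BASE, vocab_namespace

__all__ = [
    "MedicationOrder",
    "LabResult",
    "EventPredicate",
    "CaseMatch",
    "ProjectionError",
    "QuerySpec",
    "project_events",
    "pattern1_all_orders",
    "pattern2_during_each_period",
    "pattern3_initial_to_final",
    "pattern4_exclude_pre_initial",
    "run_query",
    "parse_query_spec",
]


class ProjectionError(ValueError):
    """A mandatory field (patient id, date) is missing from a message."""


@dataclass(frozen=True)
class MedicationOrder:
    patient_id: str
    drug_code: str
    dose: Decimal
    dose_unit: str
    order_date: date
    days_prescribed: int
    source_uri: str

    def period(self) -> tuple[date, date]:
        """Closed medication period; the order day is day 1."""
        return self.order_date, self.order_date + timedelta(days=self.days_prescribed - 1)


@dataclass(frozen=True)
class LabResult:
    patient_id: str
    test_code: str
    value: Decimal
    unit: str
    test_date: date
    source_uri: str


@dataclass(frozen=True)
class EventPredicate:
    """A numeric condition on one laboratory test, e.g. WBC <= 3000."""

    test_code: str
    comparator: str  # le | ge | lt | gt
    threshold: Decimal

    def __post_init__(self) -> None:
        if self.comparator not in ("le", "ge", "lt", "gt"):
            raise ValueError(f"unknown comparator {self.comparator!r}")

    def holds(self, lab: LabResult) -> bool:
        if lab.test_code != self.test_code:
            return False
        v, t = lab.value, Decimal(self.threshold)
        return {"le": v <= t, "ge": v >= t, "lt": v < t, "gt": v > t}[self.comparator]


def _any_holds(predicates: Sequence[EventPredicate], lab: LabResult) -> bool:
    return any(p.holds(lab) for p in predicates)


@dataclass(frozen=True)
class CaseMatch:
    patient_id: str
    orders: tuple[str, ...]  # source URIs
    events: tuple[str, ...] = ()  # source URIs
    period: Optional[tuple[date, date]] = None


def _sort_key(m: CaseMatch):
    return (m.patient_id, m.period or (date.min, date.min), m.orders, m.events)


# --------------------------------------------------------------------------
# Projection from converted RDF


def _first(g: Graph, s, p):
    for o in g.objects(s, p):
        return o
    return None


def _walk(g: Graph, node, preds):
    for p in preds:
        node = _first(g, node, p)
        if node is None:
            return None
    return node


def _as_date(literal) -> date:
    v = literal.toPython()
    if isinstance(v, datetime):
        return v.date()
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v)[:10])


def project_events(
    corpus: Graph,
    clinical_base: str = DEFAULT_BASE,
) -> tuple[list[MedicationOrder], list[LabResult]]:
    """Project typed clinical events from a converted corpus graph.

    One :class:`MedicationOrder` per ORDER group with a populated RXE, one
    :class:`LabResult` per numeric OBX; non-numeric OBX values are skipped
    with a warning.  A missing patient id or date raises
    :class:`ProjectionError` naming the message URI.
    """
    v = vocab_namespace(clinical_base)
    orders: list[MedicationOrder] = []
    labs: list[LabResult] = []

    for msg in sorted(corpus.subjects(RDF.type, v["RDE_O11"]), key=str):
        pid = _walk(corpus, msg, [v["PATIENT"], v["PID"], v["PID.3"], v["CX.1"]])
        if pid is None:
            raise ProjectionError(f"no patient id under {msg}")
        for order in sorted(corpus.objects(msg, v["ORDER"]), key=str):
            rxe = _first(corpus, order, v["RXE"])
            if rxe is None:
                continue
            code = _walk(corpus, rxe, [v["RXE.2"], v["CE.1"]])
            if code is None:
                continue
            dose = _walk(corpus, rxe, [v["RXE.3"], v["NM.1"]])
            unit = _walk(corpus, rxe, [v["RXE.5"], v["CE.1"]])
            tq = _first(corpus, order, v["TQ1"])
            odate = _walk(corpus, tq, [v["TQ1.7"], v["TS.1"]]) if tq is not None else None
            days = _walk(corpus, tq, [v["TQ1.6"], v["CQ.1"]]) if tq is not None else None
            if odate is None:
                raise ProjectionError(f"no order date (TQ1-7) under {msg}")
            orders.append(
                MedicationOrder(
                    patient_id=str(pid),
                    drug_code=str(code),
                    dose=Decimal(str(dose)) if dose is not None else Decimal(0),
                    dose_unit=str(unit) if unit is not None else "",
                    order_date=_as_date(odate),
                    days_prescribed=int(Decimal(str(days))) if days is not None else 1,
                    source_uri=str(order),
                )
            )

    for msg in sorted(corpus.subjects(RDF.type, v["OUL_R22"]), key=str):
        pid = _walk(corpus, msg, [v["PATIENT"], v["PID"], v["PID.3"], v["CX.1"]])
        if pid is None:
            raise ProjectionError(f"no patient id under {msg}")
        for result in sorted(corpus.objects(msg, v["RESULT"]), key=str):
            for obx in sorted(corpus.objects(result, v["OBX"]), key=str):
                code = _walk(corpus, obx, [v["OBX.3"], v["CE.1"]])
                if code is None:
                    continue
                value = _walk(corpus, obx, [v["OBX.5"], v["NM.1"]])
                if value is None:
                    nonnum = _walk(corpus, obx, [v["OBX.5"], v["ST.1"]])
                    if nonnum is not None:
                        warnings.warn(f"skipping non-numeric OBX value {str(nonnum)!r} at {obx}")
                    continue
                tdate = _walk(corpus, obx, [v["OBX.14"], v["TS.1"]])
                if tdate is None:
                    raise ProjectionError(f"no test date (OBX-14) under {msg}")
                unit = _walk(corpus, obx, [v["OBX.6"], v["CE.1"]])
                labs.append(
                    LabResult(
                        patient_id=str(pid),
                        test_code=str(code),
                        value=Decimal(str(value)),
                        unit=str(unit) if unit is not None else "",
                        test_date=_as_date(tdate),
                        source_uri=str(obx),
                    )
                )

    orders.sort(key=lambda o: (o.patient_id, o.order_date, o.source_uri))
    labs.sort(key=lambda l: (l.patient_id, l.test_date, l.source_uri))
    return orders, labs


# --------------------------------------------------------------------------
# The four patterns


def pattern1_all_orders(
    orders: Sequence[MedicationOrder],
    codes: CodeSet,
) -> list[CaseMatch]:
    """One match per order of a resolved drug, no temporal condition."""
    out = [
        CaseMatch(patient_id=o.patient_id, orders=(o.source_uri,))
        for o in orders
        if o.drug_code in codes
    ]
    return sorted(out, key=_sort_key)


def pattern2_during_each_period(
    orders: Sequence[MedicationOrder],
    labs: Sequence[LabResult],
    codes: CodeSet,
    predicate: Union[EventPredicate, Sequence[EventPredicate]],
) -> list[CaseMatch]:
    """One match per (order, qualifying lab) pair with the lab date inside
    the order's closed medication period."""
    predicates = [predicate] if isinstance(predicate, EventPredicate) else list(predicate)
    by_patient: dict[str, list[LabResult]] = {}
    for lab in labs:
        by_patient.setdefault(lab.patient_id, []).append(lab)
    out = []
    for o in orders:
        if o.drug_code not in codes:
            continue
        start, end = o.period()
        for lab in by_patient.get(o.patient_id, ()):
            if _any_holds(predicates, lab) and start <= lab.test_date <= end:
                out.append(
                    CaseMatch(
                        patient_id=o.patient_id,
                        orders=(o.source_uri,),
                        events=(lab.source_uri,),
                        period=(start, end),
                    )
                )
    return sorted(out, key=_sort_key)


def pattern3_initial_to_final(
    orders: Sequence[MedicationOrder],
    labs: Sequence[LabResult],
    codes: CodeSet,
    predicate: Union[EventPredicate, Sequence[EventPredicate]],
    extend_by_final_duration: bool = False,
) -> list[CaseMatch]:
    """Per patient with at least one resolved order: qualifying labs within
    the closed [initial order date, final order date] period.

    A single order yields a one-day period.  With
    ``extend_by_final_duration`` the period end is pushed to the end of the
    final order's medication period.
    """
    predicates = [predicate] if isinstance(predicate, EventPredicate) else list(predicate)
    per_patient: dict[str, list[MedicationOrder]] = {}
    for o in orders:
        if o.drug_code in codes:
            per_patient.setdefault(o.patient_id, []).append(o)
    by_patient_labs: dict[str, list[LabResult]] = {}
    for lab in labs:
        by_patient_labs.setdefault(lab.patient_id, []).append(lab)
    out = []
    for patient, plist in sorted(per_patient.items()):
        start = min(o.order_date for o in plist)
        end = max(o.order_date for o in plist)
        if extend_by_final_duration:
            end = max(o.period()[1] for o in plist)
        events = tuple(
            lab.source_uri
            for lab in sorted(by_patient_labs.get(patient, ()), key=lambda l: (l.test_date, l.source_uri))
            if _any_holds(predicates, lab) and start <= lab.test_date <= end
        )
        if events:
            out.append(
                CaseMatch(
                    patient_id=patient,
                    orders=tuple(o.source_uri for o in sorted(plist, key=lambda o: (o.order_date, o.source_uri))),
                    events=events,
                    period=(start, end),
                )
            )
    return sorted(out, key=_sort_key)


def pattern4_exclude_pre_initial(
    cases: Sequence[CaseMatch],
    labs: Sequence[LabResult],
    predicate: Union[EventPredicate, Sequence[EventPredicate]],
    window_days: int,
) -> list[CaseMatch]:
    """Drop each case whose patient had a qualifying event in the closed
    window [initial - window_days, initial - 1]; remaining cases unchanged.

    ``window_days=0`` is the identity.  A pure filter: output is a subset
    of the input.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    predicates = [predicate] if isinstance(predicate, EventPredicate) else list(predicate)
    by_patient: dict[str, list[LabResult]] = {}
    for lab in labs:
        by_patient.setdefault(lab.patient_id, []).append(lab)
    out = []
    for case in cases:
        if case.period is None:
            raise ValueError("pattern 4 requires cases carrying a period")
        initial = case.period[0]
        lo = initial - timedelta(days=window_days)
        excluded = window_days > 0 and any(
            _any_holds(predicates, lab) and lo <= lab.test_date < initial
            for lab in by_patient.get(case.patient_id, ())
        )
        if not excluded:
            out.append(case)
    return sorted(out, key=_sort_key)


# --------------------------------------------------------------------------
# Composite query specs (the paper-style Queries 1-3)


@dataclass
class QuerySpec:
    """A composite ADE query: expression + pattern chain + parameters."""

    expression: DrugExpression
    pattern: str  # "1" | "2" | "3" | "3+4"
    predicates: tuple[EventPredicate, ...] = ()
    window_days: int = 0
    extend_by_final_duration: bool = False


def parse_query_spec(data: Union[dict, str, Path]) -> QuerySpec:
    """Build a QuerySpec from a YAML file or an equivalent dict."""
    if not isinstance(data, dict):
        data = yaml.safe_load(Path(data).read_text(encoding="utf-8"))
    e = data["expression"]
    kind = e["kind"]
    if kind == "by_class":
        expr: DrugExpression = ByClass(e["scheme"], e["class"], by_label=e.get("by_label", True))
    elif kind == "by_ade":
        expr = ByAde(e["terms"], float(e["min_frequency"]), freq_bound=e.get("freq_bound", "upper"))
    elif kind == "by_class_and_target":
        expr = ByClassAndTarget(
            e["scheme"], e["class"], e["targets"], by_label=e.get("by_label", True)
        )
    else:
        raise ValueError(f"unknown expression kind {kind!r}")
    predicates = tuple(
        EventPredicate(p["test_code"], p["comparator"], Decimal(str(p["threshold"])))
        for p in data.get("predicates", [])
    )
    return QuerySpec(
        expression=expr,
        pattern=str(data["pattern"]),
        predicates=predicates,
        window_days=int(data.get("window_days", 0)),
        extend_by_final_duration=bool(data.get("extend_by_final_duration", False)),
    )


def run_query(
    spec: QuerySpec,
    kg: DrugKnowledgeGraph,
    corpus: Graph,
    clinical_base: str = DEFAULT_BASE,
) -> list[CaseMatch]:
    """resolve -> project -> pattern chain, with deterministic ordering."""
    codes = resolve(spec.expression, kg)
    orders, labs = project_events(corpus, clinical_base=clinical_base)
    if spec.pattern == "1":
        return pattern1_all_orders(orders, codes)
    if spec.pattern == "2":
        return pattern2_during_each_period(orders, labs, codes, spec.predicates)
    if spec.pattern in ("3", "3+4"):
        cases = pattern3_initial_to_final(
            orders, labs, codes, spec.predicates,
            extend_by_final_duration=spec.extend_by_final_duration,
        )
        if spec.pattern == "3+4":
            cases = pattern4_exclude_pre_initial(cases, labs, spec.predicates, spec.window_days)
        return cases
    raise ValueError(f"unknown pattern {spec.pattern!r}")
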