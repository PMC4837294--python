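"""Temporal pattern evaluation vs exhaustive brute-force scans."""

from __future__ import annotations

import random
import warnings
from datetime import date, timedelta
from decimal import Decimal

import pytest

from hl7rdf import hl7_model as hm
from hl7rdf import rdf_conversion as rc
from hl7rdf import query_expansion as qe
from hl7rdf import temporal_patterns as tp

WBC_LE_3000 = tp.EventPredicate("WBC", "le", Decimal(3000))


def order(patient="P1", code="A", d=date(2013, 5, 28), days=7, uri=None):
    return tp.MedicationOrder(
        patient_id=patient, drug_code=code, dose=Decimal(1), dose_unit="TAB",
        order_date=d, days_prescribed=days,
        source_uri=uri or f"o:{patient}:{code}:{d.isoformat()}:{days}",
    )


def lab(patient="P1", code="WBC", value=2800, d=date(2013, 6, 3), uri=None):
    return tp.LabResult(
        patient_id=patient, test_code=code, value=Decimal(value), unit="U",
        test_date=d, source_uri=uri or f"l:{patient}:{code}:{value}:{d.isoformat()}",
    )


def codeset(*codes):
    return qe.CodeSet(frozenset(codes))


def random_events(rng: random.Random, n_orders: int, n_labs: int, n_patients: int):
    """Random orders/labs with dates clustered so windows overlap often."""
    base = date(2012, 1, 1)
    orders, labs = [], []
    for i in range(n_orders):
        orders.append(order(
            patient=f"P{rng.randrange(n_patients)}",
            code=rng.choice("ABCD"),
            d=base + timedelta(days=rng.randrange(300)),
            days=rng.randrange(1, 15),
            uri=f"o:{i}",
        ))
    for i in range(n_labs):
        labs.append(lab(
            patient=f"P{rng.randrange(n_patients)}",
            code=rng.choice(["WBC", "GLU"]),
            value=rng.choice([2999, 3000, 3001, 2500, 3500]),
            d=base + timedelta(days=rng.randrange(300)),
            uri=f"l:{i}",
        ))
    return orders, labs


# -- exhaustive oracles over all (order, lab) pairs -------------------------

def brute2(orders, labs, codes, pred):
    out = set()
    for o in orders:
        for l in labs:
            if (o.drug_code in codes and l.patient_id == o.patient_id
                    and pred.holds(l)
                    and o.order_date <= l.test_date
                    <= o.order_date + timedelta(days=o.days_prescribed - 1)):
                out.add((o.source_uri, l.source_uri))
    return out


def brute3(orders, labs, codes, pred):
    patients = {o.patient_id for o in orders if o.drug_code in codes}
    out = {}
    for p in patients:
        dates = [o.order_date for o in orders if o.patient_id == p and o.drug_code in codes]
        lo, hi = min(dates), max(dates)
        events = frozenset(
            l.source_uri for l in labs
            if l.patient_id == p and pred.holds(l) and lo <= l.test_date <= hi
        )
        if events:
            out[p] = ((lo, hi), events)
    return out


def brute4(cases, labs, pred, window):
    kept = set()
    for c in cases:
        lo = c.period[0] - timedelta(days=window)
        bad = any(
            l.patient_id == c.patient_id and pred.holds(l)
            and lo <= l.test_date < c.period[0]
            for l in labs
        )
        if window == 0 or not bad:
            kept.add(c.patient_id)
    return kept


class TestPattern1:
    def test_empty_codeset_matches_nothing(self):
        assert tp.pattern1_all_orders([order()], codeset()) == []

    def test_all_orders_match_when_all_codes_resolved(self):
        orders = [order(code=c, uri=f"o:{c}") for c in "AAB"]
        assert len(tp.pattern1_all_orders(orders, codeset("A", "B"))) == 3

    def test_equals_linear_scan_on_random_fixture(self):
        rng = random.Random(1)
        orders, _ = random_events(rng, 200, 0, 20)
        codes = codeset("A", "C")
        got = {m.orders[0] for m in tp.pattern1_all_orders(orders, codes)}
        assert got == {o.source_uri for o in orders if o.drug_code in codes}


class TestPattern2:
    def test_day_interval_is_closed_and_starts_on_order_date(self):
        o = order(d=date(2013, 5, 28), days=7)  # period ends 2013-06-03
        codes = codeset("A")
        in_period = lab(d=date(2013, 6, 3), value=2800)
        day_after = lab(d=date(2013, 6, 4), value=2800)
        on_start = lab(d=date(2013, 5, 28), value=2800)
        matches = tp.pattern2_during_each_period([o], [in_period, day_after, on_start],
                                                 codes, WBC_LE_3000)
        assert {m.events[0] for m in matches} == {in_period.source_uri, on_start.source_uri}

    def test_threshold_is_inclusive(self):
        o = order()
        exactly = lab(value=3000)
        above = lab(value=3001)
        matches = tp.pattern2_during_each_period([o], [exactly, above], codeset("A"), WBC_LE_3000)
        assert [m.events[0] for m in matches] == [exactly.source_uri]

    def test_matched_orders_subset_of_pattern1(self):
        rng = random.Random(2)
        orders, labs = random_events(rng, 150, 150, 15)
        codes = codeset("A", "B")
        p1 = {m.orders[0] for m in tp.pattern1_all_orders(orders, codes)}
        p2 = {m.orders[0] for m in tp.pattern2_during_each_period(orders, labs, codes, WBC_LE_3000)}
        assert p2 <= p1

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_pair_scan(self, seed):
        rng = random.Random(seed)
        orders, labs = random_events(rng, 120, 120, 12)
        codes = codeset("A", "D")
        got = {(m.orders[0], m.events[0])
               for m in tp.pattern2_during_each_period(orders, labs, codes, WBC_LE_3000)}
        assert got == brute2(orders, labs, codes, WBC_LE_3000)

    def test_codeset_monotonicity(self):
        rng = random.Random(3)
        orders, labs = random_events(rng, 100, 100, 10)
        small = {(m.orders[0], m.events[0]) for m in
                 tp.pattern2_during_each_period(orders, labs, codeset("A"), WBC_LE_3000)}
        big = {(m.orders[0], m.events[0]) for m in
               tp.pattern2_during_each_period(orders, labs, codeset("A", "B"), WBC_LE_3000)}
        assert small <= big


class TestPattern3:
    def test_event_between_first_and_last_order(self):
        orders = [order(d=date(2013, 1, 10)), order(d=date(2013, 3, 1))]
        inside = lab(d=date(2013, 2, 1), value=2800)
        outside = lab(d=date(2013, 3, 2), value=2800)
        cases = tp.pattern3_initial_to_final(orders, [inside, outside], codeset("A"), WBC_LE_3000)
        assert len(cases) == 1
        assert cases[0].events == (inside.source_uri,)
        assert cases[0].period == (date(2013, 1, 10), date(2013, 3, 1))

    def test_single_order_gives_one_day_period(self):
        o = order(d=date(2013, 5, 28))
        same_day = lab(d=date(2013, 5, 28), value=2800)
        next_day = lab(d=date(2013, 5, 29), value=2800)
        cases = tp.pattern3_initial_to_final([o], [same_day, next_day], codeset("A"), WBC_LE_3000)
        assert cases[0].period == (date(2013, 5, 28), date(2013, 5, 28))
        assert cases[0].events == (same_day.source_uri,)

    def test_extend_by_final_duration_flag(self):
        o = order(d=date(2013, 5, 28), days=7)
        after_last_order = lab(d=date(2013, 6, 2), value=2800)
        plain = tp.pattern3_initial_to_final([o], [after_last_order], codeset("A"), WBC_LE_3000)
        extended = tp.pattern3_initial_to_final([o], [after_last_order], codeset("A"),
                                                WBC_LE_3000, extend_by_final_duration=True)
        assert plain == [] and len(extended) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_scan(self, seed):
        rng = random.Random(100 + seed)
        orders, labs = random_events(rng, 120, 120, 12)
        codes = codeset("B", "C")
        got = {c.patient_id: (c.period, frozenset(c.events))
               for c in tp.pattern3_initial_to_final(orders, labs, codes, WBC_LE_3000)}
        assert got == brute3(orders, labs, codes, WBC_LE_3000)


class TestPattern4:
    def _case(self, initial=date(2013, 3, 1)):
        return tp.CaseMatch(patient_id="P1", orders=("o:1",), events=("l:1",),
                            period=(initial, initial + timedelta(days=30)))

    def test_event_inside_window_drops_case(self):
        c = self._case()
        pre = lab(d=c.period[0] - timedelta(days=43), value=2800)
        assert tp.pattern4_exclude_pre_initial([c], [pre], WBC_LE_3000, 60) == []

    def test_event_just_outside_window_keeps_case(self):
        c = self._case()
        pre = lab(d=c.period[0] - timedelta(days=61), value=2800)
        assert tp.pattern4_exclude_pre_initial([c], [pre], WBC_LE_3000, 60) == [c]

    def test_event_on_initial_date_does_not_exclude(self):
        c = self._case()
        on_initial = lab(d=c.period[0], value=2800)
        assert tp.pattern4_exclude_pre_initial([c], [on_initial], WBC_LE_3000, 60) == [c]

    def test_window_zero_is_identity(self):
        c = self._case()
        pre = lab(d=c.period[0] - timedelta(days=1), value=2800)
        assert tp.pattern4_exclude_pre_initial([c], [pre], WBC_LE_3000, 0) == [c]

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            tp.pattern4_exclude_pre_initial([self._case()], [], WBC_LE_3000, -1)

    def test_output_subset_of_input_on_random_fixture(self):
        rng = random.Random(4)
        orders, labs = random_events(rng, 120, 150, 12)
        cases = tp.pattern3_initial_to_final(orders, labs, codeset("A", "B"), WBC_LE_3000)
        kept = tp.pattern4_exclude_pre_initial(cases, labs, WBC_LE_3000, 60)
        assert set(map(id, kept)) <= set(map(id, cases)) or all(c in cases for c in kept)
        assert {c.patient_id for c in kept} == brute4(cases, labs, WBC_LE_3000, 60)

    def test_case_without_period_rejected(self):
        c = tp.CaseMatch(patient_id="P1", orders=("o:1",))
        with pytest.raises(ValueError, match="period"):
            tp.pattern4_exclude_pre_initial([c], [], WBC_LE_3000, 60)


class TestProjection:
    def test_round_trip_against_generator_ground_truth(self, small_scenario, projected):
        _, gt, _ = small_scenario
        orders, labs = projected
        got_orders = {(o.patient_id, o.drug_code, o.order_date.isoformat(),
                       o.days_prescribed, str(o.dose)) for o in orders}
        want_orders = {(r["patient_id"], r["drug_code"], r["order_date"],
                        r["days"], r["dose"]) for r in gt.orders}
        assert got_orders == want_orders
        got_labs = {(l.patient_id, l.test_code, str(l.value), l.test_date.isoformat())
                    for l in labs}
        want_labs = {(r["patient_id"], r["test_code"], r["value"], r["test_date"])
                     for r in gt.labs if r["numeric"]}
        assert got_labs == want_labs

    def test_non_numeric_obx_skipped_with_warning(self):
        text = (
            "MSH|^~\\&|H|H|S|H|201306030900||OUL^R22^OUL_R22|L1|P|2.5\r"
            "PID|||0123456789\r"
            "OBR|1||F1|PANEL^chem^LOCAL|||201306030900\r"
            "OBX|1|ST|CULTURE^culture^LOCAL||POSITIVE||||||F|||201306030900\r"
        )
        msg = hm.parse_er7(text, storage_path="0123456789/20130603/OUL-01/L1.txt")
        g = rc.convert_message(msg, rc.ConversionConfig.clinical_default())
        with pytest.warns(UserWarning, match="non-numeric"):
            orders, labs = tp.project_events(g)
        assert labs == [] and orders == []

    def test_missing_patient_id_raises_naming_message(self):
        text = (
            "MSH|^~\\&|H|H|S|H|201305280900||RDE^O11^RDE_O11|M1|P|2.5\r"
            "PID|1\r"
            "ORC|NW|O1\r"
            "RXE||D001^x^MEDIS|1||TAB^t^L\r"
            "TQ1|1|||||7^d|201305280900|201306030900\r"
        )
        msg = hm.parse_er7(text, storage_path="0000000000/20130528/OMP-01/M1.txt")
        g = rc.convert_message(msg, rc.ConversionConfig(include={"PID": [3], "RXE": None, "TQ1": None, "ORC": None}))
        with pytest.raises(tp.ProjectionError, match="M1.txt"):
            tp.project_events(g)


class TestRunQuery:
    def test_query1_is_pattern1_of_resolved_codes(self, kg, small_scenario, projected):
        _, _, corpus = small_scenario
        orders, _ = projected
        from hl7rdf import synthetic_data as sd
        spec = tp.parse_query_spec(sd.query_specs()["q1"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = tp.run_query(spec, kg, corpus)
        codes = qe.resolve(spec.expression, kg)
        assert got == tp.pattern1_all_orders(orders, codes)

    def test_query3_is_pattern4_after_pattern3(self, kg, small_scenario, projected):
        _, _, corpus = small_scenario
        orders, labs = projected
        from hl7rdf import synthetic_data as sd
        spec = tp.parse_query_spec(sd.query_specs()["q3"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = tp.run_query(spec, kg, corpus)
        codes = qe.resolve(spec.expression, kg)
        cases = tp.pattern3_initial_to_final(orders, labs, codes, spec.predicates)
        assert got == tp.pattern4_exclude_pre_initial(cases, labs, spec.predicates, 60)

    def test_unknown_pattern_rejected(self, kg, small_scenario):
        _, _, corpus = small_scenario
        spec = tp.QuerySpec(expression=qe.ByClass("ATC", "x"), pattern="9")
        with pytest.raises(ValueError, match="pattern"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tp.run_query(spec, kg, corpus)

    def test_spec_yaml_parsing(self, tmp_path):
        p = tmp_path / "q.yaml"
        p.write_text(
            "expression:\n  kind: by_ade\n  terms: [leukopenia]\n  min_frequency: 0.3\n"
            "pattern: '2'\npredicates:\n  - {test_code: WBC, comparator: le, threshold: 3000}\n",
            encoding="utf-8",
        )
        spec = tp.parse_query_spec(p)
        assert spec.pattern == "2"
        assert spec.expression.terms == ("leukopenia",)
        assert spec.predicates[0].holds(lab(value=3000))
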