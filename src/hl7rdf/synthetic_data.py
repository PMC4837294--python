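"""Seeded generators for SS-MIX2-style message corpora and toy linked drug
knowledge with planted, exactly recoverable adverse-event cases.

No real hospital corpus or licensed drug-database dump ships with the
package, so every other module is exercised against synthetic data built
here.  The generator targets logical coverage, not epidemiological realism:

* a fixed drug catalog mirrors the linked structure of the public
  resources (two classification schemes with three hierarchy levels,
  compounds with receptor targets, side-effect records whose frequency
  bounds straddle the 30% query threshold, and a local code terminology);
* the corpus generator plants K1 plain medication orders, K2 in-period
  laboratory events, K3 between-initial-and-final events and K4
  pre-initial exclusion cases (each K4 case is also a K3-shaped case), and
  surrounds every planted case with decoys sitting exactly one unit
  outside each boundary — one day outside windows, one unit past value
  thresholds, codes one link outside the resolved set — so the interval
  and comparison conventions are pinned by construction;
* ground truth (expected matches per query) is computed while planting,
  never by the pipeline under test.

Synthetic patient identifiers are zero-padded 10-digit strings; the same
seed reproduces a byte-identical directory tree.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "drug_catalog",
    "generate_knowledge",
    "generate_corpus",
    "query_specs",
    "random_toy_knowledge",
    "enumerate_by_class",
    "enumerate_by_ade",
    "enumerate_by_class_and_target",
]

DATA_TYPE_ORDER = "OMP-01"  # medication-order storage data type
DATA_TYPE_LAB = "OUL-01"  # laboratory-result storage data type


class SpecError(ValueError):
    """The scenario is internally inconsistent."""


@dataclass
class ScenarioSpec:
    """Study conditions for one synthetic corpus.

    ``k1``..``k4`` are the planted positive-case counts per temporal
    pattern; every case comes with at least three one-unit-off decoys.
    """

    seed: int = 0
    k1_all_orders: int = 50
    k2_in_period: int = 20
    k3_between: int = 10
    k4_excluded: int = 5
    n_decoy_patients: int = 5
    start: date = date(2011, 1, 1)
    end: date = date(2013, 12, 31)

    def __post_init__(self) -> None:
        for name in ("k1_all_orders", "k2_in_period", "k3_between", "k4_excluded", "n_decoy_patients"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if (self.end - self.start).days < 200:
            raise SpecError("date range must span at least 200 days (temporal margins)")


@dataclass
class GroundTruth:
    """Planted event tables and the expected match set per query."""

    orders: list[dict] = dc_field(default_factory=list)
    labs: list[dict] = dc_field(default_factory=list)
    expected_q1: set = dc_field(default_factory=set)  # (patient, code, order_date)
    expected_q2: set = dc_field(default_factory=set)  # (patient, code, order_date, test_code, test_date)
    expected_q3: set = dc_field(default_factory=set)  # (patient, first_date, last_date)
    n_messages: int = 0


# --------------------------------------------------------------------------
# Fixed drug catalog (the scenario's knowledge side)


def drug_catalog() -> dict[str, pd.DataFrame]:
    """The toy linked drug data: two schemes, compounds, side effects, codes.

    Frequencies around the leukopenia records are planted at 0.29 / 0.30 /
    0.31 so the 30%-or-higher test is pinned on both sides of the
    boundary.
    """
    classes = pd.DataFrame(
        [
            # ATC-like scheme (3 levels under the query roots)
            ("ATC:C09", "renin angiotensin inhibitors", "ATC", ""),
            ("ATC:C09A", "ace inhibitors", "ATC", "ATC:C09"),
            ("ATC:C09AA", "ace inhibitors, plain", "ATC", "ATC:C09A"),
            ("ATC:C09C", "angiotensin ii antagonists", "ATC", "ATC:C09"),
            ("ATC:L01", "antineoplastic agents", "ATC", ""),
            ("ATC:L01A", "alkylating agents", "ATC", "ATC:L01"),
            ("ATC:L01B", "antimetabolites", "ATC", "ATC:L01"),
            ("ATC:L01C", "plant alkaloids", "ATC", "ATC:L01"),
            ("ATC:N02", "analgesics", "ATC", ""),
            ("ATC:N02B", "other analgesics and antipyretics", "ATC", "ATC:N02"),
            # USP-like scheme
            ("USP:PSY", "antipsychotics", "USP", ""),
            ("USP:PSY.A", "atypical antipsychotics", "USP", "USP:PSY"),
            ("USP:PSY.T", "typical antipsychotics", "USP", "USP:PSY"),
        ],
        columns=["id", "label", "scheme", "parent"],
    )
    compounds = pd.DataFrame(
        [
            ("KD001", "enalapril", ""),
            ("KD002", "candesartan", ""),
            ("KD003", "lisinopril", ""),
            ("KD010", "cyclophosphamide", ""),
            ("KD011", "methotrexate", ""),
            ("KD012", "vincristine", ""),
            ("KD020", "olanzapine", "5HT2C;H1;D2"),
            ("KD021", "quetiapine", "H1"),
            ("KD022", "risperidone", "D2"),
            ("KD023", "haloperidol", "D2"),
            ("KD030", "acetaminophen", ""),
        ],
        columns=["id", "label", "targets"],
    )
    links = pd.DataFrame(
        [
            ("KD001", "ATC:C09AA"),
            ("KD002", "ATC:C09C"),
            ("KD003", "ATC:C09A"),
            ("KD010", "ATC:L01A"),
            ("KD011", "ATC:L01B"),
            ("KD012", "ATC:L01C"),
            ("KD020", "USP:PSY.A"),
            ("KD021", "USP:PSY.A"),
            ("KD022", "USP:PSY.A"),
            ("KD023", "USP:PSY.T"),
            ("KD030", "ATC:N02B"),
        ],
        columns=["compound_id", "class_id"],
    )
    sideeffects = pd.DataFrame(
        [
            # link_id, term, lower, upper — uppers pinned at the 0.30 boundary
            ("ATC:L01A", "Leukopenia", "0.10", "0.31"),
            ("ATC:L01A", "Neutropenia", "0.05", "0.35"),
            ("ATC:L01B", "Leukopenia", "0.05", "0.30"),
            ("ATC:L01C", "Leukopenia", "0.01", "0.29"),
            ("ATC:N02B", "Nausea", "0.00", "0.10"),
            ("USP:PSY.A", "Hyperglycaemia", "0.05", "0.20"),
        ],
        columns=["link_id", "ade_term", "freq_lower", "freq_upper"],
    )
    codes = pd.DataFrame(
        [
            ("MED001", "enalapril 5mg tab", "KD001"),
            ("MED002", "enalapril 10mg tab", "KD001"),
            ("MED003", "candesartan 8mg tab", "KD002"),
            ("MED004", "lisinopril 10mg tab", "KD003"),
            ("MED010", "cyclophosphamide 50mg tab", "KD010"),
            ("MED011", "methotrexate 2mg tab", "KD011"),
            ("MED012", "vincristine 1mg inj", "KD012"),
            ("MED020", "olanzapine 5mg tab", "KD020"),
            ("MED021", "quetiapine 25mg tab", "KD021"),
            ("MED022", "risperidone 1mg tab", "KD022"),
            ("MED023", "haloperidol 1mg tab", "KD023"),
            ("MED030", "acetaminophen 300mg tab", "KD030"),
        ],
        columns=["code", "label", "compound_id"],
    )
    return {
        "classes": classes,
        "compounds": compounds,
        "links": links,
        "sideeffects": sideeffects,
        "codes": codes,
    }


def generate_knowledge(
    out_dir: Optional[Union[str, Path]] = None,
    tables: Optional[dict[str, pd.DataFrame]] = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, frozenset[str]]]:
    """Return (tables, expected code set per query expression); optionally
    write the CSV source files."""
    tables = tables or drug_catalog()
    expected = {
        "q1": enumerate_by_class(tables, "ATC", "renin angiotensin inhibitors"),
        "q2": enumerate_by_ade(tables, ("leukopenia", "neutropenia"), 0.30),
        "q3": enumerate_by_class_and_target(
            tables, "USP", "atypical antipsychotics", {"5HT2C", "H1"}
        ),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(out / f"{name}.csv", index=False)
    return tables, expected


# --------------------------------------------------------------------------
# Independent table-level enumeration (oracle for resolve())


def _descendants(classes: pd.DataFrame, roots: set[str]) -> set[str]:
    children: dict[str, list[str]] = {}
    for _, row in classes.iterrows():
        if row["parent"]:
            children.setdefault(row["parent"], []).append(row["id"])
    out = set(roots)
    frontier = list(roots)
    while frontier:
        c = frontier.pop()
        for child in children.get(c, ()):
            if child not in out:
                out.add(child)
                frontier.append(child)
    return out


def _codes_of_compounds(tables: dict[str, pd.DataFrame], compounds: set[str]) -> frozenset[str]:
    codes = tables["codes"]
    return frozenset(codes[codes["compound_id"].isin(compounds)]["code"])


def _compounds_under(tables: dict[str, pd.DataFrame], class_ids: set[str]) -> set[str]:
    links = tables["links"]
    return set(links[links["class_id"].isin(class_ids)]["compound_id"])


def enumerate_by_class(
    tables: dict[str, pd.DataFrame], scheme: str, label: str
) -> frozenset[str]:
    """Brute-force class -> all subclasses -> compounds -> codes."""
    classes = tables["classes"]
    roots = set(
        classes[
            (classes["scheme"] == scheme)
            & (classes["label"].str.strip().str.casefold() == label.strip().casefold())
        ]["id"]
    )
    return _codes_of_compounds(tables, _compounds_under(tables, _descendants(classes, roots)))


def enumerate_by_ade(
    tables: dict[str, pd.DataFrame],
    terms,
    min_frequency: float,
    freq_bound: str = "upper",
) -> frozenset[str]:
    """Brute-force side-effect record filter -> compounds -> codes."""
    if isinstance(terms, str):
        terms = (terms,)
    wanted = {t.strip().casefold() for t in terms}
    col = "freq_upper" if freq_bound == "upper" else "freq_lower"
    se = tables["sideeffects"]
    hits = se[
        se["ade_term"].str.strip().str.casefold().isin(wanted)
        & (se[col].astype(float) >= min_frequency)
    ]
    class_ids = set(tables["classes"]["id"])
    compound_ids = set(tables["compounds"]["id"])
    compounds: set[str] = set()
    for link_id in hits["link_id"]:
        if link_id in class_ids:
            compounds |= _compounds_under(
                tables, _descendants(tables["classes"], {link_id})
            )
        elif link_id in compound_ids:
            compounds.add(link_id)
    return _codes_of_compounds(tables, compounds)


def enumerate_by_class_and_target(
    tables: dict[str, pd.DataFrame], scheme: str, label: str, targets
) -> frozenset[str]:
    """Class enumeration intersected with a target (union) filter."""
    targets = set(targets)
    classes = tables["classes"]
    roots = set(
        classes[
            (classes["scheme"] == scheme)
            & (classes["label"].str.strip().str.casefold() == label.strip().casefold())
        ]["id"]
    )
    compounds = _compounds_under(tables, _descendants(classes, roots))
    cmp_tbl = tables["compounds"]
    keep = {
        row["id"]
        for _, row in cmp_tbl.iterrows()
        if row["id"] in compounds
        and targets & {t for t in str(row["targets"]).split(";") if t}
    }
    return _codes_of_compounds(tables, keep)


def random_toy_knowledge(rng: random.Random, n_classes: int = 12, n_compounds: int = 8) -> dict[str, pd.DataFrame]:
    """A random toy knowledge base for oracle property tests.

    Class parents always point at lower-numbered classes of the same
    scheme, so the hierarchy is acyclic by construction.  Side-effect
    upper bounds are drawn from a pool that includes the 0.29/0.30/0.31
    boundary values.
    """
    schemes = ["ATC", "USP"]
    class_rows = []
    per_scheme: dict[str, list[str]] = {s: [] for s in schemes}
    for i in range(n_classes):
        scheme = schemes[i % 2]
        cid = f"{scheme}:C{i:03d}"
        parent = rng.choice(per_scheme[scheme] + [""]) if per_scheme[scheme] else ""
        class_rows.append((cid, f"class {i}", scheme, parent))
        per_scheme[scheme].append(cid)
    classes = pd.DataFrame(class_rows, columns=["id", "label", "scheme", "parent"])

    target_pool = ["5HT2C", "H1", "D2", "M1", "COX1"]
    compound_rows, link_rows, code_rows = [], [], []
    for i in range(n_compounds):
        kid = f"K{i:03d}"
        targets = ";".join(sorted(rng.sample(target_pool, rng.randint(0, 3))))
        compound_rows.append((kid, f"compound {i}", targets))
        for cid in rng.sample(list(classes["id"]), rng.randint(1, 2)):
            link_rows.append((kid, cid))
        for j in range(rng.randint(0, 3)):
            code_rows.append((f"M{i:03d}{j}", f"code {i}.{j}", kid))
    compounds = pd.DataFrame(compound_rows, columns=["id", "label", "targets"])
    links = pd.DataFrame(link_rows, columns=["compound_id", "class_id"]).drop_duplicates()
    codes = pd.DataFrame(code_rows, columns=["code", "label", "compound_id"])

    term_pool = ["Leukopenia", "Neutropenia", "Nausea"]
    upper_pool = [0.29, 0.30, 0.31, 0.10, 0.50, 0.90]
    se_rows = []
    attachables = list(classes["id"]) + list(compounds["id"])
    for _ in range(rng.randint(2, 8)):
        upper = rng.choice(upper_pool)
        lower = round(rng.uniform(0, upper), 2)
        se_rows.append((rng.choice(attachables), rng.choice(term_pool), f"{lower}", f"{upper}"))
    sideeffects = pd.DataFrame(se_rows, columns=["link_id", "ade_term", "freq_lower", "freq_upper"])
    return {
        "classes": classes,
        "compounds": compounds,
        "links": links,
        "sideeffects": sideeffects,
        "codes": codes,
    }


# --------------------------------------------------------------------------
# ER7 corpus generation


def _ts(d: date, hhmm: str = "0900") -> str:
    return d.strftime("%Y%m%d") + hhmm


def _msh(message_code: str, structure: str, d: date, ctrl: str) -> str:
    return (
        f"MSH|^~\\&|HIS|HOSP|SSMIX|HOSP|{_ts(d)}||{message_code}^{structure}"
        f"|{ctrl}|P|2.5"
    )


def _order_segments(order_no: str, code: str, label: str, dose: str, d: date, days: int) -> list[str]:
    end = d + timedelta(days=days - 1)
    return [
        f"ORC|NW|{order_no}",
        f"RXE||{code}^{label}^MEDIS|{dose}||TAB^tablet^LOCAL",
        f"TQ1|1|||||{days}^d|{_ts(d)}|{_ts(end)}",
    ]


def _rde_text(patient: str, ctrl: str, d: date, orders: list[tuple[str, str, str, str, int]]) -> str:
    segs = [_msh("RDE^O11", "RDE_O11", d, ctrl), f"PID|||{patient}"]
    for i, (code, label, dose, _, days) in enumerate(orders, start=1):
        segs += _order_segments(f"{ctrl}-{i}", code, label, dose, d, days)
    return "\r".join(segs) + "\r"


def _oul_text(patient: str, ctrl: str, d: date, results: list[tuple[str, str, str, str, str, date]]) -> str:
    """results: (value_type, test_code, test_name, value, unit, test_date)."""
    segs = [_msh("OUL^R22", "OUL_R22", d, ctrl), f"PID|||{patient}", f"OBR|1||{ctrl}-R|PANEL^chemistry panel^LOCAL|||{_ts(d)}"]
    for i, (vtype, tcode, tname, value, unit, tdate) in enumerate(results, start=1):
        segs.append(f"OBX|{i}|{vtype}|{tcode}^{tname}^LOCAL||{value}|{unit}|||||F|||{_ts(tdate)}")
    return "\r".join(segs) + "\r"


class _CorpusWriter:
    def __init__(self, out_dir: Path):
        self.out = out_dir
        self.counter = 0

    def _next(self) -> str:
        self.counter += 1
        return f"MSG{self.counter:06d}"

    def _write(self, patient: str, d: date, data_type: str, text: str) -> str:
        ctrl = text.split("|")[9]
        rel = Path(patient) / d.strftime("%Y%m%d") / data_type / f"{ctrl}.txt"
        path = self.out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text, encoding="utf-8")
        return str(rel).replace("\\", "/")

    def rde(self, patient: str, d: date, orders) -> str:
        return self._write(patient, d, DATA_TYPE_ORDER, _rde_text(patient, self._next(), d, orders))

    def oul(self, patient: str, d: date, results) -> str:
        return self._write(patient, d, DATA_TYPE_LAB, _oul_text(patient, self._next(), d, results))


_CODE_LABELS: dict[str, str] = {}


def _code_label(code: str) -> str:
    if not _CODE_LABELS:
        for _, row in drug_catalog()["codes"].iterrows():
            _CODE_LABELS[row["code"]] = row["label"]
    return _CODE_LABELS.get(code, "unknown drug")


def generate_corpus(
    spec: ScenarioSpec,
    out_dir: Union[str, Path],
) -> GroundTruth:
    """Write an SS-MIX2-style directory of ER7 files with planted cases.

    Layout: ``patientID/YYYYMMDD/dataType/messageFile``, one message per
    file; RDE_O11 messages carry MSH/PID/ORC/RXE/TQ1 (some with two ORDER
    groups), OUL_R22 messages MSH/PID/OBR/OBX (some with two OBX).  The
    same seed yields a byte-identical tree.
    """
    rng = random.Random(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    w = _CorpusWriter(out)
    gt = GroundTruth()

    q1_codes = ["MED001", "MED002", "MED003", "MED004"]
    q2_codes = ["MED010", "MED011"]
    q3_codes = ["MED020", "MED021"]
    margin = 70  # headroom for pre-initial windows and period tails
    span = (spec.end - spec.start).days - 2 * margin

    patient_counter = 0

    def next_patient() -> str:
        nonlocal patient_counter
        patient_counter += 1
        return f"{patient_counter:010d}"

    def rand_date() -> date:
        return spec.start + timedelta(days=margin + rng.randrange(span))

    def add_order(patient: str, code: str, d: date, days: int, label_tag: str, bundle=None) -> None:
        dose = f"{rng.randrange(1, 4)}"
        entry = (code, _code_label(code), dose, label_tag, days)
        if bundle is None:
            w.rde(patient, d, [entry])
        else:
            w.rde(patient, d, [entry] + bundle)
        gt.orders.append(
            {"patient_id": patient, "drug_code": code, "order_date": d.isoformat(),
             "days": days, "dose": dose, "label": label_tag}
        )

    def add_lab(patient: str, tcode: str, value: str, d: date, label_tag: str,
                vtype: str = "NM", extra_obx=None) -> None:
        unit = {"WBC": "10*3/uL", "RBC": "10*6/uL", "GLU": "mg/dL", "HBA1C": "%"}.get(tcode, "U/L")
        results = [(vtype, tcode, tcode.lower(), value, unit, d)]
        if extra_obx:
            results += extra_obx
        w.oul(patient, d, results)
        for vt, tc, _, val, _, td in results:
            gt.labs.append(
                {"patient_id": patient, "test_code": tc, "value": val,
                 "test_date": td.isoformat(), "label": label_tag, "numeric": vt == "NM"}
            )

    # ---- K1: plain medication orders (pattern 1) -------------------------
    for i in range(spec.k1_all_orders):
        p = next_patient()
        d = rand_date()
        code = q1_codes[i % len(q1_codes)]
        days = rng.randrange(3, 15)
        dose = f"{rng.randrange(1, 4)}"
        decoy = ("MED030", _code_label("MED030"), dose, "k1_decoy_bundled", days)
        add_order(p, code, d, days, f"k1_pos_{i}", bundle=[decoy])
        gt.orders.append(
            {"patient_id": p, "drug_code": "MED030", "order_date": d.isoformat(),
             "days": days, "dose": dose, "label": f"k1_decoy_bundled_{i}"}
        )
        add_order(p, "MED023", rand_date(), 7, f"k1_decoy_a_{i}")
        add_order(p, "MED030", rand_date(), 7, f"k1_decoy_b_{i}")
        gt.expected_q1.add((p, code, d.isoformat()))

    # ---- K2: in-period lab events (pattern 2) ----------------------------
    for i in range(spec.k2_in_period):
        p = next_patient()
        d = rand_date()
        days = rng.randrange(5, 11)
        end = d + timedelta(days=days - 1)
        code = q2_codes[i % len(q2_codes)]
        add_order(p, code, d, days, f"k2_order_{i}")
        value = "3000" if i == 0 else f"{rng.randrange(2000, 3000)}"
        lab_date = d + timedelta(days=rng.randrange(0, days))
        add_lab(p, "WBC", value, lab_date, f"k2_pos_{i}",
                extra_obx=[("NM", "RBC", "rbc", "450", "10*6/uL", lab_date)])
        # decoys: one day outside the period, one unit past the threshold,
        # and an unresolved drug (boundary 0.29 class) with a qualifying lab
        add_lab(p, "WBC", "2800", end + timedelta(days=1), f"k2_decoy_day_{i}")
        add_lab(p, "WBC", "3001", d + timedelta(days=rng.randrange(0, days)), f"k2_decoy_value_{i}")
        decoy_d = d + timedelta(days=100)
        add_order(p, "MED012", decoy_d, 7, f"k2_decoy_code_{i}")
        add_lab(p, "WBC", "2700", decoy_d + timedelta(days=2), f"k2_decoy_code_lab_{i}")
        if i == 0:
            add_lab(p, "CULTURE", "POSITIVE", d + timedelta(days=1), "k2_nonnumeric", vtype="ST")
        gt.expected_q2.add((p, code, d.isoformat(), "WBC", lab_date.isoformat()))

    # ---- K3 / K4: between initial and final medication (patterns 3+4) ----
    def plant_between(i: int, excluded: bool) -> None:
        p = next_patient()
        d1 = rand_date()
        gap = rng.randrange(30, 61)
        d2 = d1 + timedelta(days=gap)
        add_order(p, q3_codes[i % 2], d1, 7, f"{'k4' if excluded else 'k3'}_order_first_{i}")
        add_order(p, q3_codes[(i + 1) % 2], d2, 7, f"{'k4' if excluded else 'k3'}_order_last_{i}")
        if i % 2 == 0:
            tcode, value = "GLU", "220"
        else:
            tcode, value = "HBA1C", "7.2"
        lab_date = d1 + timedelta(days=rng.randrange(0, gap + 1))
        add_lab(p, tcode, value, lab_date, f"{'k4' if excluded else 'k3'}_pos_{i}")
        # decoys: outside period, below threshold, just outside the window
        add_lab(p, "GLU", "230", d2 + timedelta(days=1), f"k3_decoy_day_{i}")
        add_lab(p, "GLU", "199", d1 + timedelta(days=rng.randrange(0, gap + 1)), f"k3_decoy_value_{i}")
        add_lab(p, "GLU", "250", d1 - timedelta(days=61), f"k3_decoy_window_{i}")
        add_order(p, "MED022", d1 + timedelta(days=5), 7, f"k3_decoy_target_{i}")
        if excluded:
            # a qualifying event inside [initial-60, initial-1]
            back = 60 if i == 0 else rng.randrange(1, 61)
            add_lab(p, "GLU", "240", d1 - timedelta(days=back), f"k4_exclusion_{i}")
        else:
            gt.expected_q3.add((p, d1.isoformat(), d2.isoformat()))

    for i in range(spec.k3_between):
        plant_between(i, excluded=False)
    for i in range(spec.k4_excluded):
        plant_between(i, excluded=True)

    # ---- decoy-only patients --------------------------------------------
    for i in range(spec.n_decoy_patients):
        p = next_patient()
        add_order(p, "MED030", rand_date(), 7, f"decoy_patient_order_{i}")
        add_lab(p, "WBC", "2500", rand_date(), f"decoy_patient_lab_{i}")

    gt.n_messages = w.counter
    return gt


def query_specs() -> dict[str, dict]:
    """The three ADE query specs matched to the planted scenario, as plain
    dicts accepted by :func:`hl7rdf.temporal_patterns.parse_query_spec`."""
    return {
        "q1": {
            "expression": {"kind": "by_class", "scheme": "ATC", "class": "renin angiotensin inhibitors"},
            "pattern": "1",
        },
        "q2": {
            "expression": {"kind": "by_ade", "terms": ["leukopenia", "neutropenia"], "min_frequency": 0.30},
            "pattern": "2",
            "predicates": [{"test_code": "WBC", "comparator": "le", "threshold": 3000}],
        },
        "q3": {
            "expression": {
                "kind": "by_class_and_target",
                "scheme": "USP",
                "class": "atypical antipsychotics",
                "targets": ["5HT2C", "H1"],
            },
            "pattern": "3+4",
            "predicates": [
                {"test_code": "GLU", "comparator": "ge", "threshold": 200},
                {"test_code": "HBA1C", "comparator": "ge", "threshold": 6.5},
            ],
            "window_days": 60,
        },
    }
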