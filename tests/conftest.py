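"""Shared fixtures: toy knowledge graph and a small converted corpus."""

from __future__ import annotations

import warnings

import pytest
from rdflib import Graph

from hl7rdf import linked_drug_data as ld
from hl7rdf import rdf_conversion as rc
from hl7rdf import synthetic_data as sd
from hl7rdf import temporal_patterns as tp


@pytest.fixture(scope="session")
def catalog():
    tables, expected = sd.generate_knowledge()
    return tables, expected


@pytest.fixture(scope="session")
def kg(catalog):
    tables, _ = catalog
    graph = ld.load_sources(
        tables["classes"], tables["compounds"], tables["sideeffects"],
        tables["codes"], tables["links"],
    )
    return ld.materialize_subclass_closure(graph)


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A small planted corpus: ER7 tree, ground truth, converted graph."""
    root = tmp_path_factory.mktemp("ssmix2")
    spec = sd.ScenarioSpec(
        seed=11, k1_all_orders=4, k2_in_period=3, k3_between=2, k4_excluded=2,
        n_decoy_patients=1,
    )
    gt = sd.generate_corpus(spec, root)
    corpus = Graph()
    for _, g in rc.convert_directory(root, rc.ConversionConfig.clinical_default()):
        for t in g:
            corpus.add(t)
    return root, gt, corpus


@pytest.fixture(scope="session")
def projected(small_scenario):
    _, _, corpus = small_scenario
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        orders, labs = tp.project_events(corpus)
    return orders, labs
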