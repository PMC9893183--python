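"""Phenotype/disease overlap: membership rules and edge rewiring."""

import pandas as pd
import pytest

from medkg.ingest import OntologyGraph, parse_obo
from medkg.overlap import compute_overlap_set, rewire_edges
from medkg.tables import TriplesTable


def _ontology(terms, xrefs=(), source="mock"):
    ont = OntologyGraph(source=source)
    for t in terms:
        ont.terms[t] = {"name": t, "definition": "", "is_obsolete": False}
    ont.xrefs = list(xrefs)
    return ont


def _table(rows, tag="t"):
    return TriplesTable(pd.DataFrame(rows), resource_tag=tag)


def _pp_edge(a, b):
    return {
        "relation": "phenotype_phenotype",
        "x_id": a, "x_type": "effect/phenotype", "x_source": "HPO",
        "y_id": b, "y_type": "effect/phenotype", "y_source": "HPO",
    }


def _pheno_protein(p, g):
    return {
        "relation": "phenotype_protein",
        "x_id": p, "x_type": "effect/phenotype", "x_source": "HPO",
        "y_id": g, "y_type": "gene/protein", "y_source": "NCBI",
    }


def _drug_effect(d, p):
    return {
        "relation": "drug_effect",
        "x_id": d, "x_type": "drug", "x_source": "DrugBank",
        "y_id": p, "y_type": "effect/phenotype", "y_source": "HPO",
    }


# ---------------------------------------------------------------------------
# Overlap membership
# ---------------------------------------------------------------------------


def test_same_numeric_id_rule():
    pheno = _ontology(["HP:0000123", "HP:0000999"])
    disease = _ontology(["MONDO:0000123"])
    overlap = compute_overlap_set(pheno, disease)
    assert overlap.members == {"HP:0000123"}
    assert overlap.evidence["HP:0000123"] == "same-numeric-id"
    assert overlap.mapping["HP:0000123"] == ("MONDO:0000123",)


def test_xref_rule():
    pheno = _ontology(["HP:0009999"])
    disease = _ontology(["MONDO:0000001"], xrefs=[("MONDO:0000001", "HP", "0009999")])
    overlap = compute_overlap_set(pheno, disease)
    assert overlap.members == {"HP:0009999"}
    assert overlap.evidence["HP:0009999"] == "xref-mapped"


def test_both_rules_recorded():
    pheno = _ontology(["HP:0000123"])
    disease = _ontology(
        ["MONDO:0000123", "MONDO:0000777"],
        xrefs=[("MONDO:0000777", "HP", "0000123")],
    )
    overlap = compute_overlap_set(pheno, disease)
    assert overlap.evidence["HP:0000123"] == "both"
    assert overlap.mapping["HP:0000123"] == ("MONDO:0000123", "MONDO:0000777")


def test_fixture_planted_overlap(fixture_bundle):
    pheno = parse_obo(fixture_bundle.paths["phenotype_obo"], "HPO")
    disease = parse_obo(fixture_bundle.paths["disease_obo"], "MONDO")
    overlap = compute_overlap_set(pheno, disease)
    assert overlap.members == fixture_bundle.truth.overlap_members


def test_zero_overlap_fraction_gives_empty_set():
    from medkg.fixtures import FixtureSpec, make_mock_ontologies
    import tempfile

    spec = FixtureSpec(rng_seed=3, overlap_fraction=0.0, n_subtype_families=2,
                       n_distractor_diseases=5, n_phenotypes=8)
    paths, truth, _ = make_mock_ontologies(spec, tempfile.mkdtemp())
    assert truth.overlap_members == set()
    overlap = compute_overlap_set(
        parse_obo(paths["phenotype_obo"], "HPO"), parse_obo(paths["disease_obo"], "MONDO")
    )
    assert overlap.members == set()


# ---------------------------------------------------------------------------
# Rewiring rules
# ---------------------------------------------------------------------------


@pytest.fixture
def overlap_p():
    pheno = _ontology(["HP:0000005", "HP:0000006", "HP:0000100"])
    disease = _ontology(["MONDO:0000005", "MONDO:0000006"])
    return compute_overlap_set(pheno, disease)


def test_rewire_one_endpoint_in_p(overlap_p):
    tables, log = rewire_edges([_table([_pp_edge("HP:0000005", "HP:0000100")])], overlap_p)
    row = tables[0].df.iloc[0]
    assert row["relation"] == "disease_phenotype_positive"
    assert row["x_id"] == "MONDO:0000005" and row["x_type"] == "disease"
    assert row["y_id"] == "HP:0000100" and row["y_type"] == "effect/phenotype"
    assert log.rows[0]["action"] == "converted"


def test_rewire_both_endpoints_in_p(overlap_p):
    tables, _ = rewire_edges([_table([_pp_edge("HP:0000005", "HP:0000006")])], overlap_p)
    row = tables[0].df.iloc[0]
    assert row["relation"] == "disease_disease"
    assert {row["x_id"], row["y_id"]} == {"MONDO:0000005", "MONDO:0000006"}


def test_rewire_protein_phenotype_converted(overlap_p):
    tables, _ = rewire_edges([_table([_pheno_protein("HP:0000005", "1001")])], overlap_p)
    row = tables[0].df.iloc[0]
    assert row["relation"] == "disease_protein"
    assert row["x_id"] == "MONDO:0000005"


def test_rewire_drops_drug_and_disease_phenotype_edges(overlap_p):
    dp = {
        "relation": "disease_phenotype_positive",
        "x_id": "MONDO:0000900", "x_type": "disease", "x_source": "MONDO",
        "y_id": "HP:0000005", "y_type": "effect/phenotype", "y_source": "HPO",
    }
    tables, log = rewire_edges(
        [_table([_drug_effect("DB1", "HP:0000005"), dp])], overlap_p
    )
    assert len(tables[0]) == 0
    assert log.n_dropped == 2
    assert all(r["reason"] for r in log.rows)


def test_rewire_leaves_non_p_edges_bitwise_unchanged(overlap_p):
    rows = [_pp_edge("HP:0000100", "HP:0000101"), _drug_effect("DB1", "HP:0000100")]
    tables, log = rewire_edges([_table(rows)], overlap_p)
    pd.testing.assert_frame_equal(tables[0].canonical(), _table(rows).canonical())
    assert len(log.rows) == 0


def test_rewire_conservation_and_fixed_point(overlap_p):
    rows = [
        _pp_edge("HP:0000005", "HP:0000100"),
        _pp_edge("HP:0000005", "HP:0000006"),
        _pheno_protein("HP:0000006", "1001"),
        _drug_effect("DB1", "HP:0000005"),
        _pp_edge("HP:0000100", "HP:0000101"),
    ]
    tables, log = rewire_edges([_table(rows)], overlap_p)
    # conservation: every input edge appears exactly once in output-or-log
    n_out = len(tables[0])
    n_expanded = sum(r["multiplicity"] - 1 for r in log.rows if r["action"] == "converted")
    assert len(rows) == (n_out - n_expanded) + log.n_dropped
    # fixed point: a second pass changes nothing
    tables2, log2 = rewire_edges(tables, overlap_p)
    pd.testing.assert_frame_equal(tables2[0].canonical(), tables[0].canonical())
    assert len(log2.rows) == 0


def test_rewire_multi_mapping_expands():
    pheno = _ontology(["HP:0000123"])
    disease = _ontology(
        ["MONDO:0000123", "MONDO:0000777"],
        xrefs=[("MONDO:0000777", "HP", "0000123")],
    )
    overlap = compute_overlap_set(pheno, disease)
    tables, log = rewire_edges([_table([_pheno_protein("HP:0000123", "1001")])], overlap)
    assert sorted(tables[0].df["x_id"]) == ["MONDO:0000123", "MONDO:0000777"]
    assert log.rows[0]["multiplicity"] == 2


def test_rewire_unmapped_member_is_contract_error(overlap_p):
    overlap_p.mapping["HP:0000005"] = ()
    with pytest.raises(ValueError, match="without a disease mapping"):
        rewire_edges([_table([_pp_edge("HP:0000005", "HP:0000100")])], overlap_p)
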