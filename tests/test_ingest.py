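"""Resource adapters: OBO parsing, per-resource filters, identifier
mapping, and the conservation-with-logging contract."""

import json

import pandas as pd
import pytest

from medkg import ingest
from medkg.ingest import (
    IngestConfig,
    OboParseError,
    filter_expression_calls,
    filter_side_effects,
    map_identifiers,
    merge_drug_protein_partners,
    parse_drug_interactions,
    parse_obo,
    select_umls_disorders,
)
from medkg.tables import TriplesTable, XrefMap


# ---------------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------------


def _write_obo(tmp_path, text):
    p = tmp_path / "mini.obo"
    p.write_text("format-version: 1.2\nontology: mini\n" + text, encoding="utf-8")
    return p


def test_parse_obo_single_stanza(tmp_path):
    ont = parse_obo(_write_obo(tmp_path, "\n[Term]\nid: MONDO:0000001\nname: disease\n"))
    assert len(ont.terms) == 1
    assert ont.terms["MONDO:0000001"]["name"] == "disease"
    assert ont.is_a == []


def test_parse_obo_is_a_edge_and_xref(tmp_path):
    text = (
        "\n[Term]\nid: MONDO:0000001\nname: disease\n"
        "\n[Term]\nid: MONDO:0000002\nname: child\nis_a: MONDO:0000001 ! disease\n"
        "xref: UMLS:C0000001\n"
    )
    ont = parse_obo(_write_obo(tmp_path, text))
    assert ont.is_a == [("MONDO:0000002", "MONDO:0000001")]
    assert ("MONDO:0000002", "UMLS", "C0000001") in ont.xrefs


def test_parse_obo_obsolete_terms_have_no_is_a(tmp_path):
    text = (
        "\n[Term]\nid: A:1\nname: root\n"
        "\n[Term]\nid: A:2\nname: old\nis_a: A:1\nis_obsolete: true\n"
    )
    ont = parse_obo(_write_obo(tmp_path, text))
    assert ont.terms["A:2"]["is_obsolete"]
    assert all(child != "A:2" for child, _ in ont.is_a)
    assert "A:2" not in ont.active_terms


def test_parse_obo_unknown_keys_ignored(tmp_path):
    text = "\n[Term]\nid: A:1\nname: x\ncomment: free text\ncreated_by: nobody\n"
    ont = parse_obo(_write_obo(tmp_path, text))
    assert "A:1" in ont.terms


def test_parse_obo_missing_id_raises_with_line_number(tmp_path):
    text = "\n[Term]\nname: orphan stanza\n"
    # header occupies lines 1-2, blank line 3, the bad stanza opens line 4
    with pytest.raises(OboParseError, match=r"line 4"):
        parse_obo(_write_obo(tmp_path, text))


def test_parse_obo_fixture_counts(fixture_bundle):
    ont = parse_obo(fixture_bundle.paths["disease_obo"], "MONDO")
    truth = fixture_bundle.truth
    # active terms = planted disease names (the obsolete term is excluded)
    assert set(ont.active_terms) == set(truth.disease_names)
    # every active non-root term hangs off the root
    assert len(ont.is_a) == len(truth.disease_names) - 1


# ---------------------------------------------------------------------------
# Expression-call filter
# ---------------------------------------------------------------------------


def _expr_row(quality="gold quality", fdr=0.005, rank=10_000, call="present"):
    return {
        "anatomy_id": "UBERON:0000001",
        "gene_id": "1001",
        "call": call,
        "quality": quality,
        "fdr": fdr,
        "rank": rank,
    }


@pytest.mark.parametrize(
    "row,kept",
    [
        (_expr_row(), True),                                  # all thresholds satisfied
        (_expr_row(fdr=0.01), True),                          # FDR bound is inclusive
        (_expr_row(rank=25_000), False),                      # strict "<" on rank
        (_expr_row(rank=24_999), True),
        (_expr_row(quality="silver quality"), False),
        (_expr_row(fdr=0.011), False),
        (_expr_row(call="absent"), True),                     # absent calls kept too
    ],
)
def test_expression_thresholds(row, kept):
    table, log = filter_expression_calls(pd.DataFrame([row]))
    assert (len(table) == 1) is kept
    assert len(table) + log.n_dropped == 1


def test_expression_relation_follows_call_column():
    table, _ = filter_expression_calls(
        pd.DataFrame([_expr_row(call="present"), _expr_row(call="absent")])
    )
    assert sorted(table.df["relation"]) == [
        "anatomy_protein_absent",
        "anatomy_protein_present",
    ]


def test_expression_non_numeric_dropped_and_logged():
    table, log = filter_expression_calls(pd.DataFrame([_expr_row(rank="NA")]))
    assert len(table) == 0
    assert log.n_dropped == 1
    assert "non-numeric" in log.to_frame().iloc[0]["reason"]


def test_expression_threshold_monotonicity(fixture_bundle):
    expr = pd.read_csv(
        fixture_bundle.paths["expression_calls"], sep="\t", dtype=str, keep_default_na=False
    )
    base, _ = filter_expression_calls(expr, IngestConfig())
    relaxed, _ = filter_expression_calls(
        expr, IngestConfig(bgee_fdr_max=0.05, bgee_rank_max=100_000)
    )
    assert len(relaxed) >= len(base)


# ---------------------------------------------------------------------------
# Disorder-concept selection
# ---------------------------------------------------------------------------


def test_umls_disorder_selection():
    conso = pd.DataFrame(
        [
            {"cui": "C1", "lat": "ENG", "name": "mock disease"},
            {"cui": "C2", "lat": "ENG", "name": "mock finding"},
            {"cui": "C3", "lat": "FRE", "name": "maladie"},
        ]
    )
    sty = pd.DataFrame(
        [
            {"cui": "C1", "sty": "Disease or Syndrome"},
            {"cui": "C2", "sty": "Finding"},
            {"cui": "C3", "sty": "Disease or Syndrome"},
        ]
    )
    mrdef = pd.DataFrame(
        [
            {"cui": "C1", "sab": "MSH", "definition": "a mock disease"},
            {"cui": "C2", "sab": "MSH", "definition": "a mock finding"},
        ]
    )
    out, log = select_umls_disorders(conso, sty, mrdef)
    assert list(out["cui"]) == ["C1"]  # Finding excluded, non-English atom logged
    assert log.n_dropped >= 1


def test_umls_fixture_count(fixture_bundle):
    p = fixture_bundle.paths
    conso = ingest.read_rrf(p["mrconso"], ["cui", "lat", "name"])
    sty = ingest.read_rrf(p["mrsty"], ["cui", "sty"])
    mrdef = ingest.read_rrf(p["mrdef"], ["cui", "sab", "definition"])
    out, _ = select_umls_disorders(conso, sty, mrdef)
    assert len(out) == fixture_bundle.truth.adapter_counts["umls_disorder_definitions"]


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------


def _toy_table(ids):
    return TriplesTable(
        pd.DataFrame(
            [
                {
                    "relation": "drug_protein",
                    "x_id": "DB00001",
                    "x_type": "drug",
                    "x_source": "DrugBank",
                    "y_id": i,
                    "y_type": "gene/protein",
                    "y_source": "UniProt",
                }
                for i in ids
            ]
        ),
        resource_tag="toy",
    )


def test_map_identifiers_direct_and_unmapped_and_expansion():
    vocab = XrefMap.from_pairs(
        "UniProt", "NCBI", [("P1", "101"), ("P2", "201"), ("P2", "202")]
    )
    table, log = map_identifiers(_toy_table(["P1", "P2", "P9"]), vocab, side="y")
    # P1 -> one row, P2 -> two rows, P9 dropped
    assert sorted(table.df["y_id"]) == ["101", "201", "202"]
    assert (table.df["y_source"] == "NCBI").all()
    assert log.n_dropped == 1
    assert log.to_frame().query("action == 'drop'").iloc[0]["reason"] == "unmapped"
    assert log.n_expansions == 1
    # conservation: |in| = |out before expansion| + |drops|
    assert 3 == (len(table) - log.n_expansions) + log.n_dropped


def test_map_identifiers_drop_policy_discards_ambiguous():
    vocab = XrefMap.from_pairs("UniProt", "NCBI", [("P2", "201"), ("P2", "202")])
    table, log = map_identifiers(_toy_table(["P2"]), vocab, side="y", policy="drop")
    assert len(table) == 0
    assert log.n_dropped == 1


def test_map_identifiers_wrong_namespace_is_contract_error():
    vocab = XrefMap.from_pairs("CAS", "DrugBank", [("50-00-0", "DB1")])
    with pytest.raises(ValueError, match="namespace"):
        map_identifiers(_toy_table(["P1"]), vocab, side="y")


# ---------------------------------------------------------------------------
# Drug knowledgebase
# ---------------------------------------------------------------------------


def _partner_table(pairs, tag):
    return TriplesTable(
        pd.DataFrame(
            [
                {
                    "relation": "drug_protein",
                    "x_id": d,
                    "x_type": "drug",
                    "x_source": "DrugBank",
                    "y_id": u,
                    "y_type": "gene/protein",
                    "y_source": "UniProt",
                }
                for d, u in pairs
            ]
        ),
        resource_tag=tag,
    )


def test_merge_partners_disjoint_union():
    merged = merge_drug_protein_partners(
        _partner_table([("D1", "P1"), ("D1", "P2")], "targets"),
        _partner_table([("D2", "P1"), ("D2", "P2"), ("D2", "P3")], "enzymes"),
        _partner_table([], "carriers"),
        _partner_table([("D3", "P1")], "transporters"),
    )
    assert len(merged) == 6


def test_merge_partners_dedups_same_pair():
    merged = merge_drug_protein_partners(
        _partner_table([("D1", "P1")], "targets"),
        _partner_table([("D1", "P1")], "enzymes"),
    )
    assert len(merged) == 1


def test_merge_partners_fixture_count(fixture_bundle):
    p = fixture_bundle.paths
    partners = [
        ingest.read_partner_table(p[f"partners_{tag}"], tag)
        for tag in ["targets", "enzymes", "carriers", "transporters"]
    ]
    merged = merge_drug_protein_partners(*partners)
    assert len(merged) == fixture_bundle.truth.adapter_counts["drug_protein_pairs"]


def _interaction_xml(tmp_path, body):
    p = tmp_path / "drugs.xml"
    p.write_text(f"<drugbank>{body}</drugbank>", encoding="utf-8")
    return p


def _drug_entry(acc, partners):
    inner = "".join(
        f"<drug-interaction><drugbank-id>{o}</drugbank-id></drug-interaction>"
        for o in partners
    )
    return (
        f"<drug><drugbank-id>{acc}</drugbank-id><name>{acc}</name>"
        f"<drug-interactions>{inner}</drug-interactions></drug>"
    )


def test_interactions_single_listing(tmp_path):
    table = parse_drug_interactions(
        _interaction_xml(tmp_path, _drug_entry("DB1", ["DB2"]) + _drug_entry("DB2", []))
    )
    assert len(table) == 1


def test_interactions_mirrored_listing_deduplicated(tmp_path):
    table = parse_drug_interactions(
        _interaction_xml(tmp_path, _drug_entry("DB1", ["DB2"]) + _drug_entry("DB2", ["DB1"]))
    )
    assert len(table) == 1


def test_interactions_malformed_xml(tmp_path):
    p = tmp_path / "bad.xml"
    p.write_text("<drugbank><drug>", encoding="utf-8")
    with pytest.raises(ValueError, match="malformed"):
        parse_drug_interactions(p)


def test_interactions_fixture_count(fixture_bundle):
    table = parse_drug_interactions(fixture_bundle.paths["drug_xml"])
    assert len(table) == fixture_bundle.truth.adapter_counts["drug_interactions"]


# ---------------------------------------------------------------------------
# Side effects
# ---------------------------------------------------------------------------


def _se_maps():
    m1 = XrefMap.from_pairs("STITCH", "ATC", [("CID1", "A01")])
    m2 = XrefMap.from_pairs("ATC", "DrugBank", [("A01", "DB1")])
    return m1, m2


def test_side_effects_preferred_term_kept():
    rows = pd.DataFrame(
        [{"drug_stitch_id": "CID1", "meddra_level": "PT", "phenotype_id": "HP:1",
          "phenotype_name": "mock"}]
    )
    table, log = filter_side_effects(rows, *_se_maps())
    assert len(table) == 1
    assert table.df.iloc[0]["x_id"] == "DB1"
    assert table.df.iloc[0]["relation"] == "drug_effect"


@pytest.mark.parametrize(
    "row,reason",
    [
        ({"drug_stitch_id": "CID1", "meddra_level": "LLT", "phenotype_id": "HP:1"},
         "not preferred term"),
        ({"drug_stitch_id": "CID9", "meddra_level": "PT", "phenotype_id": "HP:1"},
         "broken mapping chain"),
    ],
)
def test_side_effects_drops_logged(row, reason):
    table, log = filter_side_effects(pd.DataFrame([row]), *_se_maps())
    assert len(table) == 0
    assert log.to_frame().iloc[0]["reason"] == reason


def test_side_effects_fixture_count(fixture_bundle):
    p = fixture_bundle.paths
    se = pd.read_csv(p["side_effects"], sep="\t", dtype=str, keep_default_na=False)
    stitch_atc = pd.read_csv(p["stitch_atc"], sep="\t", dtype=str, keep_default_na=False)
    atc_db = pd.read_csv(p["atc_drug"], dtype=str, keep_default_na=False)
    m1 = XrefMap.from_pairs("STITCH", "ATC", zip(stitch_atc["stitch_id"], stitch_atc["atc"]))
    m2 = XrefMap.from_pairs("ATC", "DrugBank", zip(atc_db["atc"], atc_db["drug_id"]))
    table, log = filter_side_effects(se, m1, m2)
    assert len(table) == fixture_bundle.truth.adapter_counts["side_effect_survivors"]
    assert len(se) == (len(table) - log.n_expansions) + log.n_dropped


# ---------------------------------------------------------------------------
# Determinism of adapters
# ---------------------------------------------------------------------------


def test_adapters_are_pure_functions(fixture_bundle):
    expr = pd.read_csv(
        fixture_bundle.paths["expression_calls"], sep="\t", dtype=str, keep_default_na=False
    )
    a, _ = filter_expression_calls(expr)
    b, _ = filter_expression_calls(expr)
    pd.testing.assert_frame_equal(a.canonical(), b.canonical())

    ppi_paths = json.loads(fixture_bundle.paths["ppi"])
    pd.testing.assert_frame_equal(
        ingest.read_ppi(ppi_paths).canonical(), ingest.read_ppi(ppi_paths).canonical()
    )
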