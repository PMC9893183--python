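"""End-to-end build: manifest in, knowledge graph and audit artifacts out.

Order of operations: parse ontologies -> run resource adapters -> map
identifiers into the node-type ontologies -> resolve phenotype/disease
overlap -> group disease entities -> merge, clean, extract the largest
connected component -> assign node indices. Both the pre-component graph
(``kg_raw``) and the giant component (``kg_giant``) are exportable, along
with an assembly report, drop logs, the rewire log and the grouping
proposal table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ingest
from .assembly import (
    AssemblyReport,
    assign_node_indices,
    clean_edges,
    largest_connected_component,
    merge_tables,
)
from .features import (
    FeatureAttachment,
    attach_features,
    clean_reference_tokens,
    match_disease_names,
    normalize_half_life,
    numeric_to_text,
    split_when_to_see_doctor,
)
from .grouping import DiseaseGrouping, GroupingConfig, apply_grouping, group_diseases
from .ingest import IngestConfig
from .overlap import OverlapSet, RewireLog, compute_overlap_set, rewire_edges
from .schema import KnowledgeGraph, write_kg
from .tables import DropLog, TriplesTable, XrefMap

__all__ = ["BuildResult", "build_kg", "build_clinical_features"]


@dataclass
class BuildResult:
    kg_raw: KnowledgeGraph
    kg_giant: KnowledgeGraph
    report: AssemblyReport
    overlap: OverlapSet
    rewire_log: RewireLog
    grouping: DiseaseGrouping
    proposals: pd.DataFrame
    drop_logs: dict[str, DropLog] = field(default_factory=dict)
    tables: list[TriplesTable] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_kg(self.kg_raw, outdir / "kg_raw.csv", validate=False)
        write_kg(
            self.kg_giant,
            outdir / "kg_giant.csv",
            nodes_destination=outdir / "kg_giant_nodes.csv",
        )
        self.report.to_json(outdir / "assembly_report.json")
        self.rewire_log.to_frame().to_csv(outdir / "rewire_log.csv", index=False)
        self.proposals.to_csv(outdir / "grouping_proposals.csv", index=False)
        drops = [
            log.to_frame().assign(adapter=tag)
            for tag, log in self.drop_logs.items()
            if len(log)
        ]
        if drops:
            pd.concat(drops, ignore_index=True).to_csv(outdir / "drop_log.csv", index=False)


def _load_manifest(manifest: str | Path | dict) -> dict:
    if isinstance(manifest, (str, Path)):
        data = json.loads(Path(manifest).read_text(encoding="utf-8"))
    else:
        data = manifest
    if "paths" not in data:
        raise ValueError("manifest must carry a 'paths' mapping")
    return data


def _apply_names(tables: list[TriplesTable], registry: dict[tuple[str, str], str]) -> list[TriplesTable]:
    out = []
    for t in tables:
        df = t.df.copy()
        for side in ("x", "y"):
            keys = list(zip(df[f"{side}_source"], df[f"{side}_id"]))
            df[f"{side}_name"] = [
                registry.get(k, n) for k, n in zip(keys, df[f"{side}_name"])
            ]
        out.append(TriplesTable(df, resource_tag=t.resource_tag))
    return out


def build_kg(
    manifest: str | Path | dict,
    ingest_cfg: IngestConfig | None = None,
    grouping_cfg: GroupingConfig | None = None,
    review: pd.DataFrame | None = None,
) -> BuildResult:
    """Run the full construction pipeline from a build manifest.

    The manifest maps resource roles to file paths (the layout written by
    the fixture generator; real resource snapshots use the same roles).
    """
    ingest_cfg = ingest_cfg or IngestConfig()
    grouping_cfg = grouping_cfg or GroupingConfig()
    m = _load_manifest(manifest)
    p = m["paths"]
    drop_logs: dict[str, DropLog] = {}

    # --- ontologies --------------------------------------------------------
    disease_ont = ingest.parse_obo(p["disease_obo"], "MONDO")
    pheno_ont = ingest.parse_obo(p["phenotype_obo"], "HPO")
    anatomy_ont = ingest.parse_obo(p["anatomy_obo"], "UBERON")
    go_onts = {
        "bp": ingest.parse_obo(p["go_bp_obo"], "GO"),
        "mf": ingest.parse_obo(p["go_mf_obo"], "GO"),
        "cc": ingest.parse_obo(p["go_cc_obo"], "GO"),
    }

    tables: list[TriplesTable] = [
        ingest.hierarchy_table(disease_ont, "disease_disease", "disease", "disease_hierarchy"),
        ingest.hierarchy_table(pheno_ont, "phenotype_phenotype", "effect/phenotype", "phenotype_hierarchy"),
        ingest.hierarchy_table(anatomy_ont, "anatomy_anatomy", "anatomy", "anatomy_hierarchy"),
        ingest.hierarchy_table(go_onts["bp"], "bioprocess_bioprocess", "biological_process", "go_bp_hierarchy"),
        ingest.hierarchy_table(go_onts["mf"], "molfunc_molfunc", "molecular_function", "go_mf_hierarchy"),
        ingest.hierarchy_table(go_onts["cc"], "cellcomp_cellcomp", "cellular_component", "go_cc_hierarchy"),
    ]

    # --- vocabularies ------------------------------------------------------
    gene_vocab = pd.read_csv(p["gene_vocab"], dtype=str, keep_default_na=False)
    uniprot_to_ncbi = XrefMap.from_pairs(
        "UniProt", "NCBI", zip(gene_vocab["uniprot_id"], gene_vocab["ncbi_id"]),
        dst_names=dict(zip(gene_vocab["ncbi_id"], gene_vocab["symbol"])),
    )
    drug_vocab = pd.read_csv(p["drug_vocab"], dtype=str, keep_default_na=False)
    cas_to_db = XrefMap.from_pairs(
        "CAS", "DrugBank", zip(drug_vocab["cas"], drug_vocab["drug_id"]),
        dst_names=dict(zip(drug_vocab["drug_id"], drug_vocab["name"])),
    )
    stitch_atc = pd.read_csv(p["stitch_atc"], sep="\t", dtype=str, keep_default_na=False)
    atc_db = pd.read_csv(p["atc_drug"], dtype=str, keep_default_na=False)
    stitch_to_atc = XrefMap.from_pairs("STITCH", "ATC", zip(stitch_atc["stitch_id"], stitch_atc["atc"]))
    atc_to_db = XrefMap.from_pairs(
        "ATC", "DrugBank", zip(atc_db["atc"], atc_db["drug_id"]),
        dst_names=dict(zip(drug_vocab["drug_id"], drug_vocab["name"])),
    )
    cui_to_mondo = disease_ont.xref_map("UMLS", "MONDO")
    cui_to_hp = pheno_ont.xref_map("UMLS", "HPO")

    # --- resource adapters ---------------------------------------------------
    expr = pd.read_csv(p["expression_calls"], sep="\t", dtype=str, keep_default_na=False)
    expr_table, drop_logs["expression"] = ingest.filter_expression_calls(expr, ingest_cfg)
    tables.append(expr_table)

    gd_disease, gd_pheno = ingest.read_gene_disease(p["gene_disease"])
    gd_disease, drop_logs["gene_disease_map"] = ingest.map_identifiers(
        gd_disease, cui_to_mondo, side="x"
    )
    gd_pheno, drop_logs["gene_phenotype_map"] = ingest.map_identifiers(
        gd_pheno, cui_to_hp, side="x"
    )
    tables += [gd_disease, gd_pheno]

    labels = ingest.read_drug_disease_labels(p["drug_disease_labels"])
    labels, drop_logs["drug_label_map"] = ingest.map_identifiers(labels, cas_to_db, side="x")
    tables.append(labels)

    tables.append(ingest.read_ppi(json.loads(p["ppi"])))
    tables.append(ingest.parse_drug_interactions(p["drug_xml"]))

    partners = [
        ingest.read_partner_table(p[f"partners_{tag}"], tag)
        for tag in ["targets", "enzymes", "carriers", "transporters"]
    ]
    merged_partners = ingest.merge_drug_protein_partners(*partners)
    merged_partners, drop_logs["partner_map"] = ingest.map_identifiers(
        merged_partners, uniprot_to_ncbi, side="y"
    )
    tables.append(merged_partners)

    se = pd.read_csv(p["side_effects"], sep="\t", dtype=str, keep_default_na=False)
    se_table, drop_logs["side_effects"] = ingest.filter_side_effects(
        se, stitch_to_atc, atc_to_db, ingest_cfg
    )
    tables.append(se_table)

    tables.append(ingest.read_exposure_links(
        p["exposures"],
        target_sources={
            "exposure": "CTD",
            "gene/protein": "NCBI",
            "disease": "MONDO",
            "biological_process": "GO",
            "molecular_function": "GO",
            "cellular_component": "GO",
        },
    ))
    tables.append(ingest.read_gene_go(p["gene_go"]))
    pw_pp, pw_pg = ingest.read_reactome(
        p["pathways"], p["pathway_relations"], p["gene_pathways"]
    )
    tables += [pw_pp, pw_pg]
    tables.append(ingest.read_disease_phenotype_annotations(p["disease_phenotypes"]))

    # --- display names -------------------------------------------------------
    registry: dict[tuple[str, str], str] = {}
    for ont, src in [
        (disease_ont, "MONDO"),
        (pheno_ont, "HPO"),
        (anatomy_ont, "UBERON"),
        (go_onts["bp"], "GO"),
        (go_onts["mf"], "GO"),
        (go_onts["cc"], "GO"),
    ]:
        registry.update({(src, t): n for t, n in ont.names().items()})
    registry.update({("NCBI", g): s for g, s in zip(gene_vocab["ncbi_id"], gene_vocab["symbol"])})
    registry.update({("DrugBank", d): n for d, n in zip(drug_vocab["drug_id"], drug_vocab["name"])})
    tables = _apply_names(tables, registry)

    # --- overlap resolution ----------------------------------------------------
    overlap = compute_overlap_set(pheno_ont, disease_ont)
    tables, rewire_log = rewire_edges(
        tables, overlap, disease_names=disease_ont.names()
    )

    # --- disease grouping --------------------------------------------------------
    grouping, proposals = group_diseases(disease_ont.names(), grouping_cfg, review=review)
    tables, drop_logs["grouping"] = apply_grouping(tables, grouping)

    # --- assembly -------------------------------------------------------------------
    merged = merge_tables(tables)
    cleaned, report = clean_edges(merged)
    provenance = {"manifest_paths": sorted(p), "n_resources": len(tables)}
    kg_raw = assign_node_indices(cleaned, provenance={**provenance, "stage": "raw"})
    giant_table, lcc_report = largest_connected_component(cleaned)
    report.lcc = lcc_report.lcc
    kg_giant = assign_node_indices(giant_table, provenance={**provenance, "stage": "giant"})

    return BuildResult(
        kg_raw=kg_raw,
        kg_giant=kg_giant,
        report=report,
        overlap=overlap,
        rewire_log=rewire_log,
        grouping=grouping,
        proposals=proposals,
        drop_logs=drop_logs,
        tables=tables,
    )


def build_clinical_features(
    manifest: str | Path | dict,
    kg: KnowledgeGraph,
    grouping: DiseaseGrouping,
) -> FeatureAttachment:
    """Attach drug and disease clinical text features to graph nodes.

    Drug features come from the drug XML (text fields cleaned of citation
    tokens, half-life nullified when it states no data) and the numeric
    descriptor table (rendered to sentences). Disease features aggregate
    ontology definitions, metathesaurus descriptions, rare-disease fields
    and scraped-overview fields (symptoms split at the 'When to see a
    doctor' heading), each mapped to the grouped disease node.
    """
    m = _load_manifest(manifest)
    p = m["paths"]
    ingest_cfg = IngestConfig()

    # drug features -----------------------------------------------------------
    feats = ingest.parse_drug_features(p["drug_xml"])
    for col in ["description", "indication", "mechanism_of_action", "pharmacodynamics"]:
        feats[col] = feats[col].map(clean_reference_tokens)
    feats["half_life"] = feats["half_life"].map(normalize_half_life)

    drug_vocab = pd.read_csv(p["drug_vocab"], dtype=str, keep_default_na=False)
    cas_to_db = dict(zip(drug_vocab["cas"], drug_vocab["drug_id"]))
    structures = pd.read_csv(p["drug_structures"], dtype=str, keep_default_na=False)
    structures["drug_id"] = structures["cas"].map(cas_to_db)
    structures = structures.dropna(subset=["drug_id"])
    name_of = dict(zip(feats["drug_id"], feats["name"]))
    for descriptor in ["molecular_weight", "tpsa", "clogp"]:
        rendered = {
            row["drug_id"]: numeric_to_text(
                name_of.get(row["drug_id"], row["drug_id"]),
                descriptor,
                float(row[descriptor]),
            )
            for _, row in structures.iterrows()
        }
        feats[descriptor] = feats["drug_id"].map(rendered).fillna("")

    # disease features ----------------------------------------------------------
    disease_ont = ingest.parse_obo(p["disease_obo"], "MONDO")
    records: list[dict] = []
    for term, data in disease_ont.active_terms.items():
        if data["definition"]:
            records.append(
                {"disease_id": term, "source": "MONDO", "feature": "mondo_definition",
                 "value": data["definition"]}
            )

    conso = ingest.read_rrf(p["mrconso"], ["cui", "lat", "name"])
    sty = ingest.read_rrf(p["mrsty"], ["cui", "sty"])
    mrdef = ingest.read_rrf(p["mrdef"], ["cui", "sab", "definition"])
    umls_defs, _ = ingest.select_umls_disorders(conso, sty, mrdef, ingest_cfg)
    cui_to_mondo = disease_ont.xref_map("UMLS", "MONDO")
    for _, row in umls_defs.iterrows():
        for mondo in cui_to_mondo.lookup(row["cui"]):
            records.append(
                {"disease_id": mondo, "source": "UMLS", "feature": "umls_description",
                 "value": clean_reference_tokens(row["definition"])}
            )

    orpha_to_mondo = disease_ont.xref_map("ORPHA", "MONDO")
    orpha = pd.read_csv(p["rare_disease_features"], dtype=str, keep_default_na=False)
    for _, row in orpha.iterrows():
        for mondo in orpha_to_mondo.lookup(row["orpha_id"]):
            for feature in ["definition", "prevalence", "epidemiology",
                            "clinical_description", "management_and_treatment"]:
                if row[feature]:
                    records.append(
                        {"disease_id": mondo, "source": "Orphanet",
                         "feature": f"orphanet_{feature}", "value": row[feature]}
                    )

    overviews = pd.read_csv(p["clinical_overviews"], dtype=str, keep_default_na=False)
    mapping, _, _ = match_disease_names(
        dict(zip(overviews["disease_name"], overviews["disease_name"])),
        disease_ont.names(),
    )
    for _, row in overviews.iterrows():
        mondo = mapping.get(row["disease_name"])
        if mondo is None:
            continue
        symptoms, wtsd = split_when_to_see_doctor(row["symptoms"])
        fields = {
            "symptoms": symptoms,
            "when_to_see_doctor": wtsd,
            "causes": row["causes"],
            "risk_factors": row["risk_factors"],
            "complications": row["complications"],
            "prevention": row["prevention"],
        }
        for feature, value in fields.items():
            if value:
                records.append(
                    {"disease_id": mondo, "source": "overview",
                     "feature": f"mayo_{feature}", "value": value}
                )

    return attach_features(
        kg,
        drug_records=feats,
        disease_records=pd.DataFrame(records),
        grouping=grouping,
    )
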