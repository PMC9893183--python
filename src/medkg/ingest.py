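"""Resource adapters: parse standard source formats, apply per-resource
filters, and emit :class:`~medkg.tables.TriplesTable` records in
source-ontology identifier space.

Every adapter is a pure function of (rows, config) and obeys a conservation
contract: |input rows| = |output rows before expansion| + |logged drops|.

Adapter inventory
-----------------
* OBO ontologies (disease, phenotype, anatomy, gene-function vocabularies)
  -> term tables, is_a hierarchies, cross-references.
* Expression calls (anatomy x gene presence/absence with quality, FDR and
  expression rank) -> anatomy-protein edges under the gold-quality,
  FDR <= 0.01, rank < 25,000 filter.
* RRF-style concept/semantic-type/definition tables -> disorder-concept
  definitions restricted to 11 Disorder-group semantic types.
* Drug knowledgebase XML -> synergistic drug-drug interactions and the 12
  clinical text/numeric feature fields.
* Drug-protein partner exports (targets, enzymes, carriers, transporters)
  -> unioned drug-protein edges.
* Side-effect tables -> drug-phenotype edges at the MedDRA preferred-term
  coding level, drug identifiers mapped through a two-step chain.
* Thin tabular adapters for gene-disease associations, drug-disease labels
  (indication / contraindication / off-label use), PPI union, exposure
  links, gene-GO annotations, and pathway tables.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import obonet
import pandas as pd
from lxml import etree
from pydantic import BaseModel, Field, field_validator

from .tables import DropLog, TriplesTable, XrefMap

__all__ = [
    "UMLS_DISORDER_TYPES",
    "IngestConfig",
    "OntologyGraph",
    "OboParseError",
    "parse_obo",
    "hierarchy_table",
    "filter_expression_calls",
    "select_umls_disorders",
    "map_identifiers",
    "merge_drug_protein_partners",
    "parse_drug_interactions",
    "parse_drug_features",
    "filter_side_effects",
    "read_gene_disease",
    "read_drug_disease_labels",
    "read_ppi",
    "read_exposure_links",
    "read_gene_go",
    "read_reactome",
    "read_disease_phenotype_annotations",
]

#: The 11 semantic types of the Disorder semantic group retained when
#: selecting disease concepts from the metathesaurus.
UMLS_DISORDER_TYPES: frozenset[str] = frozenset(
    {
        "Congenital Abnormality",
        "Acquired Abnormality",
        "Injury or Poisoning",
        "Pathologic Function",
        "Disease or Syndrome",
        "Mental or Behavioral Dysfunction",
        "Cell or Molecular Dysfunction",
        "Experimental Model of Disease",
        "Signs and Symptoms",
        "Anatomical Abnormality",
        "Neoplastic Process",
    }
)


class IngestConfig(BaseModel):
    """Thresholds and selections applied by the adapters.

    bgee_fdr_max
        Largest FDR-corrected p-value retained for an expression call
        (inclusive bound).
    bgee_rank_max
        Expression-rank cutoff; calls are retained with rank strictly
        below this value (highly expressed genes).
    bgee_quality
        Call-quality label retained.
    bgee_filter_absent_rank
        Whether the rank cutoff also applies to 'absent' calls; the rank of
        an absent call is not an expression level, so this is configurable.
    umls_semantic_types
        Semantic types whose concepts count as disorders.
    umls_language
        Language code of retained concept atoms.
    umls_english_sources
        Definition sources treated as English-language.
    """

    bgee_fdr_max: float = 0.01
    bgee_rank_max: int = 25_000
    bgee_quality: str = "gold quality"
    bgee_filter_absent_rank: bool = True
    umls_semantic_types: frozenset[str] = UMLS_DISORDER_TYPES
    umls_language: str = "ENG"
    umls_english_sources: frozenset[str] = frozenset({"MSH", "NCI", "MONDO", "HPO", "ORPHANET"})
    sider_preferred_level: str = "PT"

    @field_validator("bgee_fdr_max")
    @classmethod
    def _fdr_in_unit_interval(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("bgee_fdr_max must be in (0, 1)")
        return v

    @field_validator("bgee_rank_max")
    @classmethod
    def _rank_positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("bgee_rank_max must be positive")
        return v


# ---------------------------------------------------------------------------
# Ontology parsing
# ---------------------------------------------------------------------------


class OboParseError(ValueError):
    pass


@dataclass
class OntologyGraph:
    """Parsed OBO ontology: terms, is_a hierarchy, cross-references.

    Obsolete terms are kept in ``terms`` (flagged) but carry no outgoing
    is_a edges.
    """

    terms: dict[str, dict] = field(default_factory=dict)
    is_a: list[tuple[str, str]] = field(default_factory=list)
    xrefs: list[tuple[str, str, str]] = field(default_factory=list)
    subsets: dict[str, list[str]] = field(default_factory=dict)
    source: str = ""

    @property
    def active_terms(self) -> dict[str, dict]:
        return {t: d for t, d in self.terms.items() if not d["is_obsolete"]}

    def names(self) -> dict[str, str]:
        return {t: d["name"] for t, d in self.active_terms.items()}

    def xref_map(self, namespace: str, dst_ns: str | None = None) -> XrefMap:
        """Foreign-namespace identifier -> term identifier map.

        Keys are the bare foreign identifiers (without the namespace
        prefix), matching how resources in that namespace print them.
        """
        pairs = [(fid, term) for term, ns, fid in self.xrefs if ns == namespace]
        return XrefMap.from_pairs(namespace, dst_ns or self.source, pairs,
                                  dst_names=self.names())


_DEF_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _clean_def(raw: str) -> str:
    m = _DEF_RE.search(raw)
    return m.group(1).replace('\\"', '"') if m else raw.strip()


def _prescan_obo(text: str) -> None:
    """Raise a line-numbered error for any [Term] stanza without an id."""
    stanza_line = None
    has_id = True
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("["):
            if stanza_line is not None and not has_id:
                raise OboParseError(
                    f"malformed [Term] stanza starting at line {stanza_line}: no id"
                )
            stanza_line = lineno if stripped == "[Term]" else None
            has_id = False
        elif stanza_line is not None and stripped.startswith("id:"):
            has_id = True
    if stanza_line is not None and not has_id:
        raise OboParseError(
            f"malformed [Term] stanza starting at line {stanza_line}: no id"
        )


def parse_obo(source: str | Path, ontology_tag: str = "") -> OntologyGraph:
    """Parse an OBO 1.2/1.4 ontology file.

    Extracts terms (id, name, definition, obsolete flag), is_a edges,
    xrefs and subsets; stanza keys outside that set are ignored.
    """
    text = Path(source).read_text(encoding="utf-8")
    _prescan_obo(text)
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    ont = OntologyGraph(source=ontology_tag or Path(source).stem)
    for term, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        ont.terms[term] = {
            "name": data.get("name", term),
            "definition": _clean_def(data.get("def", "")),
            "is_obsolete": obsolete,
        }
        for raw in data.get("xref", []):
            token = raw.split(" ")[0].strip()
            if ":" in token:
                ns, fid = token.split(":", 1)
                ont.xrefs.append((term, ns, fid))
        for sub in data.get("subset", []):
            ont.subsets.setdefault(sub, []).append(term)
        if not obsolete:
            for parent in data.get("is_a", []):
                ont.is_a.append((term, parent))
    known = set(ont.terms)
    ont.is_a = [(c, p) for c, p in ont.is_a if c in known and p in known]
    return ont


def hierarchy_table(
    ont: OntologyGraph, relation: str, node_type: str, resource_tag: str
) -> TriplesTable:
    """is_a (child, parent) edges of an ontology as a TriplesTable."""
    names = ont.names()
    rows = [
        {
            "relation": relation,
            "x_id": child,
            "x_type": node_type,
            "x_source": ont.source,
            "x_name": names.get(child, child),
            "y_id": parent,
            "y_type": node_type,
            "y_source": ont.source,
            "y_name": names.get(parent, parent),
        }
        for child, parent in ont.is_a
    ]
    return TriplesTable(pd.DataFrame(rows), resource_tag=resource_tag)


# ---------------------------------------------------------------------------
# Expression calls
# ---------------------------------------------------------------------------


def filter_expression_calls(
    table: pd.DataFrame, cfg: IngestConfig | None = None,
    anatomy_source: str = "UBERON", gene_source: str = "NCBI",
) -> tuple[TriplesTable, DropLog]:
    """Filter anatomy x gene expression calls to confident, highly expressed
    entries.

    Keeps rows with the configured quality, FDR <= bgee_fdr_max and
    expression rank strictly below bgee_rank_max, and emits
    anatomy_protein_present / anatomy_protein_absent edges per the call
    column. Rows with non-numeric fdr/rank are dropped and logged.
    """
    cfg = cfg or IngestConfig()
    log = DropLog()
    rows = []
    for pos, row in table.iterrows():
        fdr = pd.to_numeric(pd.Series([row["fdr"]]), errors="coerce").iloc[0]
        rank = pd.to_numeric(pd.Series([row["rank"]]), errors="coerce").iloc[0]
        if pd.isna(fdr) or pd.isna(rank):
            log.drop("non-numeric fdr/rank", row=int(pos))
            continue
        if row["quality"] != cfg.bgee_quality:
            log.drop("quality", row=int(pos))
            continue
        if fdr > cfg.bgee_fdr_max:
            log.drop("fdr", row=int(pos))
            continue
        apply_rank = cfg.bgee_filter_absent_rank or row["call"] == "present"
        if apply_rank and not rank < cfg.bgee_rank_max:
            log.drop("rank", row=int(pos))
            continue
        call = str(row["call"]).strip().lower()
        if call not in ("present", "absent"):
            log.drop("unknown call", row=int(pos))
            continue
        rows.append(
            {
                "relation": f"anatomy_protein_{call}",
                "x_id": row["anatomy_id"],
                "x_type": "anatomy",
                "x_source": anatomy_source,
                "y_id": str(row["gene_id"]),
                "y_type": "gene/protein",
                "y_source": gene_source,
            }
        )
    return TriplesTable(pd.DataFrame(rows), resource_tag="expression_calls"), log


# ---------------------------------------------------------------------------
# Metathesaurus disorder concepts
# ---------------------------------------------------------------------------


def select_umls_disorders(
    concept_rows: pd.DataFrame,
    semtype_rows: pd.DataFrame,
    def_rows: pd.DataFrame,
    cfg: IngestConfig | None = None,
) -> tuple[pd.DataFrame, DropLog]:
    """Select disorder concepts and attach English definitions.

    ``concept_rows``: columns cui, lat, name; ``semtype_rows``: cui, sty;
    ``def_rows``: cui, sab, definition (RRF-style content, pre-split).
    Returns one row per (cui, definition) for CUIs whose semantic type is
    in the Disorder group, restricted to atoms in the configured language.
    """
    cfg = cfg or IngestConfig()
    log = DropLog()
    eng = concept_rows[concept_rows["lat"] == cfg.umls_language]
    n_non_eng = len(concept_rows) - len(eng)
    if n_non_eng:
        log.drop("non-English atom", count=n_non_eng)
    disorder_cuis = set(
        semtype_rows.loc[semtype_rows["sty"].isin(cfg.umls_semantic_types), "cui"]
    )
    kept = eng[eng["cui"].isin(disorder_cuis)]
    n_not_disorder = len(eng) - len(kept)
    if n_not_disorder:
        log.drop("semantic type outside Disorder group", count=n_not_disorder)
    defs = def_rows[
        def_rows["sab"].isin(cfg.umls_english_sources) & def_rows["cui"].isin(disorder_cuis)
    ]
    names = kept.drop_duplicates("cui").set_index("cui")["name"]
    out = (
        defs.assign(name=defs["cui"].map(names))[["cui", "name", "definition"]]
        .drop_duplicates()
        .sort_values(["cui", "definition"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out, log


def read_rrf(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    """Read a pipe-delimited RRF-style table (trailing pipe per row)."""
    df = pd.read_csv(path, sep="|", header=None, dtype=str, keep_default_na=False)
    df = df.iloc[:, : len(columns)]
    df.columns = list(columns)
    return df


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------


def map_identifiers(
    table: TriplesTable,
    vocab: XrefMap,
    side: str,
    policy: str = "expand",
    new_source: str | None = None,
) -> tuple[TriplesTable, DropLog]:
    """Replace one column's identifiers using a cross-reference map.

    One-to-many mappings expand to one row per target under the default
    ``expand`` policy (``drop`` discards ambiguous rows); unmapped
    identifiers are dropped and logged with reason "unmapped".
    """
    if side not in ("x", "y"):
        raise ValueError("side must be 'x' or 'y'")
    src_col, name_col, source_col = f"{side}_id", f"{side}_name", f"{side}_source"
    current_ns = set(table.df[source_col].unique())
    if len(table) and current_ns - {vocab.src_ns}:
        raise ValueError(
            f"vocab maps namespace {vocab.src_ns!r} but column {src_col} holds "
            f"{sorted(current_ns)}"
        )
    log = DropLog()
    out_rows = []
    for pos, row in table.df.iterrows():
        targets = vocab.lookup(row[src_col])
        if not targets:
            log.drop("unmapped", identifier=row[src_col], row=int(pos))
            continue
        if len(targets) > 1:
            if policy == "drop":
                log.drop("ambiguous", identifier=row[src_col], row=int(pos))
                continue
            log.expand(len(targets), identifier=row[src_col], row=int(pos))
        for t in targets:
            new = dict(row)
            new[src_col] = t
            new[name_col] = vocab.dst_names.get(t, t)
            new[source_col] = new_source or vocab.dst_ns
            out_rows.append(new)
    return (
        TriplesTable(pd.DataFrame(out_rows), resource_tag=table.resource_tag),
        log,
    )


# ---------------------------------------------------------------------------
# Drug knowledgebase
# ---------------------------------------------------------------------------


def merge_drug_protein_partners(*tables: TriplesTable) -> TriplesTable:
    """Union of drug-protein partner tables (targets, enzymes, carriers,
    transporters) with exact-duplicate pairs removed."""
    frames = [t.df for t in tables if len(t)]
    if not frames:
        return TriplesTable.empty("drug_protein_partners")
    merged = pd.concat(frames, ignore_index=True)
    merged["relation"] = "drug_protein"
    merged = merged.drop_duplicates(
        subset=["x_id", "y_id"], keep="first"
    ).reset_index(drop=True)
    merged["resource"] = "drug_protein_partners"
    return TriplesTable(merged, resource_tag="drug_protein_partners")


def read_partner_table(
    path: str | Path, resource_tag: str, drug_source: str = "DrugBank",
    protein_source: str = "UniProt",
) -> TriplesTable:
    """One partner CSV export: columns drug_id, uniprot_id."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows = pd.DataFrame(
        {
            "relation": "drug_protein",
            "x_id": df["drug_id"],
            "x_type": "drug",
            "x_source": drug_source,
            "y_id": df["uniprot_id"],
            "y_type": "gene/protein",
            "y_source": protein_source,
        }
    )
    return TriplesTable(rows, resource_tag=resource_tag)


def parse_drug_interactions(source: str | Path) -> TriplesTable:
    """Extract synergistic drug-drug interactions from the XML export.

    Mirrored records (A lists B and B lists A) are deduplicated to a single
    undirected pair; symmetry is restored at assembly.
    """
    try:
        tree = etree.parse(str(source))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed drug XML: {exc}") from exc
    pairs: set[tuple[str, str]] = set()
    names: dict[str, str] = {}
    for drug in tree.getroot().findall("drug"):
        accession = drug.findtext("drugbank-id")
        if accession is None:
            continue
        names[accession] = drug.findtext("name", default=accession)
        interactions = drug.find("drug-interactions")
        if interactions is None:
            continue
        for partner in interactions.findall("drug-interaction"):
            other = partner.findtext("drugbank-id")
            if other:
                pairs.add(tuple(sorted((accession, other))))  # type: ignore[arg-type]
    rows = [
        {
            "relation": "drug_drug",
            "x_id": a,
            "x_type": "drug",
            "x_source": "DrugBank",
            "x_name": names.get(a, a),
            "y_id": b,
            "y_type": "drug",
            "y_source": "DrugBank",
            "y_name": names.get(b, b),
        }
        for a, b in sorted(pairs)
    ]
    return TriplesTable(pd.DataFrame(rows), resource_tag="drug_interactions")


DRUG_FEATURE_FIELDS = [
    "group",
    "state",
    "category",
    "description",
    "indication",
    "mechanism_of_action",
    "atc_1",
    "atc_2",
    "atc_3",
    "atc_4",
    "pharmacodynamics",
    "half_life",
    "protein_binding",
    "pathway",
]


def parse_drug_features(source: str | Path) -> pd.DataFrame:
    """Extract the clinical feature fields per drug from the XML export.

    Multi-valued fields (groups, categories, ATC levels, pathways) are
    joined into a single text description with '; ' / 'and' conjunctions.
    """
    tree = etree.parse(str(source))
    records = []
    for drug in tree.getroot().findall("drug"):
        accession = drug.findtext("drugbank-id")
        if accession is None:
            continue
        rec: dict[str, str] = {"drug_id": accession, "name": drug.findtext("name", default=accession)}
        rec["group"] = _join_text([g.text or "" for g in drug.findall("groups/group")])
        rec["state"] = drug.findtext("state", default="")
        rec["category"] = _join_text(
            [c.findtext("category", default="") for c in drug.findall("categories/category")]
        )
        for tag, fld in [
            ("description", "description"),
            ("indication", "indication"),
            ("mechanism-of-action", "mechanism_of_action"),
            ("pharmacodynamics", "pharmacodynamics"),
            ("half-life", "half_life"),
            ("protein-binding", "protein_binding"),
        ]:
            rec[fld] = drug.findtext(tag, default="")
        codes = [c.get("code", "") for c in drug.findall("atc-codes/atc-code")]
        for level in range(1, 5):
            rec[f"atc_{level}"] = _join_text([c[: level + 1] for c in codes if c])
        rec["pathway"] = _join_text(
            [p.findtext("name", default="") for p in drug.findall("pathways/pathway")]
        )
        records.append(rec)
    return pd.DataFrame(records, columns=["drug_id", "name"] + DRUG_FEATURE_FIELDS)


def _join_text(values: Iterable[str]) -> str:
    vals = [v for v in values if v]
    if not vals:
        return ""
    if len(vals) == 1:
        return vals[0]
    return "; ".join(vals[:-1]) + " and " + vals[-1]


# ---------------------------------------------------------------------------
# Side effects
# ---------------------------------------------------------------------------


def filter_side_effects(
    table: pd.DataFrame,
    stitch_to_atc: XrefMap,
    atc_to_drug: XrefMap,
    cfg: IngestConfig | None = None,
    phenotype_source: str = "HPO",
) -> tuple[TriplesTable, DropLog]:
    """Side-effect rows at the MedDRA preferred-term level, drugs mapped
    through the STITCH -> ATC -> drug-accession chain.

    ``table`` columns: drug_stitch_id, meddra_level, phenotype_id,
    phenotype_name (optional). Rows at other coding levels or with a broken
    mapping chain are dropped and logged.
    """
    cfg = cfg or IngestConfig()
    chain = stitch_to_atc.compose(atc_to_drug)
    log = DropLog()
    rows = []
    for pos, row in table.iterrows():
        if row["meddra_level"] != cfg.sider_preferred_level:
            log.drop("not preferred term", row=int(pos))
            continue
        drugs = chain.lookup(row["drug_stitch_id"])
        if not drugs:
            log.drop("broken mapping chain", identifier=row["drug_stitch_id"], row=int(pos))
            continue
        if len(drugs) > 1:
            log.expand(len(drugs), identifier=row["drug_stitch_id"], row=int(pos))
        for d in drugs:
            rows.append(
                {
                    "relation": "drug_effect",
                    "x_id": d,
                    "x_type": "drug",
                    "x_source": atc_to_drug.dst_ns,
                    "x_name": chain.dst_names.get(d, d),
                    "y_id": row["phenotype_id"],
                    "y_type": "effect/phenotype",
                    "y_source": phenotype_source,
                    "y_name": row.get("phenotype_name", row["phenotype_id"]),
                }
            )
    return TriplesTable(pd.DataFrame(rows), resource_tag="side_effects"), log


# ---------------------------------------------------------------------------
# Thin tabular adapters
# ---------------------------------------------------------------------------


def read_gene_disease(
    path: str | Path, gene_source: str = "NCBI", concept_source: str = "UMLS"
) -> tuple[TriplesTable, TriplesTable]:
    """Curated gene-disease association TSV with columns geneId, geneSymbol,
    diseaseId, diseaseName, diseaseType (disease|phenotype).

    Returns (disease_protein table, phenotype_protein table) in concept
    identifier space; consumed as-is, no further filtering.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for kind, relation, y_type in [
        ("disease", "disease_protein", "disease"),
        ("phenotype", "phenotype_protein", "effect/phenotype"),
    ]:
        sub = df[df["diseaseType"] == kind]
        rows = pd.DataFrame(
            {
                "relation": relation,
                "x_id": sub["diseaseId"],
                "x_type": y_type,
                "x_source": concept_source,
                "x_name": sub["diseaseName"],
                "y_id": sub["geneId"],
                "y_type": "gene/protein",
                "y_source": gene_source,
                "y_name": sub["geneSymbol"],
            }
        )
        out[kind] = TriplesTable(rows, resource_tag=f"gene_disease[{kind}]")
    return out["disease"], out["phenotype"]


LABEL_RELATIONS = {
    "indication": "indication",
    "contraindication": "contraindication",
    "off-label use": "off-label use",
    "off_label_use": "off-label use",
}


def read_drug_disease_labels(
    path: str | Path, drug_source: str = "CAS", disease_source: str = "MONDO"
) -> TriplesTable:
    """Drug-disease label table: columns drug_id, drug_name, disease_id,
    disease_name, label in {indication, contraindication, off-label use}."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(df["label"]) - set(LABEL_RELATIONS)
    if unknown:
        raise ValueError(f"unknown drug-disease label(s): {sorted(unknown)}")
    rows = pd.DataFrame(
        {
            "relation": df["label"].map(LABEL_RELATIONS),
            "x_id": df["drug_id"],
            "x_type": "drug",
            "x_source": drug_source,
            "x_name": df["drug_name"],
            "y_id": df["disease_id"],
            "y_type": "disease",
            "y_source": disease_source,
            "y_name": df["disease_name"],
        }
    )
    return TriplesTable(rows, resource_tag="drug_disease_labels")


def read_ppi(paths: Sequence[str | Path], gene_source: str = "NCBI") -> TriplesTable:
    """Union of physical protein-protein interaction edge lists.

    Interactions are unweighted and undirected; unordered gene pairs are
    deduplicated across sources. Each file: TSV with columns gene_a, gene_b.
    """
    pairs: set[tuple[str, str]] = set()
    for p in paths:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
        for a, b in zip(df["gene_a"], df["gene_b"]):
            pairs.add(tuple(sorted((a, b))))  # type: ignore[arg-type]
    rows = [
        {
            "relation": "protein_protein",
            "x_id": a,
            "x_type": "gene/protein",
            "x_source": gene_source,
            "y_id": b,
            "y_type": "gene/protein",
            "y_source": gene_source,
        }
        for a, b in sorted(pairs)
    ]
    return TriplesTable(pd.DataFrame(rows), resource_tag="ppi")


EXPOSURE_TARGET_RELATIONS = {
    "exposure": ("exposure_exposure", "exposure"),
    "gene/protein": ("exposure_protein", "gene/protein"),
    "disease": ("exposure_disease", "disease"),
    "biological_process": ("exposure_bioprocess", "biological_process"),
    "molecular_function": ("exposure_molfunc", "molecular_function"),
    "cellular_component": ("exposure_cellcomp", "cellular_component"),
}


def read_exposure_links(path: str | Path, target_sources: dict[str, str]) -> TriplesTable:
    """Exposure-event CSV (comment header lines starting with '#' removed):
    columns exposure_id, exposure_name, target_id, target_name, target_type."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    unknown = set(df["target_type"]) - set(EXPOSURE_TARGET_RELATIONS)
    if unknown:
        raise ValueError(f"unknown exposure target type(s): {sorted(unknown)}")
    relations = df["target_type"].map(lambda t: EXPOSURE_TARGET_RELATIONS[t][0])
    rows = pd.DataFrame(
        {
            "relation": relations,
            "x_id": df["exposure_id"],
            "x_type": "exposure",
            "x_source": "CTD",
            "x_name": df["exposure_name"],
            "y_id": df["target_id"],
            "y_type": df["target_type"],
            "y_source": df["target_type"].map(target_sources),
            "y_name": df["target_name"],
        }
    )
    return TriplesTable(rows, resource_tag="exposure_links")


GO_ASPECT = {
    "BP": ("bioprocess_protein", "biological_process"),
    "MF": ("molfunc_protein", "molecular_function"),
    "CC": ("cellcomp_protein", "cellular_component"),
}


def read_gene_go(path: str | Path, gene_source: str = "NCBI") -> TriplesTable:
    """Gene -> GO-term annotation TSV: columns gene_id, gene_symbol, go_id,
    go_name, aspect in {BP, MF, CC}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = set(df["aspect"]) - set(GO_ASPECT)
    if unknown:
        raise ValueError(f"unknown GO aspect(s): {sorted(unknown)}")
    rows = pd.DataFrame(
        {
            "relation": df["aspect"].map(lambda a: GO_ASPECT[a][0]),
            "x_id": df["go_id"],
            "x_type": df["aspect"].map(lambda a: GO_ASPECT[a][1]),
            "x_source": "GO",
            "x_name": df["go_name"],
            "y_id": df["gene_id"],
            "y_type": "gene/protein",
            "y_source": gene_source,
            "y_name": df["gene_symbol"],
        }
    )
    return TriplesTable(rows, resource_tag="gene_go")


def read_reactome(
    pathways_path: str | Path,
    relations_path: str | Path,
    gene_links_path: str | Path,
    species: str = "Homo sapiens",
    gene_source: str = "NCBI",
) -> tuple[TriplesTable, TriplesTable]:
    """Pathway tables: pathway list (id, name, species), parent-child
    relations (parent, child) and gene->pathway links (gene_id, pathway_id,
    species). Returns (pathway_pathway, pathway_protein) restricted to the
    requested species."""
    pathways = pd.read_csv(
        pathways_path, sep="\t", dtype=str, keep_default_na=False,
        header=None, names=["pathway_id", "name", "species"],
    )
    pathways = pathways[pathways["species"] == species]
    names = pathways.set_index("pathway_id")["name"]
    keep = set(names.index)

    rel = pd.read_csv(
        relations_path, sep="\t", dtype=str, keep_default_na=False,
        header=None, names=["parent", "child"],
    )
    rel = rel[rel["parent"].isin(keep) & rel["child"].isin(keep)]
    pp = pd.DataFrame(
        {
            "relation": "pathway_pathway",
            "x_id": rel["child"],
            "x_type": "pathway",
            "x_source": "Reactome",
            "x_name": rel["child"].map(names),
            "y_id": rel["parent"],
            "y_type": "pathway",
            "y_source": "Reactome",
            "y_name": rel["parent"].map(names),
        }
    )

    links = pd.read_csv(
        gene_links_path, sep="\t", dtype=str, keep_default_na=False,
        header=None, names=["gene_id", "pathway_id", "species"],
    )
    links = links[links["species"] == species]
    links = links[links["pathway_id"].isin(keep)]
    pg = pd.DataFrame(
        {
            "relation": "pathway_protein",
            "x_id": links["pathway_id"],
            "x_type": "pathway",
            "x_source": "Reactome",
            "x_name": links["pathway_id"].map(names),
            "y_id": links["gene_id"],
            "y_type": "gene/protein",
            "y_source": gene_source,
        }
    )
    return (
        TriplesTable(pp, resource_tag="pathway_hierarchy"),
        TriplesTable(pg, resource_tag="pathway_protein"),
    )


def read_disease_phenotype_annotations(
    path: str | Path, disease_source: str = "MONDO", phenotype_source: str = "HPO"
) -> TriplesTable:
    """Curated disease-phenotype annotation TSV: columns disease_id,
    disease_name, hpo_id, hpo_name, qualifier ('' for positive, 'NOT' for
    negative associations)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    relation = df["qualifier"].map(
        lambda q: "disease_phenotype_negative" if q == "NOT" else "disease_phenotype_positive"
    )
    rows = pd.DataFrame(
        {
            "relation": relation,
            "x_id": df["disease_id"],
            "x_type": "disease",
            "x_source": disease_source,
            "x_name": df["disease_name"],
            "y_id": df["hpo_id"],
            "y_type": "effect/phenotype",
            "y_source": phenotype_source,
            "y_name": df["hpo_name"],
        }
    )
    return TriplesTable(rows, resource_tag="disease_phenotype_annotations")
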