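"""Synthetic miniature versions of every consumed resource format, with
planted ground truth.

The generator emits a complete mock resource bundle — ontologies in OBO
format, tabular exports, RRF-style concept tables, a drug XML export,
identifier vocabularies and pre-scraped clinical feature tables — whose
identifier namespaces mimic real CURIE shapes (MONDO:, HP:, GO:, UBERON:,
DB...) without using real identifiers. Planted truth records the expected
overlap set, disease grouping partition, per-adapter survivor counts and
connected-component structure, and is verified against the generated files
at generation time (self-audit). Identical spec + seed produce a
byte-identical bundle.

No statistical realism is attempted beyond what the pipeline exercises: the
mock world has no realistic degree distributions and no biological meaning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from . import ingest
from .assembly import assign_node_indices, clean_edges
from .ingest import IngestConfig
from .overlap import compute_overlap_set
from .schema import KnowledgeGraph
from .tables import TriplesTable, XrefMap

__all__ = [
    "FixtureSpec",
    "PlantedTruth",
    "FixtureBundle",
    "make_mock_ontologies",
    "make_mock_resources",
    "make_fixture_bundle",
    "make_planted_disease_names",
    "ProximityTestbed",
    "make_proximity_testbed",
]


class FixtureSpec(BaseModel):
    """Knobs of the mock world. Counts are chosen to exercise every adapter
    filter and rewiring rule at desk scale."""

    rng_seed: int = 0

    # disease ontology / grouping
    n_subtype_families: int = 40
    family_size_min: int = 3
    family_size_max: int = 8
    n_distractor_diseases: int = 100
    n_near_duplicate_pairs: int = 5

    # phenotype ontology / overlap
    n_phenotypes: int = 30
    overlap_fraction: float = 0.2

    # entity pools
    n_proteins: int = 60
    n_drugs: int = 25
    n_anatomy: int = 15
    n_pathways: int = 10
    n_bioprocess: int = 12
    n_molfunc: int = 8
    n_cellcomp: int = 6
    n_exposures: int = 8

    # per-resource row counts / planted survivor counts
    expression_rows: int = 100
    expression_passes: int = 37
    side_effect_rows: int = 12
    side_effect_survivors: int = 5
    umls_concepts: int = 20
    umls_disorders: int = 8
    drug_interactions: int = 9
    drug_protein_pairs: int = 12
    ppi_edges: int = 80
    gene_disease_rows: int = 30
    gene_phenotype_rows: int = 10
    n_indications: int = 15
    n_contraindications: int = 8
    n_off_label: int = 4
    disease_phenotype_rows: int = 25
    include_isolated_component: bool = True

    @model_validator(mode="after")
    def _check(self) -> "FixtureSpec":
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.family_size_min < 1 or self.family_size_max < self.family_size_min:
            raise ValueError("bad family size range")
        for name, v in self.model_dump().items():
            if isinstance(v, int) and name != "rng_seed" and v < 0:
                raise ValueError(f"{name} must be non-negative")
        return self


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    overlap_members: set[str] = field(default_factory=set)
    partition: dict[str, str] = field(default_factory=dict)
    disease_names: dict[str, str] = field(default_factory=dict)
    adapter_counts: dict[str, int] = field(default_factory=dict)
    isolated_nodes: list[str] = field(default_factory=list)
    proximity: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "overlap_members": sorted(self.overlap_members),
                    "partition": self.partition,
                    "disease_names": self.disease_names,
                    "adapter_counts": self.adapter_counts,
                    "isolated_nodes": self.isolated_nodes,
                    "proximity": self.proximity,
                },
                indent=2,
                sort_keys=True,
            ),
            encoding="utf-8",
        )


@dataclass
class FixtureBundle:
    root: Path
    paths: dict[str, str]
    truth: PlantedTruth
    spec: FixtureSpec

    @property
    def manifest_path(self) -> Path:
        return self.root / "manifest.json"


# ---------------------------------------------------------------------------
# Pseudo-identifier and pseudo-name machinery
# ---------------------------------------------------------------------------

_SYLLABLES = [
    "ba", "co", "da", "fe", "gi", "ho", "ju", "ka", "lo", "mu", "ne", "or",
    "pa", "qui", "ra", "su", "ta", "ul", "vo", "wa", "xe", "yo", "zu", "bri",
    "cla", "dro", "fle", "gra", "ster", "min",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]

_DISEASE_SUFFIXES = ["syndrome", "disorder", "deficiency", "dysplasia", "anomaly"]


class _NameFactory:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[str] = set()

    def word(self, n_syllables: int = 3) -> str:
        while True:
            idx = self.rng.integers(0, len(_SYLLABLES), n_syllables)
            w = "".join(_SYLLABLES[i] for i in idx)
            if w not in self.used:
                self.used.add(w)
                return w


def make_planted_disease_names(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, str]]:
    """Disease id -> name map with planted subtype families, distractor
    singletons and near-duplicate pairs, plus the planted partition
    (id -> family key)."""
    rng = rng or np.random.default_rng(spec.rng_seed)
    factory = _NameFactory(rng)
    names: dict[str, str] = {}
    partition: dict[str, str] = {}
    counter = 2  # MONDO:0000001 is the root

    def next_id() -> str:
        nonlocal counter
        mid = f"MONDO:{counter:07d}"
        counter += 1
        return mid

    root = "MONDO:0000001"
    names[root] = "disease"
    partition[root] = root

    for fam in range(spec.n_subtype_families):
        base = f"{factory.word()} {_DISEASE_SUFFIXES[int(rng.integers(0, len(_DISEASE_SUFFIXES)))]}"
        size = int(rng.integers(spec.family_size_min, spec.family_size_max + 1))
        pattern = ["numeric", "roman", "susceptibility"][fam % 3]
        fam_key = f"family:{base}"
        for k in range(size):
            did = next_id()
            if pattern == "numeric":
                names[did] = f"{base} type {k + 1}"
            elif pattern == "roman":
                names[did] = f"{base} type {_ROMAN[k % len(_ROMAN)]}"
            else:
                names[did] = f"{base.capitalize()}, susceptibility to, {k + 1}"
            partition[did] = fam_key

    for _ in range(spec.n_distractor_diseases):
        did = next_id()
        names[did] = f"{factory.word()} {_DISEASE_SUFFIXES[int(rng.integers(0, len(_DISEASE_SUFFIXES)))]}"
        partition[did] = did

    for _ in range(spec.n_near_duplicate_pairs):
        base = f"{factory.word()} {_DISEASE_SUFFIXES[int(rng.integers(0, len(_DISEASE_SUFFIXES)))]}"
        a, b = next_id(), next_id()
        names[a] = base.capitalize()
        names[b] = base + "."
        partition[a] = partition[b] = f"neardup:{base}"
    return names, partition


def _obo_header(tag: str) -> str:
    return f"format-version: 1.2\nontology: {tag}\n"


def _obo_term(
    term_id: str,
    name: str,
    is_a: list[str] | None = None,
    xrefs: list[str] | None = None,
    definition: str | None = None,
    obsolete: bool = False,
) -> str:
    lines = ["", "[Term]", f"id: {term_id}", f"name: {name}"]
    if definition:
        lines.append(f'def: "{definition}" [mock:curator]')
    for parent in is_a or []:
        lines.append(f"is_a: {parent}")
    for x in xrefs or []:
        lines.append(f"xref: {x}")
    if obsolete:
        lines.append("is_obsolete: true")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Ontologies
# ---------------------------------------------------------------------------


def make_mock_ontologies(
    spec: FixtureSpec, outdir: str | Path, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], PlantedTruth, dict]:
    """Write the disease and phenotype ontologies (plus anatomy and the
    three gene-function vocabularies) and return (paths, truth fragment,
    world): ``world`` carries the entity pools reused by the resource
    generator."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = rng or np.random.default_rng(spec.rng_seed)
    truth = PlantedTruth()

    names, partition = make_planted_disease_names(spec, rng)
    truth.disease_names = names
    truth.partition = partition
    disease_ids = sorted(names)
    non_root = [d for d in disease_ids if d != "MONDO:0000001"]

    # overlap planting: half by shared numeric id, half by xref
    n_overlap = round(spec.overlap_fraction * spec.n_phenotypes)
    n_by_numeric = n_overlap // 2
    n_by_xref = n_overlap - n_by_numeric

    pheno_ids: list[str] = ["HP:0500001"]  # root
    pheno_names: dict[str, str] = {"HP:0500001": "phenotypic abnormality"}
    overlap_numeric: list[str] = []
    numeric_sources = [
        d for d in non_root[: n_by_numeric]
    ]  # deterministic choice: first family diseases
    for d in numeric_sources:
        hp = "HP:" + d.split(":")[1]
        overlap_numeric.append(hp)
        pheno_ids.append(hp)
        pheno_names[hp] = names[d].lower()

    overlap_xref: list[str] = []
    xref_targets: dict[str, str] = {}
    pnum = 500002
    for k in range(n_by_xref):
        hp = f"HP:{pnum:07d}"
        pnum += 1
        overlap_xref.append(hp)
        pheno_ids.append(hp)
        target = non_root[n_by_numeric + k]
        xref_targets[target] = hp
        pheno_names[hp] = names[target].lower()

    factory = _NameFactory(rng)
    while len(pheno_ids) < spec.n_phenotypes + 1:  # +1 for root
        hp = f"HP:{pnum:07d}"
        pnum += 1
        pheno_ids.append(hp)
        pheno_names[hp] = f"abnormal {factory.word()} morphology"

    truth.overlap_members = set(overlap_numeric) | set(overlap_xref)

    # isolated pocket: two phenotype terms only linked to each other
    isolated: list[str] = []
    if spec.include_isolated_component:
        iso_a, iso_b = f"HP:{pnum:07d}", f"HP:{pnum + 1:07d}"
        pnum += 2
        pheno_names[iso_a] = f"isolated {factory.word()} finding"
        pheno_names[iso_b] = f"isolated {factory.word()} finding"
        isolated = [iso_a, iso_b]
        truth.isolated_nodes = isolated

    # UMLS xrefs: disorder CUIs attach to the first umls_disorders diseases
    # not already used for overlap planting
    cui_counter = 1

    def next_cui() -> str:
        nonlocal cui_counter
        c = f"C{cui_counter:07d}"
        cui_counter += 1
        return c

    offset = n_by_numeric + n_by_xref
    disorder_cui_map: dict[str, str] = {}  # cui -> mondo
    for d in non_root[offset : offset + spec.umls_disorders]:
        disorder_cui_map[next_cui()] = d

    # extra CUIs for gene-disease rows (mapped via MONDO xrefs)
    gd_pool = non_root[offset + spec.umls_disorders :]
    gd_cui_map: dict[str, str] = {}
    for d in gd_pool[: spec.gene_disease_rows]:
        gd_cui_map[next_cui()] = d

    # phenotype CUIs (mapped via HPO xrefs); include one overlap member so
    # the converted protein-phenotype -> protein-disease path is exercised
    pheno_cui_map: dict[str, str] = {}
    pheno_pool = [p for p in pheno_ids[1:] if p not in truth.overlap_members]
    pheno_cui_targets = ([overlap_numeric[0]] if overlap_numeric else []) + pheno_pool
    for p in pheno_cui_targets[: spec.gene_phenotype_rows]:
        pheno_cui_map[next_cui()] = p

    # orphanet-style identifiers for a handful of diseases
    orpha_map: dict[str, str] = {}
    for i, d in enumerate(gd_pool[: min(6, len(gd_pool))]):
        orpha_map[f"{90000 + i}"] = d

    # --- write the disease ontology ---------------------------------------
    mondo_xrefs: dict[str, list[str]] = {}
    for cui, d in {**disorder_cui_map, **gd_cui_map}.items():
        mondo_xrefs.setdefault(d, []).append(f"UMLS:{cui}")
    for d, hp in xref_targets.items():
        mondo_xrefs.setdefault(d, []).append(hp)
    for orpha, d in orpha_map.items():
        mondo_xrefs.setdefault(d, []).append(f"ORPHA:{orpha}")

    parts = [_obo_header("mock-mondo")]
    parts.append(_obo_term("MONDO:0000001", "disease", definition="A disease."))
    for d in non_root:
        parts.append(
            _obo_term(
                d,
                names[d],
                is_a=["MONDO:0000001"],
                xrefs=sorted(mondo_xrefs.get(d, [])),
                definition=f"A mock disease record for {names[d]}.",
            )
        )
    parts.append(
        _obo_term("MONDO:0999999", "retired mock concept", obsolete=True)
    )
    mondo_path = outdir / "mock_mondo.obo"
    mondo_path.write_text("".join(parts), encoding="utf-8")

    # --- write the phenotype ontology --------------------------------------
    hpo_xrefs: dict[str, list[str]] = {}
    for cui, p in pheno_cui_map.items():
        hpo_xrefs.setdefault(p, []).append(f"UMLS:{cui}")
    parts = [_obo_header("mock-hpo")]
    parts.append(_obo_term("HP:0500001", pheno_names["HP:0500001"]))
    for p in pheno_ids[1:]:
        parts.append(
            _obo_term(
                p, pheno_names[p], is_a=["HP:0500001"], xrefs=sorted(hpo_xrefs.get(p, []))
            )
        )
    if isolated:
        parts.append(_obo_term(isolated[0], pheno_names[isolated[0]]))
        parts.append(
            _obo_term(isolated[1], pheno_names[isolated[1]], is_a=[isolated[0]])
        )
    hpo_path = outdir / "mock_hpo.obo"
    hpo_path.write_text("".join(parts), encoding="utf-8")

    # --- anatomy ------------------------------------------------------------
    anatomy_ids = [f"UBERON:{i:07d}" for i in range(1, spec.n_anatomy + 1)]
    parts = [_obo_header("mock-uberon")]
    parts.append(_obo_term(anatomy_ids[0], "anatomical structure"))
    for a in anatomy_ids[1:]:
        parts.append(
            _obo_term(a, f"{factory.word()} structure", is_a=[anatomy_ids[0]])
        )
    uberon_path = outdir / "mock_uberon.obo"
    uberon_path.write_text("".join(parts), encoding="utf-8")

    # --- gene-function vocabularies (one file per aspect) -------------------
    go_paths = {}
    go_ids: dict[str, list[str]] = {}
    start = 1
    for aspect, count, rootname in [
        ("bp", spec.n_bioprocess, "biological process"),
        ("mf", spec.n_molfunc, "molecular function"),
        ("cc", spec.n_cellcomp, "cellular component"),
    ]:
        ids = [f"GO:{i:07d}" for i in range(start, start + count)]
        start += count
        go_ids[aspect] = ids
        parts = [_obo_header(f"mock-go-{aspect}")]
        parts.append(_obo_term(ids[0], rootname))
        for g in ids[1:]:
            parts.append(_obo_term(g, f"{factory.word()} {rootname}", is_a=[ids[0]]))
        p = outdir / f"mock_go_{aspect}.obo"
        p.write_text("".join(parts), encoding="utf-8")
        go_paths[aspect] = str(p)

    world = {
        "disease_ids": disease_ids,
        "non_root_diseases": non_root,
        "pheno_ids": pheno_ids,
        "pheno_names": pheno_names,
        "overlap_numeric": overlap_numeric,
        "overlap_xref": overlap_xref,
        "disorder_cui_map": disorder_cui_map,
        "gd_cui_map": gd_cui_map,
        "pheno_cui_map": pheno_cui_map,
        "orpha_map": orpha_map,
        "anatomy_ids": anatomy_ids,
        "go_ids": go_ids,
        "isolated": isolated,
        "factory": factory,
    }
    paths = {
        "disease_obo": str(mondo_path),
        "phenotype_obo": str(hpo_path),
        "anatomy_obo": str(uberon_path),
        "go_bp_obo": go_paths["bp"],
        "go_mf_obo": go_paths["mf"],
        "go_cc_obo": go_paths["cc"],
    }
    return paths, truth, world


# ---------------------------------------------------------------------------
# Tabular / XML resources
# ---------------------------------------------------------------------------


def make_mock_resources(
    spec: FixtureSpec,
    outdir: str | Path,
    world: dict,
    truth: PlantedTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Write every tabular/XML resource and vocabulary; update ``truth``
    with per-adapter survivor counts."""
    outdir = Path(outdir)
    rng = rng or np.random.default_rng(spec.rng_seed + 1)
    factory: _NameFactory = world["factory"]
    paths: dict[str, str] = {}

    genes = [str(1000 + i) for i in range(spec.n_proteins)]
    symbols = {g: factory.word(2).upper() for g in genes}
    uniprot = {g: f"P{20000 + i}" for i, g in enumerate(genes)}
    drugs = [f"DB{i:05d}" for i in range(1, spec.n_drugs + 1)]
    drug_names = {d: f"{factory.word()}ib" for d in drugs}
    cas = {d: f"{50 + i}-{10 + i % 80}-{i % 10}" for i, d in enumerate(drugs)}
    stitch = {d: f"CID{100000 + i}" for i, d in enumerate(drugs)}
    atc = {d: f"{'ABCDEFG'[i % 7]}{i:02d}AB{i % 10:02d}" for i, d in enumerate(drugs)}

    def pick(seq, n):
        seq = list(seq)
        idx = sorted(rng.choice(len(seq), size=min(n, len(seq)), replace=False).tolist())
        return [seq[i] for i in idx]

    # --- expression calls ----------------------------------------------------
    rows = []
    n_pass = spec.expression_passes
    for i in range(spec.expression_rows):
        anatomy = world["anatomy_ids"][int(rng.integers(0, len(world["anatomy_ids"])))]
        gene = genes[int(rng.integers(0, len(genes)))]
        call = "present" if rng.random() < 0.8 else "absent"
        if i < n_pass:
            fdr = 0.01 if i == 0 else round(float(rng.uniform(0.0001, 0.009)), 5)
            rank = 24999 if i == 1 else int(rng.integers(1, 24000))
            quality = "gold quality"
        else:
            mode = i % 4
            if mode == 0:
                quality, fdr, rank = "silver quality", 0.001, 100
            elif mode == 1:
                quality, fdr, rank = "gold quality", round(float(rng.uniform(0.02, 0.5)), 4), 100
            elif mode == 2:
                quality, fdr, rank = "gold quality", 0.001, int(rng.integers(25000, 60000))
            else:
                quality, fdr, rank = "gold quality", 0.001, "NA"
        rows.append(
            {
                "anatomy_id": anatomy,
                "gene_id": gene,
                "call": call,
                "quality": quality,
                "fdr": fdr,
                "rank": rank,
            }
        )
    expr_path = outdir / "expression_calls.tsv"
    pd.DataFrame(rows).to_csv(expr_path, sep="\t", index=False)
    paths["expression_calls"] = str(expr_path)
    truth.adapter_counts["expression_survivors"] = n_pass

    # --- gene-disease associations -------------------------------------------
    rows = []
    gd_cuis = sorted(world["gd_cui_map"])
    for i, cui in enumerate(gd_cuis[: spec.gene_disease_rows]):
        g = genes[int(rng.integers(0, len(genes)))]
        rows.append(
            {
                "geneId": g,
                "geneSymbol": symbols[g],
                "diseaseId": cui,
                "diseaseName": truth.disease_names[world["gd_cui_map"][cui]],
                "diseaseType": "disease",
            }
        )
    pheno_cuis = sorted(world["pheno_cui_map"])
    for cui in pheno_cuis[: spec.gene_phenotype_rows]:
        g = genes[int(rng.integers(0, len(genes)))]
        rows.append(
            {
                "geneId": g,
                "geneSymbol": symbols[g],
                "diseaseId": cui,
                "diseaseName": world["pheno_names"][world["pheno_cui_map"][cui]],
                "diseaseType": "phenotype",
            }
        )
    # two unmapped concept rows, dropped at identifier mapping
    rows.append(
        {"geneId": genes[0], "geneSymbol": symbols[genes[0]], "diseaseId": "C0999998",
         "diseaseName": "unmapped concept", "diseaseType": "disease"}
    )
    rows.append(
        {"geneId": genes[1], "geneSymbol": symbols[genes[1]], "diseaseId": "C0999999",
         "diseaseName": "unmapped concept", "diseaseType": "phenotype"}
    )
    gd_path = outdir / "gene_disease.tsv"
    pd.DataFrame(rows).to_csv(gd_path, sep="\t", index=False)
    paths["gene_disease"] = str(gd_path)
    truth.adapter_counts["gene_disease_mapped"] = len(gd_cuis[: spec.gene_disease_rows])
    truth.adapter_counts["gene_phenotype_mapped"] = len(pheno_cuis[: spec.gene_phenotype_rows])
    truth.adapter_counts["gene_disease_unmapped"] = 2

    # --- drug-disease labels (drug ids in CAS space) --------------------------
    rows = []
    label_counts = {
        "indication": spec.n_indications,
        "contraindication": spec.n_contraindications,
        "off-label use": spec.n_off_label,
    }
    usable = world["non_root_diseases"]
    for label, count in label_counts.items():
        for _ in range(count):
            d = drugs[int(rng.integers(0, len(drugs)))]
            dis = usable[int(rng.integers(0, len(usable)))]
            rows.append(
                {
                    "drug_id": cas[d],
                    "drug_name": drug_names[d],
                    "disease_id": dis,
                    "disease_name": truth.disease_names[dis],
                    "label": label,
                }
            )
    labels_path = outdir / "drug_disease_labels.csv"
    pd.DataFrame(rows).to_csv(labels_path, index=False)
    paths["drug_disease_labels"] = str(labels_path)
    for label, count in label_counts.items():
        truth.adapter_counts[f"labels[{label}]"] = count

    # --- PPI union -------------------------------------------------------------
    all_pairs = set()
    while len(all_pairs) < spec.ppi_edges:
        a, b = pick(genes, 2)
        if a != b:
            all_pairs.add(tuple(sorted((a, b))))
    all_pairs = sorted(all_pairs)
    half = len(all_pairs) // 2
    file_a = all_pairs[: half + 5]  # overlapping slices: union == all_pairs
    file_b = all_pairs[half - 5 :]
    ppi_paths = []
    for tag, pairs in [("ppi_a", file_a), ("ppi_b", file_b)]:
        p = outdir / f"{tag}.tsv"
        pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(p, sep="\t", index=False)
        ppi_paths.append(str(p))
    paths["ppi"] = json.dumps(ppi_paths)
    truth.adapter_counts["ppi_unique_pairs"] = len(all_pairs)

    # --- side effects -----------------------------------------------------------
    rows = []
    se_phenos = [
        p
        for p in world["pheno_ids"][1:]
        if p not in truth.overlap_members and p not in world["isolated"]
    ]
    survivors = spec.side_effect_survivors
    se_drugs = pick(drugs, max(3, survivors))
    for i in range(spec.side_effect_rows):
        d = se_drugs[i % len(se_drugs)]
        pheno = se_phenos[i % len(se_phenos)]
        if i < survivors:
            level, sid = "PT", stitch[d]
        elif i % 2 == 0:
            level, sid = "LLT", stitch[d]
        else:
            level, sid = "PT", "CID9999999"  # broken mapping chain
        rows.append(
            {
                "drug_stitch_id": sid,
                "meddra_level": level,
                "phenotype_id": pheno,
                "phenotype_name": world["pheno_names"][pheno],
            }
        )
    # one surviving row pointing at an overlap member, to exercise the
    # drug-phenotype drop rule during rewiring
    if truth.overlap_members:
        pheno = sorted(truth.overlap_members)[0]
        rows.append(
            {
                "drug_stitch_id": stitch[se_drugs[0]],
                "meddra_level": "PT",
                "phenotype_id": pheno,
                "phenotype_name": world["pheno_names"][pheno],
            }
        )
        truth.adapter_counts["side_effect_overlap_rows"] = 1
    else:
        truth.adapter_counts["side_effect_overlap_rows"] = 0
    se_path = outdir / "side_effects.tsv"
    pd.DataFrame(rows).to_csv(se_path, sep="\t", index=False)
    paths["side_effects"] = str(se_path)
    truth.adapter_counts["side_effect_survivors"] = (
        survivors + truth.adapter_counts["side_effect_overlap_rows"]
    )

    # --- UMLS RRF tables ----------------------------------------------------------
    disorder_cuis = sorted(world["disorder_cui_map"])
    other_cuis = [f"C{800000 + i:07d}" for i in range(spec.umls_concepts - len(disorder_cuis))]
    disorder_types = sorted(ingest.UMLS_DISORDER_TYPES)
    conso, sty, mrdef = [], [], []
    for i, cui in enumerate(disorder_cuis):
        name = truth.disease_names[world["disorder_cui_map"][cui]]
        conso.append(f"{cui}|ENG|{name}|")
        conso.append(f"{cui}|FRE|{name} (fr)|")
        sty.append(f"{cui}|{disorder_types[i % len(disorder_types)]}|")
        mrdef.append(f"{cui}|MSH|A mock disorder definition for {name}.|")
    for i, cui in enumerate(other_cuis):
        conso.append(f"{cui}|ENG|non disorder concept {i}|")
        sty.append(f"{cui}|Finding|")
        mrdef.append(f"{cui}|MSH|A mock non-disorder definition.|")
    for fname, lines in [
        ("MRCONSO.RRF", conso),
        ("MRSTY.RRF", sty),
        ("MRDEF.RRF", mrdef),
    ]:
        (outdir / fname).write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths[fname.split(".")[0].lower()] = str(outdir / fname)
    truth.adapter_counts["umls_disorder_definitions"] = len(disorder_cuis)

    # --- drug XML -------------------------------------------------------------------
    interactions = set()
    while len(interactions) < spec.drug_interactions:
        a, b = pick(drugs, 2)
        if a != b:
            interactions.add(tuple(sorted((a, b))))
    interactions = sorted(interactions)
    listed: dict[str, list[str]] = {d: [] for d in drugs}
    for k, (a, b) in enumerate(interactions):
        listed[a].append(b)
        if k % 2 == 0:  # mirror every other record
            listed[b].append(a)
    xml_lines = ["<drugbank>"]
    for i, d in enumerate(drugs):
        half_life = (
            "No half-life data is available."
            if i % 5 == 0
            else f"{2 + i % 7}.1-{3 + i % 7}.5 hours"
        )
        xml_lines += [
            "  <drug>",
            f"    <drugbank-id>{d}</drugbank-id>",
            f"    <name>{drug_names[d]}</name>",
            f"    <state>{'solid' if i % 2 else 'liquid'}</state>",
            "    <groups><group>approved</group>"
            + ("<group>vet approved</group>" if i % 3 == 0 else "")
            + "</groups>",
            "    <categories><category><category>Mock Agents</category></category></categories>",
            f"    <description>{drug_names[d]} is a mock compound [L{1000 + i}] for testing.</description>",
            f"    <indication>Indicated for mock conditions [A{i + 1}].</indication>",
            f"    <mechanism-of-action>Binds the mock receptor [L{2000 + i}].</mechanism-of-action>",
            f"    <pharmacodynamics>Produces mock effects.</pharmacodynamics>",
            f"    <half-life>{half_life}</half-life>",
            f"    <protein-binding>{40 + i % 50}% bound.</protein-binding>",
            f"    <atc-codes><atc-code code=\"{atc[d]}\"/></atc-codes>",
            "    <pathways><pathway><name>Mock Action Pathway</name></pathway></pathways>",
            "    <drug-interactions>"
            + "".join(
                f"<drug-interaction><drugbank-id>{o}</drugbank-id></drug-interaction>"
                for o in listed[d]
            )
            + "</drug-interactions>",
            "  </drug>",
        ]
    xml_lines.append("</drugbank>")
    xml_path = outdir / "drugs.xml"
    xml_path.write_text("\n".join(xml_lines), encoding="utf-8")
    paths["drug_xml"] = str(xml_path)
    truth.adapter_counts["drug_interactions"] = len(interactions)

    # --- drug-protein partner exports ---------------------------------------------
    partner_pairs = set()
    while len(partner_pairs) < spec.drug_protein_pairs:
        d = drugs[int(rng.integers(0, len(drugs)))]
        g = genes[int(rng.integers(0, len(genes)))]
        partner_pairs.add((d, uniprot[g]))
    partner_pairs = sorted(partner_pairs)
    quarters = [partner_pairs[i::4] for i in range(4)]
    quarters[1] = quarters[1] + partner_pairs[:2]  # overlap across files
    partner_paths = {}
    for tag, pairs in zip(["targets", "enzymes", "carriers", "transporters"], quarters):
        p = outdir / f"{tag}.csv"
        pd.DataFrame(sorted(pairs), columns=["drug_id", "uniprot_id"]).to_csv(p, index=False)
        partner_paths[tag] = str(p)
    paths.update({f"partners_{k}": v for k, v in partner_paths.items()})
    truth.adapter_counts["drug_protein_pairs"] = len(partner_pairs)

    # --- exposures -------------------------------------------------------------------
    exposures = [f"MESH:D{i:06d}" for i in range(1, spec.n_exposures + 1)]
    exp_names = {e: f"{factory.word()} exposure" for e in exposures}
    rows = []
    go_ids = world["go_ids"]
    target_cycle = [
        ("exposure", exposures[0], exp_names[exposures[0]]),
        ("gene/protein", genes[2], symbols[genes[2]]),
        ("disease", usable[2], truth.disease_names[usable[2]]),
        ("biological_process", go_ids["bp"][1], "mock process"),
        ("molecular_function", go_ids["mf"][1], "mock function"),
        ("cellular_component", go_ids["cc"][1], "mock component"),
    ]
    for i, e in enumerate(exposures[1:], start=1):
        ttype, tid, tname = target_cycle[i % len(target_cycle)]
        rows.append(
            {
                "exposure_id": e,
                "exposure_name": exp_names[e],
                "target_id": tid,
                "target_name": tname,
                "target_type": ttype,
            }
        )
    # anchor the hub exposure to a gene so the exposure-exposure pair is
    # connected to the rest of the graph
    rows.append(
        {
            "exposure_id": exposures[0],
            "exposure_name": exp_names[exposures[0]],
            "target_id": genes[3],
            "target_name": symbols[genes[3]],
            "target_type": "gene/protein",
        }
    )
    exp_path = outdir / "exposure_events.csv"
    with open(exp_path, "w", encoding="utf-8") as fh:
        fh.write("# mock exposure export\n# generated fixture, header comments removed by adapter\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    paths["exposures"] = str(exp_path)
    truth.adapter_counts["exposure_rows"] = len(rows)

    # --- gene -> GO annotations --------------------------------------------------------
    rows = []
    for aspect, key in [("BP", "bp"), ("MF", "mf"), ("CC", "cc")]:
        for g_term in go_ids[key][1:]:
            g = genes[int(rng.integers(0, len(genes)))]
            rows.append(
                {
                    "gene_id": g,
                    "gene_symbol": symbols[g],
                    "go_id": g_term,
                    "go_name": f"mock {aspect} term",
                    "aspect": aspect,
                }
            )
    rows.append(dict(rows[0]))  # planted exact duplicate, dropped at assembly
    go_path = outdir / "gene2go.tsv"
    pd.DataFrame(rows).to_csv(go_path, sep="\t", index=False)
    paths["gene_go"] = str(go_path)
    truth.adapter_counts["gene_go_rows"] = len(rows)

    # --- pathways ------------------------------------------------------------------------
    pathways = [f"R-HSA-{7000 + i}" for i in range(spec.n_pathways)]
    pw_rows = [(p, f"{factory.word()} pathway", "Homo sapiens") for p in pathways]
    pw_rows.append(("R-MMU-999", "mouse pathway", "Mus musculus"))
    pw_path = outdir / "pathways.tsv"
    pd.DataFrame(pw_rows).to_csv(pw_path, sep="\t", index=False, header=False)
    rel_rows = [(pathways[0], p) for p in pathways[1:]]
    rel_path = outdir / "pathway_relations.tsv"
    pd.DataFrame(rel_rows).to_csv(rel_path, sep="\t", index=False, header=False)
    link_rows = []
    for p in pathways:
        g = genes[int(rng.integers(0, len(genes)))]
        link_rows.append((g, p, "Homo sapiens"))
    link_rows.append((genes[0], "R-MMU-999", "Mus musculus"))
    link_path = outdir / "gene_pathways.tsv"
    pd.DataFrame(link_rows).to_csv(link_path, sep="\t", index=False, header=False)
    paths["pathways"] = str(pw_path)
    paths["pathway_relations"] = str(rel_path)
    paths["gene_pathways"] = str(link_path)
    truth.adapter_counts["pathway_hierarchy_rows"] = len(rel_rows)
    truth.adapter_counts["pathway_gene_rows"] = len(link_rows) - 1

    # --- disease-phenotype annotations ----------------------------------------------------
    rows = []
    ann_phenos = [p for p in world["pheno_ids"][1:] if p not in world["isolated"]]
    safe_phenos = [p for p in ann_phenos if p not in truth.overlap_members]
    n_overlap_rows = min(3, len([p for p in ann_phenos if p in truth.overlap_members]))
    overlap_list = sorted(truth.overlap_members)[:n_overlap_rows]
    for i in range(spec.disease_phenotype_rows - n_overlap_rows):
        dis = usable[int(rng.integers(0, len(usable)))]
        pheno = safe_phenos[i % len(safe_phenos)]
        rows.append(
            {
                "disease_id": dis,
                "disease_name": truth.disease_names[dis],
                "hpo_id": pheno,
                "hpo_name": world["pheno_names"][pheno],
                "qualifier": "NOT" if i % 6 == 0 else "",
            }
        )
    for pheno in overlap_list:  # dropped at rewiring
        dis = usable[0]
        rows.append(
            {
                "disease_id": dis,
                "disease_name": truth.disease_names[dis],
                "hpo_id": pheno,
                "hpo_name": world["pheno_names"][pheno],
                "qualifier": "",
            }
        )
    dp_path = outdir / "disease_phenotypes.tsv"
    pd.DataFrame(rows).to_csv(dp_path, sep="\t", index=False)
    paths["disease_phenotypes"] = str(dp_path)
    truth.adapter_counts["disease_phenotype_rows"] = len(rows)
    truth.adapter_counts["disease_phenotype_overlap_rows"] = n_overlap_rows

    # --- vocabularies ------------------------------------------------------------------------
    hgnc = pd.DataFrame(
        {"uniprot_id": [uniprot[g] for g in genes], "ncbi_id": genes,
         "symbol": [symbols[g] for g in genes]}
    )
    hgnc_path = outdir / "gene_vocab.csv"
    hgnc.to_csv(hgnc_path, index=False)
    vocab = pd.DataFrame(
        {"drug_id": drugs, "cas": [cas[d] for d in drugs],
         "name": [drug_names[d] for d in drugs]}
    )
    vocab_path = outdir / "drug_vocab.csv"
    vocab.to_csv(vocab_path, index=False)
    stitch_atc = pd.DataFrame(
        {"stitch_id": [stitch[d] for d in drugs], "atc": [atc[d] for d in drugs]}
    )
    stitch_path = outdir / "stitch_atc.tsv"
    stitch_atc.to_csv(stitch_path, sep="\t", index=False)
    atc_db = pd.DataFrame({"atc": [atc[d] for d in drugs], "drug_id": drugs})
    atc_path = outdir / "atc_drug.csv"
    atc_db.to_csv(atc_path, index=False)
    paths.update(
        {
            "gene_vocab": str(hgnc_path),
            "drug_vocab": str(vocab_path),
            "stitch_atc": str(stitch_path),
            "atc_drug": str(atc_path),
        }
    )

    # --- numeric drug descriptors (drug-central style) -----------------------------------------
    structures = pd.DataFrame(
        {
            "cas": [cas[d] for d in drugs],
            "molecular_weight": [round(200 + 10 * i + 0.45, 2) for i in range(len(drugs))],
            "tpsa": [round(40 + 3.7 * i, 2) for i in range(len(drugs))],
            "clogp": [round(-1 + 0.3 * i, 2) for i in range(len(drugs))],
        }
    )
    structures_path = outdir / "drug_structures.csv"
    structures.to_csv(structures_path, index=False)
    paths["drug_structures"] = str(structures_path)

    # --- pre-scraped clinical feature tables (synthetic stand-ins) ------------------------------
    mayo_rows = []
    for d in pick(world["non_root_diseases"], 8):
        name = truth.disease_names[d]
        mayo_rows.append(
            {
                "disease_name": name,
                "symptoms": f"Common signs of {name} include mock symptom A and B. "
                "When to see a doctor: seek care if symptoms persist.",
                "causes": f"{name} is caused by a mock mechanism.",
                "risk_factors": "Mock risk factors include age.",
                "complications": "Mock complications may occur.",
                "prevention": "No known prevention.",
            }
        )
    mayo_path = outdir / "clinical_overviews_synthetic.csv"
    pd.DataFrame(mayo_rows).to_csv(mayo_path, index=False)
    paths["clinical_overviews"] = str(mayo_path)

    orpha_rows = []
    for orpha_id, d in sorted(world["orpha_map"].items()):
        name = truth.disease_names[d]
        orpha_rows.append(
            {
                "orpha_id": orpha_id,
                "definition": f"A rare mock condition: {name}.",
                "prevalence": "1/200000",
                "epidemiology": "Described in mock cohorts.",
                "clinical_description": "Mock clinical course.",
                "management_and_treatment": "Supportive mock care.",
            }
        )
    orpha_path = outdir / "rare_disease_features_synthetic.csv"
    pd.DataFrame(orpha_rows).to_csv(orpha_path, index=False)
    paths["rare_disease_features"] = str(orpha_path)

    return paths


# ---------------------------------------------------------------------------
# Bundle + self-audit
# ---------------------------------------------------------------------------


def make_fixture_bundle(spec: FixtureSpec, outdir: str | Path) -> FixtureBundle:
    """Generate the full bundle, write manifest and truth files, and verify
    the planted truth against the generated files (self-audit)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)
    onto_paths, truth, world = make_mock_ontologies(spec, outdir, rng)
    resource_paths = make_mock_resources(spec, outdir, world, truth, rng)
    paths = {**onto_paths, **resource_paths}

    manifest = {"spec": spec.model_dump(), "paths": paths}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    truth.to_json(outdir / "truth.json")
    bundle = FixtureBundle(root=outdir, paths=paths, truth=truth, spec=spec)
    _self_audit(bundle)
    return bundle


def _self_audit(bundle: FixtureBundle) -> None:
    """Check planted counts and the planted overlap set against the files."""
    t, p = bundle.truth, bundle.paths
    cfg = IngestConfig()

    expr = pd.read_csv(p["expression_calls"], sep="\t", dtype=str, keep_default_na=False)
    table, _ = ingest.filter_expression_calls(expr, cfg)
    _audit_eq(len(table), t.adapter_counts["expression_survivors"], "expression survivors")

    conso = ingest.read_rrf(p["mrconso"], ["cui", "lat", "name"])
    sty = ingest.read_rrf(p["mrsty"], ["cui", "sty"])
    mrdef = ingest.read_rrf(p["mrdef"], ["cui", "sab", "definition"])
    defs, _ = ingest.select_umls_disorders(conso, sty, mrdef, cfg)
    _audit_eq(
        len(defs), t.adapter_counts["umls_disorder_definitions"], "disorder definitions"
    )

    interactions = ingest.parse_drug_interactions(p["drug_xml"])
    _audit_eq(len(interactions), t.adapter_counts["drug_interactions"], "drug interactions")

    partners = [
        ingest.read_partner_table(p[f"partners_{tag}"], tag)
        for tag in ["targets", "enzymes", "carriers", "transporters"]
    ]
    merged = ingest.merge_drug_protein_partners(*partners)
    _audit_eq(len(merged), t.adapter_counts["drug_protein_pairs"], "drug-protein pairs")

    se = pd.read_csv(p["side_effects"], sep="\t", dtype=str, keep_default_na=False)
    stitch_atc = pd.read_csv(p["stitch_atc"], sep="\t", dtype=str, keep_default_na=False)
    atc_db = pd.read_csv(p["atc_drug"], dtype=str, keep_default_na=False)
    m1 = XrefMap.from_pairs("STITCH", "ATC", zip(stitch_atc["stitch_id"], stitch_atc["atc"]))
    m2 = XrefMap.from_pairs("ATC", "DrugBank", zip(atc_db["atc"], atc_db["drug_id"]))
    se_table, _ = ingest.filter_side_effects(se, m1, m2, cfg)
    _audit_eq(len(se_table), t.adapter_counts["side_effect_survivors"], "side-effect survivors")

    ppi = ingest.read_ppi(json.loads(p["ppi"]))
    _audit_eq(len(ppi), t.adapter_counts["ppi_unique_pairs"], "ppi unique pairs")

    disease_ont = ingest.parse_obo(p["disease_obo"], "MONDO")
    pheno_ont = ingest.parse_obo(p["phenotype_obo"], "HPO")
    overlap = compute_overlap_set(pheno_ont, disease_ont)
    if overlap.members != t.overlap_members:
        raise AssertionError(
            "self-audit failed: overlap set mismatch "
            f"(planted {len(t.overlap_members)}, computed {len(overlap.members)})"
        )


def _audit_eq(got: int, want: int, what: str) -> None:
    if got != want:
        raise AssertionError(f"self-audit failed: {what}: planted {want}, computed {got}")


# ---------------------------------------------------------------------------
# Proximity testbeds
# ---------------------------------------------------------------------------


@dataclass
class ProximityTestbed:
    """Planted graphs for the permutation-test properties.

    ``exchangeable_kg``: a drug at the head of a protein chain with one
    disease per chain position, so every candidate disease sits at a
    distinct hop distance and the tested disease is exchangeable with the
    null sample. ``planted_kg``: one indicated disease at 2 hops against a
    background of diseases all at >= 4 hops.
    """

    exchangeable_kg: KnowledgeGraph
    exchangeable_drug: str
    exchangeable_diseases: list[str]
    planted_kg: KnowledgeGraph
    planted_pair: tuple[str, str]
    planted_background: list[str]
    truth: dict


def _kg_from_rows(rows: list[dict]) -> KnowledgeGraph:
    table = TriplesTable(pd.DataFrame(rows), resource_tag="testbed")
    cleaned, _ = clean_edges(table)
    return assign_node_indices(cleaned)


def _edge(rel, x_id, x_type, y_id, y_type, source="mock") -> dict:
    return {
        "relation": rel,
        "x_id": x_id,
        "x_type": x_type,
        "x_source": source,
        "y_id": y_id,
        "y_type": y_type,
        "y_source": source,
    }


def make_proximity_testbed(
    n_chain_diseases: int = 100, n_background: int = 1100
) -> ProximityTestbed:
    """Build the exchangeable-null and planted-signal graphs.

    The construction is deterministic; randomness enters only through the
    permutation test itself.
    """
    # exchangeable chain: drug - g1 - g2 - ... - gN; disease_i hangs off g_i
    rows = []
    drug = "DBX00001"
    diseases = [f"MONDO:{8000000 + i:07d}" for i in range(1, n_chain_diseases + 1)]
    prev = "gene0"
    rows.append(_edge("drug_protein", drug, "drug", prev, "gene/protein"))
    for i, dis in enumerate(diseases, start=1):
        g = f"gene{i}"
        rows.append(_edge("protein_protein", prev, "gene/protein", g, "gene/protein"))
        rows.append(_edge("disease_protein", dis, "disease", g, "gene/protein"))
        prev = g
    exchangeable_kg = _kg_from_rows(rows)

    # planted signal: indicated disease at 2 hops, background at 4 hops
    rows = []
    drug2 = "DBX00002"
    target = "MONDO:9000001"
    rows.append(_edge("drug_protein", drug2, "drug", "pA", "gene/protein"))
    rows.append(_edge("disease_protein", target, "disease", "pA", "gene/protein"))
    rows.append(_edge("drug_protein", drug2, "drug", "p1", "gene/protein"))
    rows.append(_edge("protein_protein", "p1", "gene/protein", "p2", "gene/protein"))
    rows.append(_edge("protein_protein", "p2", "gene/protein", "p3", "gene/protein"))
    background = [f"MONDO:{9100000 + i:07d}" for i in range(1, n_background + 1)]
    for dis in background:
        rows.append(_edge("disease_protein", dis, "disease", "p3", "gene/protein"))
    planted_kg = _kg_from_rows(rows)

    truth = {
        "exchangeable": {
            "n_diseases": n_chain_diseases,
            # drug-gene0 is hop 1; disease_i hangs off gene_i at hop i+1
            "distances": {dis: i + 2 for i, dis in enumerate(diseases, start=1)},
            "label": "null",
        },
        "planted": {
            "observed_distance": 2,
            "background_distance": 4,
            "label": "significant expected",
        },
    }
    return ProximityTestbed(
        exchangeable_kg=exchangeable_kg,
        exchangeable_drug=drug,
        exchangeable_diseases=diseases,
        planted_kg=planted_kg,
        planted_pair=(drug2, target),
        planted_background=background,
        truth=truth,
    )
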