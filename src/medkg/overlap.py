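"""Resolving overlap between phenotype and disease nodes.

Disease and phenotype vocabularies maintained by one initiative share
term numbering and cross-references, so some phenotype terms also denote
diseases. The overlap set P collects phenotype identifiers that (i) carry
the same numeric identifier as a disease term or (ii) are cross-referenced
from the disease ontology. Edges touching P are rewired so that each
entity is represented in exactly one role:

* phenotype-phenotype with one endpoint in P  -> disease-phenotype
* phenotype-phenotype with both endpoints in P -> disease-disease
* protein-phenotype with the phenotype in P    -> protein-disease
* disease-phenotype / drug-phenotype with the phenotype in P -> dropped
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .ingest import OntologyGraph
from .tables import TriplesTable, XrefMap

__all__ = ["OverlapSet", "RewireLog", "compute_overlap_set", "rewire_edges"]

_NUMERIC_SUFFIX = re.compile(r":0*(\d+)$")


def _numeric_suffix(curie: str) -> str | None:
    m = _NUMERIC_SUFFIX.search(curie)
    return m.group(1) if m else None


@dataclass
class OverlapSet:
    """Phenotype terms that also denote diseases.

    ``evidence`` maps each member to 'same-numeric-id', 'xref-mapped' or
    'both'; ``mapping`` gives the disease identifier(s) each member
    resolves to.
    """

    members: set[str] = field(default_factory=set)
    evidence: dict[str, str] = field(default_factory=dict)
    mapping: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __contains__(self, pheno_id: str) -> bool:
        return pheno_id in self.members

    def __len__(self) -> int:
        return len(self.members)

    def to_xref_map(self, src_ns: str = "HPO", dst_ns: str = "MONDO") -> XrefMap:
        pairs = [(p, d) for p, ds in self.mapping.items() for d in ds]
        return XrefMap.from_pairs(src_ns, dst_ns, pairs)


def compute_overlap_set(
    phenotype_ontology: OntologyGraph,
    disease_ontology: OntologyGraph,
    phenotype_prefix: str = "HP",
) -> OverlapSet:
    """Compute the overlap set P with per-member evidence.

    Rule (i): the zero-stripped numeric suffix of the phenotype CURIE equals
    that of some disease CURIE. Rule (ii): the disease ontology carries an
    xref to the phenotype term.
    """
    overlap = OverlapSet()
    disease_by_num: dict[str, list[str]] = {}
    for did in disease_ontology.active_terms:
        num = _numeric_suffix(did)
        if num is not None:
            disease_by_num.setdefault(num, []).append(did)

    xref_targets: dict[str, set[str]] = {}
    for term, ns, fid in disease_ontology.xrefs:
        if ns == phenotype_prefix:
            xref_targets.setdefault(f"{ns}:{fid}", set()).add(term)

    for pid in phenotype_ontology.active_terms:
        diseases: set[str] = set()
        ev = []
        num = _numeric_suffix(pid)
        if num is not None and num in disease_by_num:
            diseases.update(disease_by_num[num])
            ev.append("same-numeric-id")
        if pid in xref_targets:
            diseases.update(xref_targets[pid])
            ev.append("xref-mapped")
        if diseases:
            overlap.members.add(pid)
            overlap.evidence[pid] = "both" if len(ev) == 2 else ev[0]
            overlap.mapping[pid] = tuple(sorted(diseases))
    return overlap


@dataclass
class RewireLog:
    """One row per affected input edge: converted or dropped, with reason."""

    rows: list[dict] = field(default_factory=list)

    def converted(self, edge: dict, new_relation: str, multiplicity: int = 1) -> None:
        self.rows.append(
            {
                "original_x": edge["x_id"],
                "original_relation": edge["relation"],
                "original_y": edge["y_id"],
                "action": "converted",
                "new_relation": new_relation,
                "reason": "",
                "multiplicity": multiplicity,
            }
        )

    def dropped(self, edge: dict, reason: str) -> None:
        self.rows.append(
            {
                "original_x": edge["x_id"],
                "original_relation": edge["relation"],
                "original_y": edge["y_id"],
                "action": "dropped",
                "new_relation": "",
                "reason": reason,
                "multiplicity": 0,
            }
        )

    @property
    def n_dropped(self) -> int:
        return sum(1 for r in self.rows if r["action"] == "dropped")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=[
                "original_x",
                "original_relation",
                "original_y",
                "action",
                "new_relation",
                "reason",
                "multiplicity",
            ],
        )


#: relations whose phenotype endpoint, when in P, drops the edge
_DROP_RELATIONS = {"disease_phenotype_positive", "disease_phenotype_negative", "drug_effect"}


def _disease_fields(pheno_row_side: dict, disease_id: str, disease_names: dict[str, str],
                    disease_source: str) -> dict:
    return {
        "id": disease_id,
        "type": "disease",
        "source": disease_source,
        "name": disease_names.get(disease_id, disease_id),
    }


def rewire_edges(
    tables: list[TriplesTable],
    overlap: OverlapSet,
    pheno_to_disease: XrefMap | None = None,
    disease_source: str = "MONDO",
    disease_names: dict[str, str] | None = None,
) -> tuple[list[TriplesTable], RewireLog]:
    """Apply the overlap rewiring rules to every table.

    A P member that maps to several disease identifiers duplicates the
    rewired edge for each target (deduplicated at assembly). Raises before
    touching any edge if a P member has no disease mapping.
    """
    mapping = (
        {p: pheno_to_disease.lookup(p) for p in overlap.members}
        if pheno_to_disease is not None
        else dict(overlap.mapping)
    )
    unmapped = [p for p in overlap.members if not mapping.get(p)]
    if unmapped:
        raise ValueError(
            f"{len(unmapped)} overlap member(s) without a disease mapping, "
            f"e.g. {sorted(unmapped)[:3]}"
        )
    disease_names = disease_names or {}
    log = RewireLog()
    out_tables = []
    for table in tables:
        out_rows: list[dict] = []
        for _, row in table.df.iterrows():
            edge = dict(row)
            x_in = edge["x_type"] == "effect/phenotype" and edge["x_id"] in overlap
            y_in = edge["y_type"] == "effect/phenotype" and edge["y_id"] in overlap
            if not (x_in or y_in):
                out_rows.append(edge)
                continue
            rel = edge["relation"]
            if rel == "phenotype_phenotype":
                if x_in and y_in:
                    targets_x = mapping[edge["x_id"]]
                    targets_y = mapping[edge["y_id"]]
                    for dx in targets_x:
                        for dy in targets_y:
                            new = dict(edge)
                            new["relation"] = "disease_disease"
                            for side, d in (("x", dx), ("y", dy)):
                                f = _disease_fields(new, d, disease_names, disease_source)
                                new[f"{side}_id"], new[f"{side}_type"] = f["id"], f["type"]
                                new[f"{side}_source"], new[f"{side}_name"] = f["source"], f["name"]
                            out_rows.append(new)
                    log.converted(edge, "disease_disease",
                                  multiplicity=len(targets_x) * len(targets_y))
                else:
                    pheno_side = "x" if x_in else "y"
                    targets = mapping[edge[f"{pheno_side}_id"]]
                    for d in targets:
                        new = dict(edge)
                        new["relation"] = "disease_phenotype_positive"
                        f = _disease_fields(new, d, disease_names, disease_source)
                        new[f"{pheno_side}_id"], new[f"{pheno_side}_type"] = f["id"], f["type"]
                        new[f"{pheno_side}_source"], new[f"{pheno_side}_name"] = f["source"], f["name"]
                        out_rows.append(new)
                    log.converted(edge, "disease_phenotype_positive", multiplicity=len(targets))
            elif rel == "phenotype_protein":
                pheno_side = "x" if x_in else "y"
                targets = mapping[edge[f"{pheno_side}_id"]]
                for d in targets:
                    new = dict(edge)
                    new["relation"] = "disease_protein"
                    f = _disease_fields(new, d, disease_names, disease_source)
                    new[f"{pheno_side}_id"], new[f"{pheno_side}_type"] = f["id"], f["type"]
                    new[f"{pheno_side}_source"], new[f"{pheno_side}_name"] = f["source"], f["name"]
                    out_rows.append(new)
                log.converted(edge, "disease_protein", multiplicity=len(targets))
            elif rel in _DROP_RELATIONS:
                log.dropped(edge, "phenotype endpoint in overlap set")
            else:
                # phenotype endpoint in P under a relation with no stated
                # rule (none exist among the 30); pass through unchanged
                out_rows.append(edge)
        out_tables.append(
            TriplesTable(pd.DataFrame(out_rows), resource_tag=table.resource_tag)
        )
    return out_tables, log
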