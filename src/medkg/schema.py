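"""Typed graph data model and the deposited node/edge file schema.

The knowledge graph is a heterogeneous network with 10 node types and 30
relation types. Undirected semantics are stored as two directed rows per
edge (the deposited-file convention); :meth:`KnowledgeGraph.undirected_view`
exposes one row per unordered pair.

Enum labels are stored verbatim in machine form (lowercase, e.g.
``gene/protein``, ``anatomy_protein_present``); ``DISPLAY_RELATION`` maps
them to human-readable display names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = [
    "NODE_TYPES",
    "RELATION_ENDPOINTS",
    "RELATION_TYPES",
    "DISPLAY_RELATION",
    "Node",
    "Edge",
    "KnowledgeGraph",
    "ValidationReport",
    "SchemaError",
    "write_kg",
    "read_kg",
    "validate_kg",
]

#: The 10 admissible node-type labels.
NODE_TYPES: frozenset[str] = frozenset(
    {
        "gene/protein",
        "drug",
        "effect/phenotype",
        "disease",
        "biological_process",
        "molecular_function",
        "cellular_component",
        "exposure",
        "pathway",
        "anatomy",
    }
)

#: The 30 admissible relation labels with their unordered endpoint-type pair.
#: Stored rows may carry the pair in either orientation because every
#: undirected edge is materialized in both directions.
RELATION_ENDPOINTS: dict[str, tuple[str, str]] = {
    "anatomy_protein_present": ("anatomy", "gene/protein"),
    "anatomy_protein_absent": ("anatomy", "gene/protein"),
    "drug_drug": ("drug", "drug"),
    "protein_protein": ("gene/protein", "gene/protein"),
    "disease_phenotype_positive": ("disease", "effect/phenotype"),
    "disease_phenotype_negative": ("disease", "effect/phenotype"),
    "bioprocess_protein": ("biological_process", "gene/protein"),
    "cellcomp_protein": ("cellular_component", "gene/protein"),
    "disease_protein": ("disease", "gene/protein"),
    "molfunc_protein": ("molecular_function", "gene/protein"),
    "drug_effect": ("drug", "effect/phenotype"),
    "bioprocess_bioprocess": ("biological_process", "biological_process"),
    "pathway_protein": ("pathway", "gene/protein"),
    "disease_disease": ("disease", "disease"),
    "contraindication": ("drug", "disease"),
    "indication": ("drug", "disease"),
    "off-label use": ("drug", "disease"),
    "drug_protein": ("drug", "gene/protein"),
    "phenotype_phenotype": ("effect/phenotype", "effect/phenotype"),
    "anatomy_anatomy": ("anatomy", "anatomy"),
    "molfunc_molfunc": ("molecular_function", "molecular_function"),
    "cellcomp_cellcomp": ("cellular_component", "cellular_component"),
    "phenotype_protein": ("effect/phenotype", "gene/protein"),
    "pathway_pathway": ("pathway", "pathway"),
    "exposure_disease": ("exposure", "disease"),
    "exposure_exposure": ("exposure", "exposure"),
    "exposure_bioprocess": ("exposure", "biological_process"),
    "exposure_protein": ("exposure", "gene/protein"),
    "exposure_molfunc": ("exposure", "molecular_function"),
    "exposure_cellcomp": ("exposure", "cellular_component"),
}

RELATION_TYPES: frozenset[str] = frozenset(RELATION_ENDPOINTS)

DISPLAY_RELATION: dict[str, str] = {
    "anatomy_protein_present": "expression present",
    "anatomy_protein_absent": "expression absent",
    "drug_drug": "synergistic interaction",
    "protein_protein": "ppi",
    "disease_phenotype_positive": "phenotype present",
    "disease_phenotype_negative": "phenotype absent",
    "bioprocess_protein": "interacts with",
    "cellcomp_protein": "interacts with",
    "disease_protein": "associated with",
    "molfunc_protein": "interacts with",
    "drug_effect": "side effect",
    "bioprocess_bioprocess": "parent-child",
    "pathway_protein": "interacts with",
    "disease_disease": "parent-child",
    "contraindication": "contraindication",
    "indication": "indication",
    "off-label use": "off-label use",
    "drug_protein": "target",
    "phenotype_phenotype": "parent-child",
    "anatomy_anatomy": "parent-child",
    "molfunc_molfunc": "parent-child",
    "cellcomp_cellcomp": "parent-child",
    "phenotype_protein": "associated with",
    "pathway_pathway": "parent-child",
    "exposure_disease": "linked to",
    "exposure_exposure": "parent-child",
    "exposure_bioprocess": "interacts with",
    "exposure_protein": "interacts with",
    "exposure_molfunc": "interacts with",
    "exposure_cellcomp": "interacts with",
}

NODE_COLUMNS = ["node_index", "node_id", "node_type", "node_name", "node_source"]
EDGE_COLUMNS = ["relation", "x_index", "y_index"]
EDGE_FILE_COLUMNS = [
    "relation",
    "display_relation",
    "x_index",
    "x_id",
    "x_type",
    "x_name",
    "x_source",
    "y_index",
    "y_id",
    "y_type",
    "y_name",
    "y_source",
]


class SchemaError(ValueError):
    """Raised when a file or in-memory graph violates the closed schema."""


@dataclass(frozen=True)
class Node:
    node_index: int
    node_id: str
    node_type: str
    node_name: str
    node_source: str


@dataclass(frozen=True)
class Edge:
    relation: str
    x_index: int
    y_index: int


@dataclass
class KnowledgeGraph:
    """Typed heterogeneous graph in the deposited-file schema.

    ``nodes`` has columns node_index, node_id, node_type, node_name,
    node_source; ``edges`` has relation, x_index, y_index (one row per
    stored direction).
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = pd.DataFrame(self.nodes, columns=NODE_COLUMNS).reset_index(drop=True)
        self.edges = pd.DataFrame(self.edges, columns=EDGE_COLUMNS).reset_index(drop=True)
        if len(self.nodes):
            self.nodes["node_index"] = self.nodes["node_index"].astype(int)
        if len(self.edges):
            self.edges["x_index"] = self.edges["x_index"].astype(int)
            self.edges["y_index"] = self.edges["y_index"].astype(int)

    # -- canonical ordering ------------------------------------------------
    def canonical(self) -> "KnowledgeGraph":
        """Return a copy with nodes sorted by node_index and edges sorted
        lexicographically by (relation, x_index, y_index)."""
        nodes = self.nodes.sort_values("node_index", kind="mergesort").reset_index(drop=True)
        edges = self.edges.sort_values(
            ["relation", "x_index", "y_index"], kind="mergesort"
        ).reset_index(drop=True)
        return KnowledgeGraph(nodes, edges, dict(self.provenance))

    def equals(self, other: "KnowledgeGraph") -> bool:
        a, b = self.canonical(), other.canonical()
        return a.nodes.equals(b.nodes) and a.edges.equals(b.edges)

    # -- views -------------------------------------------------------------
    def undirected_view(self) -> pd.DataFrame:
        """One row per unordered (relation, {x, y}) pair."""
        e = self.edges
        lo = e[["x_index", "y_index"]].min(axis=1)
        hi = e[["x_index", "y_index"]].max(axis=1)
        und = pd.DataFrame({"relation": e["relation"], "x_index": lo, "y_index": hi})
        return und.drop_duplicates().reset_index(drop=True)

    def to_networkx(self) -> nx.Graph:
        """Undirected simple graph over node indices, all relations pooled."""
        g: nx.Graph = nx.Graph()
        g.add_nodes_from(self.nodes["node_index"].tolist())
        g.add_edges_from(
            (int(x), int(y))
            for x, y in zip(self.edges["x_index"], self.edges["y_index"])
            if x != y
        )
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges_directed(self) -> int:
        return len(self.edges)


@dataclass
class ValidationReport:
    """Per-rule violation listing; empty in every field iff the graph is clean."""

    dangling_endpoints: list[int] = field(default_factory=list)
    self_loops: list[int] = field(default_factory=list)
    asymmetric_edges: list[int] = field(default_factory=list)
    duplicate_rows: list[int] = field(default_factory=list)
    endpoint_type_mismatches: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.dangling_endpoints
            or self.self_loops
            or self.asymmetric_edges
            or self.duplicate_rows
            or self.endpoint_type_mismatches
        )

    @property
    def n_violations(self) -> int:
        return (
            len(self.dangling_endpoints)
            + len(self.self_loops)
            + len(self.asymmetric_edges)
            + len(self.duplicate_rows)
            + len(self.endpoint_type_mismatches)
        )

    def summary(self) -> dict[str, int]:
        return {
            "dangling_endpoints": len(self.dangling_endpoints),
            "self_loops": len(self.self_loops),
            "asymmetric_edges": len(self.asymmetric_edges),
            "duplicate_rows": len(self.duplicate_rows),
            "endpoint_type_mismatches": len(self.endpoint_type_mismatches),
        }


def validate_kg(kg: KnowledgeGraph) -> ValidationReport:
    """Check the five structural rules; row positions of violations reported.

    Rules: (1) edge endpoints refer to existing nodes, (2) no self-loops,
    (3) for every (r, x, y) the reverse (r, y, x) exists, (4) no exact
    duplicate edge rows, (5) endpoint node types match the relation's
    declared pair (in either orientation).
    """
    report = ValidationReport()
    nodes, edges = kg.nodes, kg.edges
    known = set(nodes["node_index"].tolist())
    type_of = dict(zip(nodes["node_index"], nodes["node_type"]))

    seen: set[tuple] = set()
    rows = set(
        zip(edges["relation"], edges["x_index"], edges["y_index"])
    )
    for pos, (rel, x, y) in enumerate(
        zip(edges["relation"], edges["x_index"], edges["y_index"])
    ):
        key = (rel, x, y)
        if x not in known or y not in known:
            report.dangling_endpoints.append(pos)
            continue
        if x == y:
            report.self_loops.append(pos)
        if (rel, y, x) not in rows:
            report.asymmetric_edges.append(pos)
        if key in seen:
            report.duplicate_rows.append(pos)
        seen.add(key)
        pair = RELATION_ENDPOINTS.get(rel)
        if pair is None:
            report.endpoint_type_mismatches.append(pos)
        else:
            got = (type_of[x], type_of[y])
            if got != pair and got != pair[::-1]:
                report.endpoint_type_mismatches.append(pos)
    return report


def write_kg(
    kg: KnowledgeGraph,
    destination: str | Path,
    nodes_destination: str | Path | None = None,
    validate: bool = True,
) -> None:
    """Write the edge file (and optionally a node file) as UTF-8 CSV.

    Edge rows carry relation, display_relation, x_index plus denormalized
    x_/y_ node columns; a graph failing :func:`validate_kg` is rejected.
    """
    if validate:
        report = validate_kg(kg)
        if not report.ok:
            raise SchemaError(f"graph fails validation: {report.summary()}")
    kg = kg.canonical()
    nodes = kg.nodes.set_index("node_index")
    e = kg.edges
    out = pd.DataFrame(
        {
            "relation": e["relation"],
            "display_relation": e["relation"].map(lambda r: DISPLAY_RELATION.get(r, r)),
            "x_index": e["x_index"],
            "x_id": e["x_index"].map(nodes["node_id"]),
            "x_type": e["x_index"].map(nodes["node_type"]),
            "x_name": e["x_index"].map(nodes["node_name"]),
            "x_source": e["x_index"].map(nodes["node_source"]),
            "y_index": e["y_index"],
            "y_id": e["y_index"].map(nodes["node_id"]),
            "y_type": e["y_index"].map(nodes["node_type"]),
            "y_name": e["y_index"].map(nodes["node_name"]),
            "y_source": e["y_index"].map(nodes["node_source"]),
        },
        columns=EDGE_FILE_COLUMNS,
    )
    out.to_csv(destination, index=False, encoding="utf-8")
    if nodes_destination is not None:
        kg.nodes.to_csv(nodes_destination, index=False, encoding="utf-8")


def _check_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _check_enum(values: pd.Series, allowed: frozenset[str], what: str) -> None:
    bad = values[~values.isin(allowed)]
    if len(bad):
        row = int(bad.index[0])
        raise SchemaError(f"unknown {what} label {bad.iloc[0]!r} at row {row}")


def read_kg(
    source: str | Path, nodes_source: str | Path | None = None
) -> KnowledgeGraph:
    """Read a graph written by :func:`write_kg`.

    Unknown relation or node-type labels are rejected, never coerced. A
    separate node file restores nodes without any incident edge.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    _check_columns(df, EDGE_FILE_COLUMNS, "edge file")
    _check_enum(df["relation"], RELATION_TYPES, "relation")
    _check_enum(df["x_type"], NODE_TYPES, "node-type")
    _check_enum(df["y_type"], NODE_TYPES, "node-type")

    frames = []
    for side in ("x", "y"):
        frames.append(
            df[[f"{side}_index", f"{side}_id", f"{side}_type", f"{side}_name", f"{side}_source"]]
            .rename(
                columns={
                    f"{side}_index": "node_index",
                    f"{side}_id": "node_id",
                    f"{side}_type": "node_type",
                    f"{side}_name": "node_name",
                    f"{side}_source": "node_source",
                }
            )
        )
    nodes = pd.concat(frames, ignore_index=True)
    if nodes_source is not None:
        extra = pd.read_csv(nodes_source, dtype=str, keep_default_na=False)
        _check_columns(extra, NODE_COLUMNS, "node file")
        _check_enum(extra["node_type"], NODE_TYPES, "node-type")
        nodes = pd.concat([nodes, extra], ignore_index=True)
    if len(nodes):
        nodes["node_index"] = nodes["node_index"].astype(int)
    nodes = nodes.drop_duplicates(subset=["node_index"]).reset_index(drop=True)

    edges = df[["relation", "x_index", "y_index"]].copy()
    if len(edges):
        edges["x_index"] = edges["x_index"].astype(int)
        edges["y_index"] = edges["y_index"].astype(int)
    return KnowledgeGraph(nodes, edges).canonical()
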