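"""Graph assembly: merge harmonized tables, clean, extract the largest
connected component, and assign node indices.

The cleaning sequence is fixed: drop rows with missing endpoints, drop
duplicate edges, add reverse edges, drop duplicates again, remove
self-loops. Connectivity for the giant-component step ignores relation
types and direction. Node indices are assigned deterministically by
sorting unique nodes by (node_type, node_source, node_id).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .schema import KnowledgeGraph
from .tables import TRIPLES_COLUMNS, TriplesTable

__all__ = [
    "AssemblyReport",
    "merge_tables",
    "clean_edges",
    "largest_connected_component",
    "assign_node_indices",
]

_EDGE_KEY = ["relation", "x_id", "x_type", "x_source", "y_id", "y_type", "y_source"]
_NODE_KEY = ["node_type", "node_source", "node_id"]


@dataclass
class AssemblyReport:
    """Per-stage row accounting for one build.

    Stage counts reconcile exactly:
    rows_out = rows_in - nan_dropped - duplicates_dropped_pass1
               + reverse_edges_added - duplicates_dropped_pass2
               - self_loops_removed.
    """

    stages: dict[str, int] = field(default_factory=dict)
    lcc: dict[str, float] = field(default_factory=dict)

    def reconciles(self) -> bool:
        s = self.stages
        if not s:
            return True
        expected = (
            s["rows_in"]
            - s["nan_dropped"]
            - s["duplicates_dropped_pass1"]
            + s["reverse_edges_added"]
            - s["duplicates_dropped_pass2"]
            - s["self_loops_removed"]
        )
        return expected == s["rows_out"]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"stages": self.stages, "lcc": self.lcc}, indent=2),
            encoding="utf-8",
        )


def merge_tables(tables: list[TriplesTable]) -> TriplesTable:
    """Concatenate harmonized tables, preserving per-row resource tags.

    Raises when one (node_source, node_id) identifier appears with
    conflicting node types across tables.
    """
    frames = [t.df for t in tables if len(t)]
    if not frames:
        return TriplesTable.empty("merged")
    merged = pd.concat(frames, ignore_index=True)
    sides = pd.concat(
        [
            merged[["x_source", "x_id", "x_type"]].rename(
                columns={"x_source": "source", "x_id": "id", "x_type": "type"}
            ),
            merged[["y_source", "y_id", "y_type"]].rename(
                columns={"y_source": "source", "y_id": "id", "y_type": "type"}
            ),
        ],
        ignore_index=True,
    ).drop_duplicates()
    conflicts = sides.groupby(["source", "id"])["type"].nunique()
    bad = conflicts[conflicts > 1]
    if len(bad):
        ids = [f"{s}:{i}" for s, i in bad.index[:5]]
        raise ValueError(f"conflicting endpoint types for identifier(s): {ids}")
    return TriplesTable(merged, resource_tag="merged")


def clean_edges(table: TriplesTable) -> tuple[TriplesTable, AssemblyReport]:
    """Execute the cleaning sequence, in order: drop NaN, drop duplicates,
    add reverse edges, drop duplicates again, remove self-loops."""
    report = AssemblyReport()
    df = table.df.copy()
    report.stages["rows_in"] = len(df)

    bad = (
        df["x_id"].isin(["", "nan", "None"])
        | df["y_id"].isin(["", "nan", "None"])
        | df["relation"].isin(["", "nan", "None"])
        | df["x_id"].isna()
        | df["y_id"].isna()
    )
    report.stages["nan_dropped"] = int(bad.sum())
    df = df[~bad]

    before = len(df)
    df = df.drop_duplicates(subset=_EDGE_KEY, keep="first")
    report.stages["duplicates_dropped_pass1"] = before - len(df)

    swap = {
        "x_id": "y_id", "y_id": "x_id",
        "x_type": "y_type", "y_type": "x_type",
        "x_source": "y_source", "y_source": "x_source",
        "x_name": "y_name", "y_name": "x_name",
    }
    reverse = df.rename(columns=swap)[df.columns]
    report.stages["reverse_edges_added"] = len(reverse)
    df = pd.concat([df, reverse], ignore_index=True)

    before = len(df)
    df = df.drop_duplicates(subset=_EDGE_KEY, keep="first")
    report.stages["duplicates_dropped_pass2"] = before - len(df)

    self_loop = (
        (df["x_id"] == df["y_id"])
        & (df["x_type"] == df["y_type"])
        & (df["x_source"] == df["y_source"])
    )
    report.stages["self_loops_removed"] = int(self_loop.sum())
    df = df[~self_loop].reset_index(drop=True)
    report.stages["rows_out"] = len(df)
    return TriplesTable(df, resource_tag=table.resource_tag or "cleaned"), report


def _node_key_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Unique (type, source, id, name) across both endpoints, names resolved
    deterministically (shortest, then lexicographic)."""
    sides = pd.concat(
        [
            df[["x_type", "x_source", "x_id", "x_name"]].rename(
                columns={
                    "x_type": "node_type",
                    "x_source": "node_source",
                    "x_id": "node_id",
                    "x_name": "node_name",
                }
            ),
            df[["y_type", "y_source", "y_id", "y_name"]].rename(
                columns={
                    "y_type": "node_type",
                    "y_source": "node_source",
                    "y_id": "node_id",
                    "y_name": "node_name",
                }
            ),
        ],
        ignore_index=True,
    ).drop_duplicates()
    sides["_rank"] = sides["node_name"].map(lambda n: (len(n), n))
    sides = sides.sort_values(_NODE_KEY + ["_rank"], kind="mergesort")
    return sides.drop_duplicates(subset=_NODE_KEY, keep="first").drop(columns="_rank")


def largest_connected_component(
    table: TriplesTable,
) -> tuple[TriplesTable, AssemblyReport]:
    """Edge-induced subtable on the largest component of the undirected
    graph over all relation types.

    Component ties (equal node counts) break toward the larger edge count,
    then the smallest canonical node identifier. The report carries the
    component count and the fraction of edge rows retained.
    """
    report = AssemblyReport()
    df = table.df
    if not len(df):
        report.lcc = {
            "component_count": 0,
            "nodes_retained": 0,
            "edges_retained": 0,
            "fraction_edges_retained": 1.0,
        }
        return TriplesTable.empty(table.resource_tag), report

    xk = list(zip(df["x_type"], df["x_source"], df["x_id"]))
    yk = list(zip(df["y_type"], df["y_source"], df["y_id"]))
    g: nx.Graph = nx.Graph()
    g.add_edges_from(zip(xk, yk))
    components = list(nx.connected_components(g))

    def edge_count(comp: set) -> int:
        return sum(1 for a, b in zip(xk, yk) if a in comp)

    # tie-break: node count, then edge count, then smallest canonical node key
    best = min(components, key=lambda c: (-len(c), -edge_count(c), min(c)))
    keep = pd.Series([a in best for a in xk], index=df.index)
    out = df[keep].reset_index(drop=True)
    report.lcc = {
        "component_count": len(components),
        "nodes_retained": len(best),
        "edges_retained": len(out),
        "fraction_edges_retained": len(out) / len(df),
    }
    return TriplesTable(out, resource_tag=table.resource_tag), report


def assign_node_indices(
    table: TriplesTable, provenance: dict | None = None
) -> KnowledgeGraph:
    """Number unique nodes consecutively from 0 in (node_type, node_source,
    node_id) sort order and re-express edges over indices. Deterministic and
    independent of input row order."""
    df = table.df
    nodes = _node_key_frame(df).reset_index(drop=True)
    nodes.insert(0, "node_index", range(len(nodes)))
    lookup = {
        (t, s, i): idx
        for idx, t, s, i in zip(
            nodes["node_index"], nodes["node_type"], nodes["node_source"], nodes["node_id"]
        )
    }
    edges = pd.DataFrame(
        {
            "relation": df["relation"],
            "x_index": [
                lookup[k] for k in zip(df["x_type"], df["x_source"], df["x_id"])
            ],
            "y_index": [
                lookup[k] for k in zip(df["y_type"], df["y_source"], df["y_id"])
            ],
        }
    )
    nodes = nodes[["node_index", "node_id", "node_type", "node_name", "node_source"]]
    return KnowledgeGraph(nodes, edges, provenance or {}).canonical()
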