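"""Assembly: merge, the fixed cleaning sequence, giant-component
extraction, and deterministic index assignment."""

import numpy as np
import pandas as pd
import pytest

from medkg.assembly import (
    assign_node_indices,
    clean_edges,
    largest_connected_component,
    merge_tables,
)
from medkg.tables import TriplesTable

from conftest import UnionFind


def _ppi(a, b):
    return {
        "relation": "protein_protein",
        "x_id": a, "x_type": "gene/protein", "x_source": "NCBI",
        "y_id": b, "y_type": "gene/protein", "y_source": "NCBI",
    }


def _table(rows, tag="t"):
    return TriplesTable(pd.DataFrame(rows), resource_tag=tag, check=False)


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------


def test_merge_concatenates_and_keeps_provenance():
    a = _table([_ppi("g1", "g2")] * 4, "a")
    b = _table([_ppi("g3", "g4")] * 6, "b")
    merged = merge_tables([a, b])
    assert len(merged) == 10
    assert set(merged.df["resource"]) == {"a", "b"}


def test_merge_keeps_cross_table_duplicates_for_clean_stage():
    a = _table([_ppi("g1", "g2")], "a")
    b = _table([_ppi("g1", "g2")], "b")
    assert len(merge_tables([a, b])) == 2


def test_merge_rejects_conflicting_endpoint_types():
    a = _table([_ppi("g1", "g2")], "a")
    conflict = _table(
        [{
            "relation": "drug_protein",
            "x_id": "g1", "x_type": "drug", "x_source": "NCBI",
            "y_id": "g2", "y_type": "gene/protein", "y_source": "NCBI",
        }],
        "b",
    )
    with pytest.raises(ValueError, match="NCBI:g1"):
        merge_tables([a, conflict])


# ---------------------------------------------------------------------------
# cleaning sequence
# ---------------------------------------------------------------------------


def test_clean_adds_reverse_edges():
    out, report = clean_edges(_table([_ppi("a", "b")]))
    pairs = sorted(zip(out.df["x_id"], out.df["y_id"]))
    assert pairs == [("a", "b"), ("b", "a")]
    assert report.reconciles()


def test_clean_does_not_double_symmetric_input():
    out, report = clean_edges(_table([_ppi("a", "b"), _ppi("b", "a")]))
    assert len(out) == 2
    assert report.stages["duplicates_dropped_pass2"] == 2
    assert report.reconciles()


def test_clean_removes_self_loops_and_nans():
    rows = [_ppi("a", "a"), _ppi("a", "b"), _ppi("", "c"), _ppi("d", "nan")]
    out, report = clean_edges(_table(rows))
    assert report.stages["nan_dropped"] == 2
    # the loop's reverse is itself, so the second dedup pass leaves one row
    assert report.stages["self_loops_removed"] == 1
    assert sorted(zip(out.df["x_id"], out.df["y_id"])) == [("a", "b"), ("b", "a")]
    assert report.reconciles()


def test_clean_drops_exact_duplicates_first_pass():
    out, report = clean_edges(_table([_ppi("a", "b"), _ppi("a", "b")]))
    assert report.stages["duplicates_dropped_pass1"] == 1
    assert len(out) == 2


def test_clean_is_idempotent():
    rng = np.random.default_rng(8)
    rows = [_ppi(f"g{int(rng.integers(0, 10))}", f"g{int(rng.integers(0, 10))}") for _ in range(60)]
    once, _ = clean_edges(_table(rows))
    twice, report = clean_edges(once)
    pd.testing.assert_frame_equal(once.canonical(), twice.canonical())
    assert report.stages["nan_dropped"] == 0
    assert report.stages["self_loops_removed"] == 0
    assert report.stages["duplicates_dropped_pass2"] == len(once)  # reverses all existed


# ---------------------------------------------------------------------------
# largest connected component
# ---------------------------------------------------------------------------


def test_lcc_connected_graph_is_identity():
    rows = [_ppi("a", "b"), _ppi("b", "c")]
    cleaned, _ = clean_edges(_table(rows))
    out, report = largest_connected_component(cleaned)
    assert len(out) == len(cleaned)
    assert report.lcc["fraction_edges_retained"] == 1.0
    assert report.lcc["component_count"] == 1


def test_lcc_picks_five_node_component():
    # components of 5 and 3 nodes
    rows = [_ppi("a", "b"), _ppi("b", "c"), _ppi("c", "d"), _ppi("d", "e"),
            _ppi("x", "y"), _ppi("y", "z")]
    cleaned, _ = clean_edges(_table(rows))
    out, report = largest_connected_component(cleaned)
    assert set(out.df["x_id"]) == {"a", "b", "c", "d", "e"}
    assert report.lcc["nodes_retained"] == 5
    assert report.lcc["component_count"] == 2


def test_lcc_tie_breaks_on_edges_then_smallest_id():
    # two 3-node components; the second has more edges (a triangle)
    rows = [_ppi("x1", "x2"), _ppi("x2", "x3"),
            _ppi("b1", "b2"), _ppi("b2", "b3"), _ppi("b1", "b3")]
    cleaned, _ = clean_edges(_table(rows))
    out, _ = largest_connected_component(cleaned)
    assert set(out.df["x_id"]) == {"b1", "b2", "b3"}

    # equal node and edge counts: smallest canonical node id wins
    rows = [_ppi("m1", "m2"), _ppi("a1", "a2")]
    cleaned, _ = clean_edges(_table(rows))
    out, _ = largest_connected_component(cleaned)
    assert set(out.df["x_id"]) == {"a1", "a2"}


def test_lcc_empty_input():
    out, report = largest_connected_component(TriplesTable.empty())
    assert len(out) == 0
    assert report.lcc["fraction_edges_retained"] == 1.0


def test_lcc_agrees_with_union_find_oracle():
    rng = np.random.default_rng(31)
    for _ in range(20):
        n = int(rng.integers(10, 200))
        rows = [
            _ppi(f"g{int(rng.integers(0, n))}", f"g{int(rng.integers(0, n))}")
            for _ in range(int(rng.integers(n // 2, 2 * n)))
        ]
        cleaned, _ = clean_edges(_table(rows))
        if not len(cleaned):
            continue
        out, _ = largest_connected_component(cleaned)

        uf = UnionFind(set(cleaned.df["x_id"]) | set(cleaned.df["y_id"]))
        for a, b in zip(cleaned.df["x_id"], cleaned.df["y_id"]):
            uf.union(a, b)
        comps = uf.components()
        got = set(out.df["x_id"]) | set(out.df["y_id"])
        # the returned subgraph is exactly one oracle component, of maximal size
        assert got in comps
        assert len(got) == len(comps[0])


def test_lcc_is_maximal_by_exhaustive_enumeration():
    rng = np.random.default_rng(17)
    import networkx as nx

    for _ in range(10):
        n = int(rng.integers(8, 40))
        rows = [
            _ppi(f"g{int(rng.integers(0, n))}", f"g{int(rng.integers(0, n))}")
            for _ in range(int(rng.integers(4, n)))
        ]
        cleaned, _ = clean_edges(_table(rows))
        if not len(cleaned):
            continue
        out, report = largest_connected_component(cleaned)
        g = nx.Graph(list(zip(cleaned.df["x_id"], cleaned.df["y_id"])))
        best = max(len(c) for c in nx.connected_components(g))
        assert report.lcc["nodes_retained"] == best


# ---------------------------------------------------------------------------
# index assignment
# ---------------------------------------------------------------------------


def _mixed_rows():
    return [
        {
            "relation": "disease_protein",
            "x_id": "M:2", "x_type": "disease", "x_source": "MONDO", "x_name": "m2",
            "y_id": "g1", "y_type": "gene/protein", "y_source": "NCBI", "y_name": "g1",
        },
        {
            "relation": "drug_protein",
            "x_id": "DB1", "x_type": "drug", "x_source": "DrugBank", "x_name": "d1",
            "y_id": "g1", "y_type": "gene/protein", "y_source": "NCBI", "y_name": "g1",
        },
    ]


def test_indices_follow_type_source_id_sort_order():
    cleaned, _ = clean_edges(_table(_mixed_rows()))
    kg = assign_node_indices(cleaned)
    nodes = kg.nodes
    assert list(nodes["node_index"]) == [0, 1, 2]
    keys = list(zip(nodes["node_type"], nodes["node_source"], nodes["node_id"]))
    assert keys == sorted(keys)


def test_index_assignment_is_order_independent_and_deterministic():
    cleaned, _ = clean_edges(_table(_mixed_rows()))
    kg = assign_node_indices(cleaned)
    permuted = TriplesTable(
        cleaned.df.sample(frac=1.0, random_state=3).reset_index(drop=True),
        resource_tag="p",
    )
    for _ in range(5):
        again = assign_node_indices(permuted)
        assert again.equals(kg)
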