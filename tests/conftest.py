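"""Shared fixtures: one session-scoped mock resource bundle, its build
result, the proximity testbed, and random-graph helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from medkg.fixtures import (
    FixtureSpec,
    ProximityTestbed,
    make_fixture_bundle,
    make_proximity_testbed,
)
from medkg.pipeline import build_kg
from medkg.schema import (
    NODE_TYPES,
    RELATION_ENDPOINTS,
    KnowledgeGraph,
)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    return make_fixture_bundle(FixtureSpec(rng_seed=7), tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def build_result(fixture_bundle):
    return build_kg(fixture_bundle.manifest_path)


@pytest.fixture(scope="session")
def proximity_testbed() -> ProximityTestbed:
    return make_proximity_testbed(n_chain_diseases=100, n_background=1100)


def random_kg(rng: np.random.Generator, max_nodes: int = 60) -> KnowledgeGraph:
    """A random valid graph: typed nodes, symmetric directed rows, no
    self-loops, no duplicates."""
    n = int(rng.integers(4, max_nodes + 1))
    types = sorted(NODE_TYPES)
    node_types = [types[int(rng.integers(0, len(types)))] for _ in range(n)]
    nodes = pd.DataFrame(
        {
            "node_index": range(n),
            "node_id": [f"ID:{i:05d}" for i in range(n)],
            "node_type": node_types,
            "node_name": [f"node {i}" for i in range(n)],
            "node_source": ["mock"] * n,
        }
    )
    by_type: dict[str, list[int]] = {}
    for i, t in enumerate(node_types):
        by_type.setdefault(t, []).append(i)
    relations = sorted(RELATION_ENDPOINTS)
    seen: set[tuple] = set()
    rows = []
    for _ in range(int(rng.integers(5, 4 * n))):
        rel = relations[int(rng.integers(0, len(relations)))]
        ta, tb = RELATION_ENDPOINTS[rel]
        if not by_type.get(ta) or not by_type.get(tb):
            continue
        x = by_type[ta][int(rng.integers(0, len(by_type[ta])))]
        y = by_type[tb][int(rng.integers(0, len(by_type[tb])))]
        if x == y or (rel, x, y) in seen:
            continue
        seen.add((rel, x, y))
        seen.add((rel, y, x))
        rows.append({"relation": rel, "x_index": x, "y_index": y})
        rows.append({"relation": rel, "x_index": y, "y_index": x})
    edges = pd.DataFrame(rows, columns=["relation", "x_index", "y_index"])
    return KnowledgeGraph(nodes, edges).canonical()


class UnionFind:
    """Independent union-find oracle for component membership."""

    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        comps = {}
        for i in self.parent:
            comps.setdefault(self.find(i), set()).add(i)
        return sorted(comps.values(), key=lambda c: (-len(c), sorted(c)[0]))
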