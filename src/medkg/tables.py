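"""Harmonized per-resource relation tables and identifier cross-reference maps.

A :class:`TriplesTable` holds relation records in source-ontology identifier
space, one row per directed statement as extracted from a resource (symmetry
is restored later, at assembly). An :class:`XrefMap` is a many-to-many
identifier mapping between two namespaces with provenance per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .schema import NODE_TYPES, RELATION_ENDPOINTS

__all__ = ["TRIPLES_COLUMNS", "TriplesTable", "DropLog", "XrefMap"]

TRIPLES_COLUMNS = [
    "relation",
    "x_id",
    "x_type",
    "x_source",
    "x_name",
    "y_id",
    "y_type",
    "y_source",
    "y_name",
    "resource",
]


class DropLog:
    """Audit log of rows removed (or expanded) by an adapter.

    Conservation contract: |input rows| = |output rows before expansion|
    + |dropped rows|; expansions are logged with their multiplicity.
    """

    def __init__(self) -> None:
        self._rows: list[dict] = []

    def drop(self, reason: str, **info) -> None:
        self._rows.append({"action": "drop", "reason": reason, **info})

    def expand(self, multiplicity: int, **info) -> None:
        self._rows.append(
            {"action": "expand", "reason": "one-to-many", "multiplicity": multiplicity, **info}
        )

    @property
    def n_dropped(self) -> int:
        return sum(1 for r in self._rows if r["action"] == "drop")

    @property
    def n_expansions(self) -> int:
        return sum(
            r["multiplicity"] - 1 for r in self._rows if r["action"] == "expand"
        )

    def __len__(self) -> int:
        return len(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows)

    def extend(self, other: "DropLog") -> None:
        self._rows.extend(other._rows)


@dataclass
class TriplesTable:
    """Relation records from one resource, pre-assembly.

    Rows never carry an empty identifier, and every row's endpoint types are
    consistent with the relation's declared endpoint pair (checked on
    construction unless ``check=False``).
    """

    df: pd.DataFrame
    resource_tag: str = ""

    def __init__(self, df: pd.DataFrame | Iterable[dict], resource_tag: str = "", check: bool = True):
        df = pd.DataFrame(df)
        for col in TRIPLES_COLUMNS:
            if col not in df.columns:
                if col == "x_name":
                    df[col] = df["x_id"] if "x_id" in df.columns else ""
                elif col == "y_name":
                    df[col] = df["y_id"] if "y_id" in df.columns else ""
                elif col == "resource":
                    df[col] = resource_tag
                else:
                    df[col] = pd.Series(dtype=str)
        self.df = df[TRIPLES_COLUMNS].reset_index(drop=True).astype(str)
        self.resource_tag = resource_tag
        if check:
            self._check()

    def _check(self) -> None:
        df = self.df
        if not len(df):
            return
        empty = (
            df["x_id"].isin(["", "nan", "None"]) | df["y_id"].isin(["", "nan", "None"])
        )
        if empty.any():
            raise ValueError(
                f"{int(empty.sum())} row(s) with empty identifier in table "
                f"{self.resource_tag!r} (first at position {int(empty.idxmax())})"
            )
        bad_rel = ~df["relation"].isin(RELATION_ENDPOINTS)
        if bad_rel.any():
            raise ValueError(f"unknown relation {df.loc[bad_rel.idxmax(), 'relation']!r}")
        bad_type = ~(df["x_type"].isin(NODE_TYPES) & df["y_type"].isin(NODE_TYPES))
        if bad_type.any():
            raise ValueError("unknown node type in table " + repr(self.resource_tag))
        for rel, sub in df.groupby("relation"):
            a, b = RELATION_ENDPOINTS[rel]
            ok = ((sub["x_type"] == a) & (sub["y_type"] == b)) | (
                (sub["x_type"] == b) & (sub["y_type"] == a)
            )
            if not ok.all():
                raise ValueError(
                    f"endpoint types inconsistent with relation {rel!r} in "
                    f"table {self.resource_tag!r}"
                )

    def __len__(self) -> int:
        return len(self.df)

    def canonical(self) -> pd.DataFrame:
        return (
            self.df.sort_values(TRIPLES_COLUMNS, kind="mergesort").reset_index(drop=True)
        )

    @classmethod
    def empty(cls, resource_tag: str = "") -> "TriplesTable":
        return cls(pd.DataFrame(columns=TRIPLES_COLUMNS), resource_tag=resource_tag)


@dataclass
class XrefMap:
    """Many-to-many identifier mapping between two namespaces.

    ``provenance`` records, per (src, dst) pair, whether the mapping came
    from a direct xref or through an intermediate ontology (``via:<ont>``).
    ``dst_names`` optionally carries display names for mapped identifiers.
    """

    src_ns: str
    dst_ns: str
    pairs: dict[str, tuple[str, ...]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)
    dst_names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls,
        src_ns: str,
        dst_ns: str,
        pairs: Iterable[tuple[str, str]],
        provenance: str = "direct",
        dst_names: Mapping[str, str] | None = None,
    ) -> "XrefMap":
        m = cls(src_ns=src_ns, dst_ns=dst_ns, dst_names=dict(dst_names or {}))
        grouped: dict[str, set[str]] = {}
        for s, d in pairs:
            grouped.setdefault(str(s), set()).add(str(d))
            m.provenance[(str(s), str(d))] = provenance
        m.pairs = {s: tuple(sorted(ds)) for s, ds in grouped.items()}
        return m

    def lookup(self, identifier: str) -> tuple[str, ...]:
        return self.pairs.get(str(identifier), ())

    def __contains__(self, identifier: str) -> bool:
        return str(identifier) in self.pairs

    def __len__(self) -> int:
        return sum(len(v) for v in self.pairs.values())

    def compose(self, other: "XrefMap") -> "XrefMap":
        """Chain two maps: self (A->B) then other (B->C) gives A->C."""
        if self.dst_ns != other.src_ns:
            raise ValueError(
                f"cannot compose {self.src_ns}->{self.dst_ns} with "
                f"{other.src_ns}->{other.dst_ns}"
            )
        out = XrefMap(src_ns=self.src_ns, dst_ns=other.dst_ns, dst_names=dict(other.dst_names))
        grouped: dict[str, set[str]] = {}
        for s, mids in self.pairs.items():
            targets: set[str] = set()
            for mid in mids:
                targets.update(other.lookup(mid))
            if targets:
                grouped[s] = targets
                for t in targets:
                    out.provenance[(s, t)] = f"via:{self.dst_ns}"
        out.pairs = {s: tuple(sorted(ds)) for s, ds in grouped.items()}
        return out

    def invert(self) -> "XrefMap":
        out = XrefMap(src_ns=self.dst_ns, dst_ns=self.src_ns)
        grouped: dict[str, set[str]] = {}
        for s, ds in self.pairs.items():
            for d in ds:
                grouped.setdefault(d, set()).add(s)
                out.provenance[(d, s)] = self.provenance.get((s, d), "direct")
        out.pairs = {s: tuple(sorted(v)) for s, v in grouped.items()}
        return out
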