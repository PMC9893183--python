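"""Two-stage disease entity grouping.

Disease vocabularies contain many repetitive subtype records ("autism,
susceptibility to, 1", "mucopolysaccharidosis type II", ...) with little
standalone clinical meaning. Grouping collapses them into one node per
disease family in two stages:

1. **String matching.** A disease name whose normalized form ends with a
   number, a roman numeral, a short alphanumeric qualifier, or has "type"
   as its second-last word seeds a candidate group; its *base phrase* (the
   name minus the qualifying ending) collects every name that begins with
   the base phrase, plus every name whose word bag equals the base-phrase
   word bag regardless of word order (the words "type" and "(disease)" and
   qualifier tokens are ignored in the bag comparison). The transitive
   closure of these matches forms a partition.
2. **Embedding refinement.** Cosine similarity between group-representative
   name embeddings proposes further merges at a cutoff (default 0.98);
   proposals are written to a review file so that a human can approve,
   reject, or rename them before they are applied. Without review, all
   proposals merge.

The embedder is a pluggable contract. The bundled default is a
deterministic character-trigram hashing embedder: no model downloads,
byte-reproducible, and adequate for near-duplicate name detection. A
pretrained clinical language model can be plugged in through the same
interface.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol

import numpy as np
import pandas as pd

from .tables import DropLog, TriplesTable

__all__ = [
    "GroupingConfig",
    "DiseaseGrouping",
    "NameEmbedder",
    "TrigramEmbedder",
    "normalize_name",
    "extract_base_phrase",
    "string_match_groups",
    "embedding_refine",
    "apply_grouping",
    "group_diseases",
    "read_review_file",
    "REVIEW_COLUMNS",
]


@dataclass
class GroupingConfig:
    """Tunable knobs of the grouping pipeline.

    similarity_cutoff
        Cosine-similarity threshold for a merge proposal, in [-1, 1].
    ignored_words
        Words ignored during bag-of-words comparison. Entries containing
        punctuation (e.g. "(disease)") are removed from the raw name before
        normalization; bare words are dropped from the token bags.
    max_qualifier_len
        Maximum length of an alphanumeric qualifier token (must contain a
        digit unless it is a single letter).
    require_review
        When true, only proposals marked ``approve`` in the review file
        are merged.
    """

    similarity_cutoff: float = 0.98
    ignored_words: frozenset[str] = frozenset({"type", "(disease)"})
    max_qualifier_len: int = 2
    require_review: bool = False

    def __post_init__(self) -> None:
        if not -1.0 <= self.similarity_cutoff <= 1.0:
            raise ValueError("similarity_cutoff must be in [-1, 1]")


class NameEmbedder(Protocol):
    """Deterministic fixed-length embedding of a name string."""

    model_tag: str

    def embed(self, name: str) -> np.ndarray: ...


class TrigramEmbedder:
    """Character-trigram hashing embedder.

    Trigrams of the padded, normalized name are hashed (stable MD5-based
    hash, independent of interpreter seeding) into a fixed-dimension count
    vector and L2-normalized, so similarity(s, s) == 1 and near-duplicate
    strings score near 1.
    """

    def __init__(self, dim: int = 256):
        self.dim = dim
        self.model_tag = f"char-trigram-{dim}"
        self._cache: dict[str, np.ndarray] = {}

    def _bucket(self, trigram: str) -> int:
        digest = hashlib.md5(trigram.encode("utf-8")).digest()
        return int.from_bytes(digest[:4], "little") % self.dim

    def embed(self, name: str) -> np.ndarray:
        cached = self._cache.get(name)
        if cached is not None:
            return cached
        padded = f"  {normalize_name(name)} "
        vec = np.zeros(self.dim)
        for i in range(len(padded) - 2):
            vec[self._bucket(padded[i : i + 3])] += 1.0
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        self._cache[name] = vec
        return vec


# ---------------------------------------------------------------------------
# Name normalization and the suffix rule
# ---------------------------------------------------------------------------

_PUNCT_RE = re.compile(r"[^0-9a-z]+")

#: roman numerals I..XX, the range used for disease subtype numbering
_ROMANS = frozenset(
    "i ii iii iv v vi vii viii ix x xi xii xiii xiv xv xvi xvii xviii xix xx".split()
)


def normalize_name(name: str, ignored_phrases: Iterable[str] = ("(disease)",)) -> str:
    """Lowercase, strip punctuation, collapse whitespace.

    Ignored phrases that contain punctuation are removed verbatim before
    punctuation stripping so they do not leave stray tokens behind.
    """
    s = name.lower()
    for phrase in ignored_phrases:
        if any(not (c.isalnum() or c.isspace()) for c in phrase):
            s = s.replace(phrase.lower(), " ")
    s = _PUNCT_RE.sub(" ", s)
    return " ".join(s.split())


def _is_qualifier(token: str, max_len: int = 2) -> bool:
    """Subtype qualifier: a number, a roman numeral (I-XX), a short
    alphanumeric token containing a digit, or a single letter."""
    if token.isdigit():
        return True
    if token in _ROMANS:
        return True
    if len(token) == 1:
        return True
    return len(token) <= max_len and any(c.isdigit() for c in token)


def extract_base_phrase(name: str, cfg: GroupingConfig | None = None) -> str | None:
    """Base phrase of a subtype-qualified disease name, or None.

    Returns the normalized name with its qualifying ending dropped when the
    final token is a number, roman numeral, or short alphanumeric
    qualifier, or when "type" is the second-last word.
    """
    cfg = cfg or GroupingConfig()
    ignored_phrases = [w for w in cfg.ignored_words if not w.isalnum()]
    tokens = normalize_name(name, ignored_phrases).split()
    if len(tokens) < 2:
        return None
    if _is_qualifier(tokens[-1], cfg.max_qualifier_len) or tokens[-2] == "type":
        return " ".join(tokens[:-1])
    return None


def _bag(tokens: Iterable[str], cfg: GroupingConfig) -> frozenset[str]:
    """Token bag for order-insensitive comparison: ignored words and
    qualifier tokens removed."""
    bare_ignored = {w for w in cfg.ignored_words if w.isalnum()}
    return frozenset(
        t for t in tokens
        if t not in bare_ignored and not _is_qualifier(t, cfg.max_qualifier_len)
    )


# ---------------------------------------------------------------------------
# Partition container
# ---------------------------------------------------------------------------


@dataclass
class DiseaseGrouping:
    """Partition of disease identifiers into grouped nodes.

    ``partition`` maps every input disease id to its group id; singleton
    groups keep the original disease name as the group name. ``evidence``
    records one entry per merge decision (rule, similarity, review status).
    """

    partition: dict[str, str] = field(default_factory=dict)
    group_names: dict[str, str] = field(default_factory=dict)
    evidence: list[dict] = field(default_factory=list)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for did, gid in self.partition.items():
            out.setdefault(gid, []).append(did)
        return {g: sorted(members) for g, members in out.items()}

    @property
    def n_groups(self) -> int:
        return len(set(self.partition.values()))

    def is_identity(self) -> bool:
        return self.n_groups == len(self.partition)

    def labels(self, order: Iterable[str]) -> list[str]:
        return [self.partition[d] for d in order]


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, a: str) -> str:
        root = a
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[a] != root:
            self.parent[a], a = root, self.parent[a]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


# ---------------------------------------------------------------------------
# Stage 1: string matching
# ---------------------------------------------------------------------------


def _prefix_match(norm: str, base: str) -> bool:
    return norm == base or norm.startswith(base + " ")


def string_match_groups(
    names: Mapping[str, str], cfg: GroupingConfig | None = None
) -> DiseaseGrouping:
    """Stage-1 partition by suffix-driven string matching.

    Every subtype-qualified name seeds a group via its base phrase; the
    transitive closure of initial-phrase and bag-of-words matches yields
    the partition. Names sharing no normalized tokens are never merged.
    """
    cfg = cfg or GroupingConfig()
    ignored_phrases = [w for w in cfg.ignored_words if not w.isalnum()]
    ids = sorted(names)
    norm = {d: normalize_name(names[d], ignored_phrases) for d in ids}
    base = {d: extract_base_phrase(names[d], cfg) for d in ids}
    stripped = {d: (base[d] if base[d] is not None else norm[d]) for d in ids}
    bags = {d: _bag(stripped[d].split(), cfg) for d in ids}

    uf = _UnionFind(ids)
    evidence: list[dict] = []
    # index names by first token to keep candidate scans near-linear
    by_first_token: dict[str, list[str]] = {}
    for d in ids:
        toks = norm[d].split()
        if toks:
            by_first_token.setdefault(toks[0], []).append(d)
    by_bag: dict[frozenset[str], list[str]] = {}
    for d in ids:
        if bags[d]:
            by_bag.setdefault(bags[d], []).append(d)

    for seed in ids:
        b = base[seed]
        if b is None:
            continue
        first = b.split()[0]
        for cand in by_first_token.get(first, ()):
            if cand != seed and _prefix_match(norm[cand], b):
                uf.union(seed, cand)
                evidence.append({"rule": "initial-phrase", "a": seed, "b": cand})
        seed_bag = _bag(b.split(), cfg)
        if seed_bag:
            for cand in by_bag.get(seed_bag, ()):
                if cand != seed and uf.find(cand) != uf.find(seed):
                    uf.union(seed, cand)
                    evidence.append({"rule": "bag-of-words", "a": seed, "b": cand})

    grouping = DiseaseGrouping(evidence=evidence)
    members_by_root: dict[str, list[str]] = {}
    for d in ids:
        members_by_root.setdefault(uf.find(d), []).append(d)
    for root, members in members_by_root.items():
        if len(members) == 1:
            gid = members[0]
            grouping.partition[gid] = gid
            grouping.group_names[gid] = names[gid]
        else:
            gid = min(members)
            display = _group_display_name(members, names, base)
            for m in members:
                grouping.partition[m] = gid
            grouping.group_names[gid] = display
    return grouping


def _group_display_name(
    members: list[str], names: Mapping[str, str], base: Mapping[str, str | None]
) -> str:
    """Most common base phrase among members; shortest member name as
    fallback. Deterministic ties by lexicographic order."""
    phrases = [base[m] for m in members if base[m]]
    if phrases:
        counts: dict[str, int] = {}
        for p in phrases:
            counts[p] = counts.get(p, 0) + 1
        return min(counts, key=lambda p: (-counts[p], p))
    return min((names[m] for m in members), key=lambda n: (len(n), n))


# ---------------------------------------------------------------------------
# Stage 2: embedding refinement
# ---------------------------------------------------------------------------

REVIEW_COLUMNS = [
    "proposal_id",
    "group_a",
    "group_b",
    "representative_a",
    "representative_b",
    "similarity",
    "decision",
    "assigned_name",
]


def read_review_file(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REVIEW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"review file missing column(s): {', '.join(missing)}")
    df["similarity"] = df["similarity"].astype(float)
    return df


def embedding_refine(
    grouping: DiseaseGrouping,
    embedder: NameEmbedder | None = None,
    cfg: GroupingConfig | None = None,
    review: pd.DataFrame | None = None,
) -> tuple[DiseaseGrouping, pd.DataFrame]:
    """Stage-2 refinement: merge groups with near-identical representative
    names under the embedder's cosine similarity.

    Returns the refined grouping and the proposal table (the review file
    content). With ``cfg.require_review`` only proposals whose ``decision``
    is ``approve`` in ``review`` are merged; otherwise every proposal
    merges. ``assigned_name`` in the review file overrides the default
    group name (the shortest representative).
    """
    cfg = cfg or GroupingConfig()
    embedder = embedder or TrigramEmbedder()
    gids = sorted(set(grouping.partition.values()))
    reps = {g: grouping.group_names.get(g, g) for g in gids}

    if gids:
        mat = np.vstack([embedder.embed(reps[g]) for g in gids])
        sims = mat @ mat.T
    else:
        sims = np.zeros((0, 0))

    proposals = []
    pid = 0
    for i in range(len(gids)):
        for j in range(i + 1, len(gids)):
            s = float(sims[i, j])
            if s >= cfg.similarity_cutoff:
                proposals.append(
                    {
                        "proposal_id": f"P{pid:05d}",
                        "group_a": gids[i],
                        "group_b": gids[j],
                        "representative_a": reps[gids[i]],
                        "representative_b": reps[gids[j]],
                        "similarity": s,
                        "decision": "",
                        "assigned_name": "",
                    }
                )
                pid += 1
    proposal_df = pd.DataFrame(proposals, columns=REVIEW_COLUMNS)

    if cfg.require_review:
        if review is None:
            to_merge = proposal_df.iloc[0:0]
        else:
            known = set(gids)
            bad = set(review["group_a"]) | set(review["group_b"]) - known
            bad -= known
            if bad:
                raise ValueError(f"review file references unknown group id(s): {sorted(bad)[:3]}")
            to_merge = review[review["decision"] == "approve"]
    else:
        to_merge = proposal_df

    uf = _UnionFind(gids)
    assigned: dict[str, str] = {}
    for _, prop in to_merge.iterrows():
        uf.union(prop["group_a"], prop["group_b"])
        name = str(prop.get("assigned_name", "") or "")
        if name:
            assigned[uf.find(prop["group_a"])] = name

    refined = DiseaseGrouping(evidence=list(grouping.evidence))
    members_by_root: dict[str, list[str]] = {}
    for g in gids:
        members_by_root.setdefault(uf.find(g), []).append(g)
    for root, group_members in members_by_root.items():
        new_gid = min(group_members)
        if len(group_members) == 1:
            name = grouping.group_names.get(new_gid, new_gid)
        else:
            name = assigned.get(root) or min(
                (reps[g] for g in group_members), key=lambda n: (len(n), n)
            )
            for g in group_members:
                refined.evidence.append(
                    {
                        "rule": "embedding",
                        "a": new_gid,
                        "b": g,
                        "similarity": float(
                            to_merge.loc[
                                (to_merge["group_a"] == g) | (to_merge["group_b"] == g),
                                "similarity",
                            ].max()
                        )
                        if g != new_gid
                        else 1.0,
                        "review": "approved" if cfg.require_review else "auto",
                    }
                )
        refined.group_names[new_gid] = name
        for g in group_members:
            for did, gid in grouping.partition.items():
                if gid == g:
                    refined.partition[did] = new_gid
    return refined, proposal_df


# ---------------------------------------------------------------------------
# Applying the partition to relation tables
# ---------------------------------------------------------------------------


def apply_grouping(
    tables: list[TriplesTable], grouping: DiseaseGrouping
) -> tuple[list[TriplesTable], DropLog]:
    """Replace every disease identifier by its group id and deduplicate.

    Self-edges created by grouping (both endpoints collapse into one group)
    are removed and logged. Raises if a disease id in the tables is missing
    from the partition.
    """
    log = DropLog()
    out = []
    for table in tables:
        df = table.df.copy()
        for side in ("x", "y"):
            mask = df[f"{side}_type"] == "disease"
            if not mask.any():
                continue
            missing = sorted(set(df.loc[mask, f"{side}_id"]) - set(grouping.partition))
            if missing:
                raise ValueError(
                    f"disease id(s) missing from partition: {missing[:5]} "
                    f"in table {table.resource_tag!r}"
                )
            df.loc[mask, f"{side}_id"] = df.loc[mask, f"{side}_id"].map(grouping.partition)
            df.loc[mask, f"{side}_name"] = df.loc[mask, f"{side}_id"].map(grouping.group_names)
        self_loop = (
            (df["x_id"] == df["y_id"])
            & (df["x_type"] == df["y_type"])
            & (df["x_source"] == df["y_source"])
            & (df["x_type"] == "disease")
        )
        for _, row in df[self_loop].iterrows():
            log.drop("self-edge after grouping", x_id=row["x_id"], relation=row["relation"])
        df = df[~self_loop]
        before = len(df)
        df = df.drop_duplicates(
            subset=[c for c in df.columns if c != "resource"]
        ).reset_index(drop=True)
        dup = before - len(df)
        if dup:
            log.drop("duplicate after grouping", count=dup, table=table.resource_tag)
        out.append(TriplesTable(df, resource_tag=table.resource_tag))
    return out, log


def group_diseases(
    names: Mapping[str, str],
    cfg: GroupingConfig | None = None,
    embedder: NameEmbedder | None = None,
    review: pd.DataFrame | None = None,
) -> tuple[DiseaseGrouping, pd.DataFrame]:
    """Full two-stage grouping pipeline: string matching then embedding
    refinement. Returns (grouping, proposal table)."""
    cfg = cfg or GroupingConfig()
    stage1 = string_match_groups(names, cfg)
    return embedding_refine(stage1, embedder, cfg, review)
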