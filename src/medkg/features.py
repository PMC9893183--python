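"""Clinical text features for drug and disease nodes.

Drug nodes carry free-text fields (description, indication, mechanism of
action, pharmacodynamics, half-life, protein binding, pathways, grouped
attributes joined with conjunctions) plus numeric physicochemical
descriptors (molecular weight, topological polar surface area, cLogP)
rendered to fixed sentence templates. Disease nodes aggregate definitions
and guideline text from several knowledgebases, keyed by node_index; a
grouped disease node may carry multiple feature rows, one per contributing
source identifier.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grouping import (
    DiseaseGrouping,
    GroupingConfig,
    NameEmbedder,
    TrigramEmbedder,
    normalize_name,
)
from .schema import KnowledgeGraph
from .tables import DropLog

__all__ = [
    "clean_reference_tokens",
    "normalize_half_life",
    "numeric_to_text",
    "split_when_to_see_doctor",
    "match_disease_names",
    "attach_features",
    "NO_DATA_TRIGGERS",
]

# citation tokens look like [L64839] / [A12]: letter prefix + digits
_REF_TOKEN_RE = re.compile(r"\s*\[[A-Za-z]\d+\]")


def clean_reference_tokens(text: str) -> str:
    """Remove bracketed citation tokens (letter prefix + digits inside
    square brackets); all other bracketed text is preserved."""
    return _REF_TOKEN_RE.sub("", text).strip()


#: trigger phrases meaning the half-life field carries no information
NO_DATA_TRIGGERS: tuple[str, ...] = (
    "no data",
    "not available",
    "no half-life",
    "unavailable",
    "not known",
)


def normalize_half_life(text: str, triggers: tuple[str, ...] = NO_DATA_TRIGGERS) -> str:
    """Empty out half-life text stating that no data is available."""
    if not text:
        return ""
    low = text.lower()
    if any(t in low for t in triggers):
        return ""
    return text


def _fmt(value: float) -> str:
    return f"{value:g}"


def numeric_to_text(drug_name: str, descriptor: str, value: float) -> str:
    """Render a numeric descriptor as a standardized sentence.

    Descriptors: ``molecular_weight``, ``tpsa``, ``clogp``. Non-finite
    values render as the empty string, never a fabricated sentence.
    """
    try:
        v = float(value)
    except (TypeError, ValueError):
        return ""
    if not math.isfinite(v):
        return ""
    if descriptor == "molecular_weight":
        return f"The molecular weight is {_fmt(v)}."
    if descriptor == "tpsa":
        return f"{drug_name} has a topological polar surface area of {_fmt(v)}."
    if descriptor == "clogp":
        return f"The log p value of {drug_name} is {_fmt(v)}."
    raise ValueError(f"unknown descriptor {descriptor!r}")


_WTSD_RE = re.compile(r"when to see (?:a|the) doctor\s*[:.\-]?\s*", re.IGNORECASE)


def split_when_to_see_doctor(symptoms_text: str) -> tuple[str, str]:
    """Split symptom text at the first 'When to see a doctor' heading.

    Returns (symptoms, when_to_see_doctor); the second element is empty
    when the heading is absent.
    """
    m = _WTSD_RE.search(symptoms_text)
    if m is None:
        return symptoms_text, ""
    return symptoms_text[: m.start()].strip(), symptoms_text[m.end() :].strip()


def _encapsulates(source_norm: str, target_norm: str) -> bool:
    """Source name wholly contained in the target name, on token boundaries."""
    return (
        f" {source_norm} " in f" {target_norm} "
        and source_norm != target_norm
        and bool(source_norm)
    )


def match_disease_names(
    source_names: Mapping[str, str],
    target_names: Mapping[str, str],
    embedder: NameEmbedder | None = None,
    cfg: GroupingConfig | None = None,
    review: pd.DataFrame | None = None,
) -> tuple[dict[str, str], pd.DataFrame, list[str]]:
    """Map source disease names (e.g. a scraped knowledgebase) onto target
    ontology names.

    Stage 1 auto-accepts exact normalized matches and encapsulating matches
    (the source name wholly contained in the target name). Stage 2 proposes
    embedding-similarity matches for the remainder through the review-file
    workflow. Returns (mapping source_id -> target_id, proposal table,
    unmatched source ids).
    """
    cfg = cfg or GroupingConfig()
    embedder = embedder or TrigramEmbedder()
    t_norm = {t: normalize_name(n) for t, n in target_names.items()}
    by_norm: dict[str, list[str]] = {}
    for t, n in t_norm.items():
        by_norm.setdefault(n, []).append(t)

    mapping: dict[str, str] = {}
    remaining: list[str] = []
    for sid in sorted(source_names):
        s_norm = normalize_name(source_names[sid])
        exact = by_norm.get(s_norm)
        if exact:
            mapping[sid] = min(exact)
            continue
        encl = [t for t, n in t_norm.items() if _encapsulates(s_norm, n)]
        if encl:
            # most specific (shortest) containing name, ties lexicographic
            mapping[sid] = min(encl, key=lambda t: (len(t_norm[t]), t))
            continue
        remaining.append(sid)

    tids = sorted(target_names)
    proposals = []
    if remaining and tids:
        tmat = np.vstack([embedder.embed(target_names[t]) for t in tids])
        pid = 0
        for sid in remaining:
            sims = tmat @ embedder.embed(source_names[sid])
            best = int(np.argmax(sims))
            if sims[best] >= cfg.similarity_cutoff:
                proposals.append(
                    {
                        "proposal_id": f"M{pid:05d}",
                        "group_a": sid,
                        "group_b": tids[best],
                        "representative_a": source_names[sid],
                        "representative_b": target_names[tids[best]],
                        "similarity": float(sims[best]),
                        "decision": "",
                        "assigned_name": "",
                    }
                )
                pid += 1
    proposal_df = pd.DataFrame(
        proposals,
        columns=[
            "proposal_id",
            "group_a",
            "group_b",
            "representative_a",
            "representative_b",
            "similarity",
            "decision",
            "assigned_name",
        ],
    )
    accepted = (
        review[review["decision"] == "approve"]
        if (cfg.require_review and review is not None)
        else (proposal_df if not cfg.require_review else proposal_df.iloc[0:0])
    )
    for _, prop in accepted.iterrows():
        mapping[prop["group_a"]] = prop["group_b"]
    unmatched = sorted(set(source_names) - set(mapping))
    return mapping, proposal_df, unmatched


@dataclass
class FeatureAttachment:
    drug_features: pd.DataFrame = field(default_factory=pd.DataFrame)
    disease_features: pd.DataFrame = field(default_factory=pd.DataFrame)
    log: DropLog = field(default_factory=DropLog)


def attach_features(
    kg: KnowledgeGraph,
    drug_records: pd.DataFrame | None = None,
    disease_records: pd.DataFrame | None = None,
    grouping: DiseaseGrouping | None = None,
) -> FeatureAttachment:
    """Key feature records by node_index.

    ``drug_records`` must carry a ``drug_id`` column (one record per drug);
    ``disease_records`` a ``disease_id`` column in the pre-grouping
    identifier space (the grouping partition routes each record to its
    grouped node, so one node_index may collect several rows). Records for
    identifiers absent from the graph are logged, never attached or
    invented.
    """
    out = FeatureAttachment()
    nodes = kg.nodes
    drug_index = dict(
        zip(
            nodes.loc[nodes["node_type"] == "drug", "node_id"],
            nodes.loc[nodes["node_type"] == "drug", "node_index"],
        )
    )
    disease_index = dict(
        zip(
            nodes.loc[nodes["node_type"] == "disease", "node_id"],
            nodes.loc[nodes["node_type"] == "disease", "node_index"],
        )
    )

    if drug_records is not None and len(drug_records):
        rows = []
        for _, rec in drug_records.iterrows():
            idx = drug_index.get(rec["drug_id"])
            if idx is None:
                out.log.drop("drug not in graph", identifier=rec["drug_id"])
                continue
            row = {"node_index": idx, **rec.to_dict()}
            rows.append(row)
        out.drug_features = pd.DataFrame(rows)
        if len(out.drug_features):
            dup = out.drug_features["node_index"].duplicated()
            if dup.any():
                raise ValueError("more than one feature record for a drug node")

    if disease_records is not None and len(disease_records):
        rows = []
        for _, rec in disease_records.iterrows():
            did = rec["disease_id"]
            gid = grouping.partition.get(did, did) if grouping is not None else did
            idx = disease_index.get(gid)
            if idx is None:
                out.log.drop("disease not in graph", identifier=did)
                continue
            rows.append({"node_index": idx, "contributing_node_id": did, **rec.to_dict()})
        out.disease_features = pd.DataFrame(rows)
    return out
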