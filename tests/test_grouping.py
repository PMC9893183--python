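"""Disease entity grouping: suffix rule, string matching, embedding
refinement, partition application, and recovery of planted families."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from medkg.fixtures import FixtureSpec, make_planted_disease_names
from medkg.grouping import (
    DiseaseGrouping,
    GroupingConfig,
    TrigramEmbedder,
    apply_grouping,
    embedding_refine,
    extract_base_phrase,
    group_diseases,
    normalize_name,
    string_match_groups,
)
from medkg.tables import TriplesTable


# ---------------------------------------------------------------------------
# Base-phrase extraction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "name,expected",
    [
        ("Autism, susceptibility to, 1", "autism susceptibility to"),
        ("mucopolysaccharidosis type II", "mucopolysaccharidosis type"),
        ("asthma", None),                       # no qualifying ending
        ("Diabetes mellitus type 1", "diabetes mellitus type"),
        ("familial disorder 2a", "familial disorder"),   # short alphanumeric
        ("hemoglobin h disease", None),          # 'disease' is not a qualifier
        ("retinitis pigmentosa x", "retinitis pigmentosa"),  # single letter
        ("syndrome type foo", "syndrome type"),  # 'type' second-last
        ("x", None),                             # single token, nothing to strip
    ],
)
def test_extract_base_phrase(name, expected):
    assert extract_base_phrase(name) == expected


@settings(derandomize=True, max_examples=200)
@given(st.text(max_size=60))
def test_normalize_is_idempotent_on_arbitrary_text(text):
    once = normalize_name(text)
    assert normalize_name(once) == once
    assert "  " not in once and once == once.strip()


_word = st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=3, max_size=10)


@settings(derandomize=True, max_examples=200)
@given(st.lists(_word, min_size=1, max_size=5), st.integers(min_value=1, max_value=20))
def test_base_phrase_strips_exactly_one_token(words, subtype):
    """For a name built as '<words> <number>', the base phrase is the
    normalized words; names without a qualifying ending yield None."""
    name = " ".join(words)
    assert extract_base_phrase(f"{name} {subtype}") == normalize_name(name)
    if words[-1] != "type" and (len(words) < 2 or words[-2] != "type"):
        assert extract_base_phrase(name) in (None, normalize_name(" ".join(words[:-1])))


def test_normalize_is_idempotent_and_strips_ignored_phrase():
    n = normalize_name("Fabry (disease), Type II!")
    assert n == normalize_name(n)
    assert "(" not in n
    assert n == "fabry type ii"


# ---------------------------------------------------------------------------
# String matching
# ---------------------------------------------------------------------------


def test_autism_susceptibility_names_form_one_group():
    names = {
        "M:1": "Autism, susceptibility to, 1",
        "M:2": "Autism, susceptibility to, 2",
        "M:3": "Autism, susceptibility to, x-linked",
    }
    g = string_match_groups(names)
    assert g.n_groups == 1


def test_bag_of_words_match_ignores_order_and_type():
    names = {"M:1": "Diabetes mellitus type 1", "M:2": "type 1 diabetes mellitus"}
    g = string_match_groups(names)
    assert g.n_groups == 1


def test_unrelated_names_stay_singletons():
    g = string_match_groups({"M:1": "asthma", "M:2": "psoriasis"})
    assert g.n_groups == 2
    assert g.group_names["M:1"] == "asthma"
    assert g.group_names["M:2"] == "psoriasis"


def test_no_merge_without_shared_tokens():
    """Guard property: the string stage never merges names sharing no
    normalized tokens."""
    spec = FixtureSpec(rng_seed=5, n_subtype_families=10, n_distractor_diseases=30)
    names, _ = make_planted_disease_names(spec)
    g = string_match_groups(names)
    groups = g.groups()
    for members in groups.values():
        if len(members) < 2:
            continue
        token_sets = [set(normalize_name(names[m]).split()) for m in members]
        for ts in token_sets[1:]:
            assert token_sets[0] & ts


# ---------------------------------------------------------------------------
# Embedding refinement
# ---------------------------------------------------------------------------


class OrthogonalEmbedder:
    """Toy embedder: distinct names map to orthogonal basis vectors."""

    model_tag = "orthogonal-toy"

    def __init__(self):
        self.seen: dict[str, int] = {}

    def embed(self, name: str) -> np.ndarray:
        i = self.seen.setdefault(name, len(self.seen))
        v = np.zeros(64)
        v[i % 64] = 1.0
        return v


def test_identical_representatives_always_proposed():
    g = DiseaseGrouping(
        partition={"M:1": "M:1", "M:2": "M:2"},
        group_names={"M:1": "same name", "M:2": "same name"},
    )
    refined, proposals = embedding_refine(g, TrigramEmbedder())
    assert len(proposals) == 1
    assert proposals.iloc[0]["similarity"] == pytest.approx(1.0)
    assert refined.n_groups == 1


def test_orthogonal_embedder_proposes_nothing():
    g = DiseaseGrouping(
        partition={"M:1": "M:1", "M:2": "M:2"},
        group_names={"M:1": "asthma", "M:2": "psoriasis"},
    )
    refined, proposals = embedding_refine(g, OrthogonalEmbedder())
    assert len(proposals) == 0
    assert refined.n_groups == 2


def test_trigram_proposals_match_bruteforce_on_planted_pairs():
    spec = FixtureSpec(rng_seed=9, n_subtype_families=0, n_distractor_diseases=20,
                       n_near_duplicate_pairs=4)
    names, partition = make_planted_disease_names(spec)
    cfg = GroupingConfig()
    stage1 = string_match_groups(names, cfg)
    refined, proposals = embedding_refine(stage1, TrigramEmbedder(), cfg)

    # brute-force pairwise similarity over representatives
    emb = TrigramEmbedder()
    gids = sorted(set(stage1.partition.values()))
    reps = {g: stage1.group_names[g] for g in gids}
    expected = set()
    for i, a in enumerate(gids):
        for b in gids[i + 1 :]:
            if float(emb.embed(reps[a]) @ emb.embed(reps[b])) >= cfg.similarity_cutoff:
                expected.add((a, b))
    got = set(zip(proposals["group_a"], proposals["group_b"]))
    assert got == expected
    # the planted near-duplicate pairs end up merged
    order = sorted(names)
    ari = adjusted_rand_score(
        [partition[d] for d in order], [refined.partition[d] for d in order]
    )
    assert ari == pytest.approx(1.0)


def test_cutoff_monotonicity():
    spec = FixtureSpec(rng_seed=2, n_subtype_families=5, n_distractor_diseases=20,
                       n_near_duplicate_pairs=3)
    names, _ = make_planted_disease_names(spec)
    counts = []
    for cutoff in (0.999, 0.98, 0.8, 0.5):
        stage1 = string_match_groups(names)
        _, proposals = embedding_refine(
            stage1, TrigramEmbedder(), GroupingConfig(similarity_cutoff=cutoff)
        )
        counts.append(len(proposals))
    assert counts == sorted(counts)


def test_review_workflow_merges_only_approved():
    g = DiseaseGrouping(
        partition={"M:1": "M:1", "M:2": "M:2", "M:3": "M:3"},
        group_names={"M:1": "alpha syndrome", "M:2": "alpha syndrome", "M:3": "alpha syndrome"},
    )
    cfg = GroupingConfig(require_review=True)
    _, proposals = embedding_refine(g, TrigramEmbedder(), cfg)
    assert len(proposals) == 3  # all pairs identical
    review = proposals.copy()
    review.loc[:, "decision"] = "reject"
    review.loc[0, "decision"] = "approve"
    review.loc[0, "assigned_name"] = "alpha syndrome (reviewed)"
    refined, _ = embedding_refine(g, TrigramEmbedder(), cfg, review=review)
    assert refined.n_groups == 2
    merged_gid = refined.partition[review.loc[0, "group_a"]]
    assert refined.group_names[merged_gid] == "alpha syndrome (reviewed)"


def test_review_file_with_unknown_group_rejected():
    g = DiseaseGrouping(partition={"M:1": "M:1"}, group_names={"M:1": "x"})
    cfg = GroupingConfig(require_review=True)
    review = pd.DataFrame(
        [{"proposal_id": "P0", "group_a": "M:1", "group_b": "M:99",
          "representative_a": "x", "representative_b": "y",
          "similarity": 1.0, "decision": "approve", "assigned_name": ""}]
    )
    with pytest.raises(ValueError, match="unknown group"):
        embedding_refine(g, TrigramEmbedder(), cfg, review=review)


# ---------------------------------------------------------------------------
# Applying the partition
# ---------------------------------------------------------------------------


def _disease_protein(d, g):
    return {
        "relation": "disease_protein",
        "x_id": d, "x_type": "disease", "x_source": "MONDO",
        "y_id": g, "y_type": "gene/protein", "y_source": "NCBI",
    }


def test_apply_identity_partition_is_noop():
    table = TriplesTable(pd.DataFrame([_disease_protein("M:1", "g1")]), resource_tag="t")
    grouping = DiseaseGrouping(partition={"M:1": "M:1"}, group_names={"M:1": "m1"})
    out, log = apply_grouping([table], grouping)
    assert list(out[0].df["x_id"]) == ["M:1"]
    assert log.n_dropped == 0


def test_apply_grouping_dedups_and_removes_self_edges():
    rows = [
        _disease_protein("M:1", "g1"),
        _disease_protein("M:2", "g1"),  # same group, same protein -> dedup
        {
            "relation": "disease_disease",
            "x_id": "M:1", "x_type": "disease", "x_source": "MONDO",
            "y_id": "M:2", "y_type": "disease", "y_source": "MONDO",
        },  # becomes a self-edge -> removed
    ]
    grouping = DiseaseGrouping(
        partition={"M:1": "M:1", "M:2": "M:1"}, group_names={"M:1": "m family"}
    )
    out, log = apply_grouping([TriplesTable(pd.DataFrame(rows), resource_tag="t")], grouping)
    assert len(out[0]) == 1
    assert out[0].df.iloc[0]["x_id"] == "M:1"
    assert out[0].df.iloc[0]["x_name"] == "m family"
    reasons = {r["reason"] for r in log.to_frame().to_dict("records")}
    assert "self-edge after grouping" in reasons


def test_apply_grouping_matches_relabel_then_dedup_oracle():
    rng = np.random.default_rng(4)
    diseases = [f"M:{i}" for i in range(12)]
    partition = {d: f"M:{int(i // 3) * 3}" for i, d in enumerate(diseases)}
    rows = [
        _disease_protein(diseases[int(rng.integers(0, 12))], f"g{int(rng.integers(0, 5))}")
        for _ in range(40)
    ]
    table = TriplesTable(pd.DataFrame(rows), resource_tag="t")
    grouping = DiseaseGrouping(
        partition=partition, group_names={g: g for g in set(partition.values())}
    )
    out, _ = apply_grouping([table], grouping)

    oracle = table.df.copy()
    oracle["x_id"] = oracle["x_id"].map(partition)
    oracle["x_name"] = oracle["x_id"]
    oracle = oracle.drop_duplicates(subset=[c for c in oracle.columns if c != "resource"])
    assert sorted(zip(out[0].df["x_id"], out[0].df["y_id"])) == sorted(
        zip(oracle["x_id"], oracle["y_id"])
    )


def test_missing_disease_id_is_contract_error():
    table = TriplesTable(pd.DataFrame([_disease_protein("M:9", "g1")]), resource_tag="t")
    with pytest.raises(ValueError, match="M:9"):
        apply_grouping([table], DiseaseGrouping(partition={"M:1": "M:1"}))


# ---------------------------------------------------------------------------
# Recovery and idempotence on planted families
# ---------------------------------------------------------------------------


def test_partition_recovery_on_planted_families():
    spec = FixtureSpec(rng_seed=13)  # 40 families x 3-8 + 100 distractors
    names, planted = make_planted_disease_names(spec)
    grouping, _ = group_diseases(names)
    order = sorted(names)
    ari = adjusted_rand_score(
        [planted[d] for d in order], [grouping.partition[d] for d in order]
    )
    assert ari >= 0.95


def test_grouping_pipeline_is_idempotent():
    spec = FixtureSpec(rng_seed=21, n_subtype_families=15, n_distractor_diseases=40)
    names, _ = make_planted_disease_names(spec)
    grouping, _ = group_diseases(names)
    grouped_names = {
        gid: grouping.group_names[gid] for gid in set(grouping.partition.values())
    }
    second, _ = group_diseases(grouped_names)
    assert second.is_identity()
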