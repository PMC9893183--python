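# Methods

This note documents the models, rules and numerical choices behind
`medkg`, and what the synthetic test world does and does not establish
about behavior on real resource snapshots.

## Graph model

The knowledge graph is a typed heterogeneous network. Ten node types are
admissible (gene/protein, drug, effect/phenotype, disease,
biological_process, molecular_function, cellular_component, exposure,
pathway, anatomy) and thirty relation types, each declaring its unordered
endpoint-type pair. Both enums are closed: readers reject unknown labels
rather than coercing them.

All edges are undirected in meaning but stored as two directed rows, one
per orientation — the convention of the deposited-file format this schema
is compatible with. A clean graph has no self-loops, no exact duplicate
rows, and a perfectly symmetric edge multiset; `validate_kg` checks these
three rules plus endpoint existence and endpoint-type consistency, and the
writer refuses graphs that fail.

Canonical ordering (nodes by `node_index`, edges lexicographically by
`(relation, x_index, y_index)`) defines equality, makes serialization
byte-stable, and keeps diffs meaningful. Node indices are assigned by
sorting unique nodes by `(node_type, node_source, node_id)` and numbering
from zero. This rule is deterministic and order-independent, but it is a
choice of this package: no claim is made that indices coincide with any
externally published artifact, whose assignment rule is not documented.

## Resource adapters

Each adapter is a pure function of (rows, config) with a logged-drop
contract: every input row is either emitted (possibly expanded by a
one-to-many identifier mapping, with the multiplicity logged) or dropped
with a recorded reason. This makes `|in| = |out before expansion| +
|drops|` checkable on every run and keeps ingest failures attributable.
Rows with missing identifiers are dropped here rather than at assembly, so
the later NaN-dropping stage is normally a no-op.

Filter semantics worth stating precisely:

* **Expression calls** keep rows with the configured quality label
  (default "gold quality"), FDR ≤ 0.01 (inclusive), and expression rank
  strictly below 25,000. The strict/inclusive split follows the stated
  thresholds ("rank less than 25,000"; FDR "of ≤ 0.01"). Whether the rank
  cutoff should also apply to *absent* calls is genuinely ambiguous — the
  rank of an absent call is not an expression level — so
  `bgee_filter_absent_rank` exposes the choice; the default applies all
  three filters uniformly.
* **Metathesaurus disorder selection** keeps concepts whose semantic type
  is one of the 11 Disorder-group types, restricted to English-language
  atoms, attaching definitions from an allowlist of English sources
  (configurable; RRF definition rows carry a source but no language tag).
* **Side effects** keep rows coded at the MedDRA preferred-term level and
  map drugs through the STITCH → ATC → drug-accession chain; a break
  anywhere in the chain drops the row with reason.
* **PPI union** treats all sources as unweighted and undirected,
  deduplicating on unordered gene pairs.
* **Drug interactions** from the XML export are deduplicated to one
  undirected pair even when both partners list each other; symmetry is
  restored once, at assembly.

## Overlap resolution

The overlap set *P* contains phenotype identifiers that also denote
diseases, by either of two rules: (i) equal zero-stripped numeric CURIE
suffix ("same ID number" under shared numbering), or (ii) a
cross-reference from the disease ontology to the phenotype term. Evidence
(`same-numeric-id`, `xref-mapped`, `both`) is kept per member.

Rewiring is relation-specific: phenotype–phenotype edges with one endpoint
in *P* become disease–phenotype edges (labeled as positive associations,
the only affirmative disease–phenotype label in the enum); with both
endpoints in *P*, disease–disease edges. Protein–phenotype edges whose
phenotype is in *P* become protein–disease edges. Disease–phenotype and
drug–phenotype edges on *P* are dropped outright — converting them would
only add noise to the carefully curated drug–disease label set. A member
of *P* mapping to several disease identifiers duplicates the rewired edge
for each target (consistent with the expand policy of identifier mapping);
assembly deduplication absorbs any resulting repeats. The operation is a
fixed point: a second pass changes nothing, because no phenotype endpoint
in *P* survives the first.

## Disease grouping

Stage 1 (string matching). Names are normalized (lowercase, punctuation
stripped, whitespace collapsed; the literal phrase "(disease)" is removed
before punctuation stripping so it leaves no stray token). A name whose
final token is a number, a roman numeral (I–XX, the range used by subtype
nomenclature), a short alphanumeric qualifier (≤ 2 characters containing a
digit, or a single letter), or whose second-last word is "type", seeds a
candidate group through its *base phrase* — the name minus the ending. The
group collects (a) names beginning with the base phrase on a token
boundary and (b) names whose word bag equals the base-phrase word bag.
For the bag comparison the word "type" and qualifier tokens are removed
from both sides; stripping qualifiers only at the suffix position would
make order-insensitive matching fail exactly where it is needed
("type 1 diabetes mellitus" vs "diabetes mellitus type 1"), contradicting
the rule's purpose. The transitive closure of matches yields the
partition. The "alphanumeric phrase with a length of less than 2"
predicate is ambiguous in its source description (string length vs token
count); the reading above is explicit and configurable
(`max_qualifier_len`).

Stage 2 (embedding refinement). Each group is represented by its most
common base phrase (falling back to the shortest member name). Cosine
similarity between representative embeddings at or above the cutoff
(default 0.98) emits a merge proposal. The quantity is treated as cosine
*similarity* — the source description says "cosine distance" yet applies
"similarity ≥ 0.98", a terminological slip. Proposals are written to a
review file (`proposal_id, group_a, group_b, representative_a,
representative_b, similarity, decision, assigned_name`); with
`require_review` only approved rows merge and `assigned_name` overrides
the default group name, replacing interactive manual approval with a
reproducible audit trail. Refinement only merges groups; whether it could
also split string-matched groups is left out of scope.

The bundled embedder hashes character trigrams of the normalized name into
a 256-dimension count vector (stable MD5-based hashing, so results do not
depend on interpreter hash seeding) and L2-normalizes. It is deterministic,
needs no downloads, and scores near-duplicate strings near 1 — sufficient
for the merge-proposal role in testing. It does **not** capture synonymy
("cancer" vs "neoplasm" score low); on real vocabularies a clinical
language model plugged into the `NameEmbedder` contract will propose
semantically equivalent names the trigram embedder cannot. Consequences
for interpretation: recovery results on the synthetic fixtures certify the
algorithmic machinery (suffix rule, bag matching, closure, refinement,
review), not the linguistic quality of any particular embedder.

Applying a partition replaces each disease identifier by its group id,
removes self-edges created when both endpoints collapse into one group
(logged), and deduplicates. Grouping is idempotent: regrouping the grouped
names yields the identity partition.

## Assembly

Cleaning executes a fixed sequence — drop rows with missing endpoints,
drop exact duplicates, add reverse rows, drop duplicates again, remove
self-loops — and reports per-stage counts that must reconcile exactly
(`out = in − nan − dup1 + rev − dup2 − self`). Connectivity for
giant-component extraction ignores relation types and direction, treating
the graph as one network. Component ties (never observed in practice, but
determinism requires a rule) break toward the larger edge count, then the
smallest canonical node key. Both the pre-component graph (`kg_raw`) and
the giant component (`kg_giant`) are exportable.

## Clinical features

Citation tokens are removed by the pattern `[<letter><digits>]` (the
source material shows a single example token; the letter class is
configurable), leaving all other bracketed text intact. Half-life text
stating that no data is available is emptied via a configurable trigger
list (default: "no data", "not available", "no half-life", "unavailable",
"not known") — the original build's trigger phrases are not recorded
anywhere, so the default is this package's choice. Numeric descriptors
render to fixed sentence templates; non-finite values render to the empty
string, never a fabricated sentence. Multi-valued fields join with
"; … and …". The "When to see a doctor" heading splits case-insensitively
with optional punctuation. All cleaning operations are idempotent.

Name-based feature mapping auto-accepts exact normalized matches and
encapsulating matches (source name wholly contained in the target, token
boundaries respected; the shortest containing target wins ties as the most
specific), then routes embedding-similarity proposals for the remainder
through the same review-file workflow as grouping. Disease features key by
`node_index`; because grouping collapses many source identifiers into one
node, a node may carry several rows per feature, each tagged with its
contributing identifier. Attachment never invents rows: outputs are a
subset of inputs, with multiplicity explained entirely by grouping fan-in.

## Network proximity test

Distance is the unweighted shortest-path hop count on the undirected view
over all relation types (single-source breadth-first search; disconnected
pairs are infinitely far). For a tested pair the null draws
`n_permutations` (default 1000) diseases uniformly without replacement
from the diseases lacking an indication edge to the drug (with replacement
only when the pool is smaller than the draw). The empirical p-value uses
add-one smoothing, `p = (1 + #{d_null ≤ d_obs}) / (n + 1)`, so p > 0
always and the test is exact-conservative. The direction — small p for
*closer than random* — is the standard repurposing reading; small observed
distances must yield small p-values. Bonferroni multiplicity counts only
the pairs actually tested: pairs already holding an indication edge are
flagged, reported with their distance, and excluded (testing a known
indication would answer no repurposing question).

Unreachable sampled diseases are excluded from the null mean and its
confidence interval (their count is reported) but still participate in the
p-value, where `inf ≤ d_obs` is false for finite observations. The
confidence interval is normal-theory for the null mean
(mean ± z·sd/√n at `ci_level`, default 0.95); whether such an interval
describes the mean or the sample distribution is a presentation choice,
and the mean is what the accompanying summary column reports.

## Synthetic test world

The fixture generator plants: subtype families (default 40 families of
3–8 variants, one naming pattern per family — numeric, roman, or
"susceptibility to" — over unique pseudo-word bases) plus 100 distractor
singletons and 5 near-duplicate pairs whose names differ only in case or
trailing punctuation (exercising the embedding stage); an overlap set
built half by shared numeric identifiers and half by cross-references; a
two-node isolated component; per-adapter survivor counts including
boundary rows (rank exactly 25,000 fails, FDR exactly 0.01 passes,
non-numeric ranks, broken mapping chains, mirrored interaction records,
non-preferred-term rows, a non-human pathway species); and proximity
testbeds. Generation is byte-deterministic for a fixed seed, and a
self-audit re-runs every adapter at generation time, failing loudly if any
planted count or the overlap set disagrees with the files.

The proximity testbeds are shaped by what the statistics require. The
exchangeable-null graph is a protein chain with one disease per position,
so all 100 candidate distances are *distinct*; with the exhaustive
permutation (n = 99) the empirical p is exactly uniform on its grid and
the fraction below 0.05 can be compared to a binomial band around 0.05.
With tied integer distances — the typical case on arbitrary graphs — the
empirical p is super-uniform (conservative) and no correct implementation
could sit inside that band; the chain design isolates the calibration
property from the tie structure. The power testbed plants one indication
at 2 hops against ~1,100 background diseases all at 4 hops, where
p_raw = 1/(n+1) deterministically.

What the mock world does not emulate: realistic degree distributions,
biological plausibility of associations, vocabulary-scale name collections
(real disease ontologies have ~20k+ names with genuine synonymy),
multi-rooted ontology topology, or full-scale edge counts. Passing tests
certify the construction rules, accounting identities and statistical
behavior of the method — not the content quality of any real build.

## Problem sizes and defaults

Defaults used throughout the tests and the acceptance script, chosen as
the smallest sizes that exercise every rule and make the statistical
checks sharp: mock world of ~315 diseases / 60 proteins / 25 drugs /
~1,000 directed edge rows; grouping recovery over 20 independent worlds;
calibration over 400 exchangeable pairs with exhaustive 99-draw nulls;
power over 200 replicates at 1,000 permutations; schema round-trips over
50 random graphs (≤ 60 nodes); component-extraction oracle over 100 random
graphs (≤ 1,000 nodes). The full pipeline on the default mock world builds
in well under a second; the complete acceptance run takes a few seconds.

## Known limitations

* The trigram embedder is a near-duplicate detector, not a semantic model;
  real-vocabulary grouping quality depends on the plugged-in embedder and
  the human review pass.
* The grouping suffix predicate is one defensible reading of an ambiguous
  rule; both the qualifier length bound and the ignored-word set are
  configuration, not fixed truths.
* Scraped clinical content enters as pre-extracted tables; the scraping
  itself (and its idiosyncrasies) is out of scope, and the bundled tables
  are labeled synthetic.
* Proximity uses plain hop distance, as specified — no degree-preserving
  null, no module-based or z-score proximity variants.
* In-memory, desk-scale assembly only; no streaming build, no graph
  database, no RDF/OWL export.
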