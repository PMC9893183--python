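# medkg

A construction toolkit for disease-centric biomedical knowledge graphs.

Biomedical knowledge about any one disease is scattered across ontologies
(disease, phenotype, anatomy, gene-function vocabularies), curated
association tables (gene–disease, drug–disease labels, side effects,
exposures), experimental readouts (expression calls) and clinical
guideline text. `medkg` harmonizes such resources into a single typed
graph — 10 node types, 30 relation types — and implements the analysis
steps that make the graph usable for precision-medicine work:

* **Resource adapters** that parse each standard format (OBO, RRF-style
  pipe-delimited tables, TSV/CSV exports, drug XML) and apply the
  per-resource filters: gold-quality expression calls with FDR ≤ 0.01 and
  expression rank < 25,000; the 11 Disorder-group semantic types when
  selecting disease concepts from a metathesaurus; MedDRA preferred-term
  side effects with a two-step drug identifier mapping chain; and so on.
  Every adapter logs each dropped row with a reason, so
  `|input| = |output| + |drops|` always holds.
* **Phenotype/disease overlap resolution.** When the disease and phenotype
  vocabularies come from one initiative, some phenotype terms also denote
  diseases (the overlap set *P*: same numeric identifier, or a
  cross-reference from the disease ontology). Edges touching *P* are
  rewired so each entity plays one role: phenotype–phenotype edges become
  disease–phenotype or disease–disease edges, protein–phenotype edges
  become protein–disease edges, and disease–phenotype / drug–phenotype
  edges on *P* are dropped.
* **Disease entity grouping.** Ontologies carry many repetitive subtype
  records ("X, susceptibility to, 1", "X type II") with little standalone
  clinical meaning. A two-stage algorithm collapses them: (1) suffix-driven
  string matching — a name ending in a number, roman numeral, short
  alphanumeric qualifier, or with "type" as its second-last word seeds a
  group via its *base phrase*, collecting names that share the initial
  phrase or the same word bag regardless of order; (2) embedding
  refinement — cosine similarity ≥ 0.98 between group-representative name
  embeddings proposes merges, routed through a machine-readable review
  file. A deterministic character-trigram embedder is bundled; a
  pretrained clinical language model can be plugged into the same
  interface.
* **Assembly.** Tables are merged and cleaned in a fixed order (drop
  missing endpoints, drop duplicates, add reverse edges, drop duplicates
  again, remove self-loops), the largest connected component is extracted,
  and node indices are assigned deterministically. Undirected edges are
  stored as two directed rows, matching the deposited-file convention
  (`relation, display_relation, x_index, x_id, ..., y_source`).
* **Clinical features.** Drug nodes carry twelve text features plus
  numeric descriptors rendered to sentences ("The molecular weight is
  360.45."); disease nodes aggregate definitions and guideline text from
  several knowledgebases, keyed by node index with one row per
  contributing source identifier.
* **Network-proximity drug repurposing.** For a drug–disease pair, the
  observed statistic is the shortest-path hop count *d* on the undirected
  graph. The null samples *n* non-indicated diseases and recomputes the
  distance; the empirical p-value with add-one smoothing is
  `p = (1 + #{d_null ≤ d_obs}) / (n + 1)`, Bonferroni-adjusted over the
  pairs actually tested (pairs already holding an indication edge are
  flagged and excluded).
* **Synthetic fixtures.** A generator emits miniature mock versions of
  every consumed format with planted ground truth (subtype families,
  overlap members, adapter survivor counts, component structure, proximity
  testbeds), so the entire pipeline builds and validates with no
  downloads.

## Worked example

```bash
medkg make-fixtures --seed 1 --out bundle
medkg build --manifest bundle/manifest.json --out build
```

prints

```
bundle written to bundle (32 resources)
kg_giant: 313 nodes, 974 directed edge rows (99.79508% of edges retained)
```

The mock world builds into a graph spanning all 10 node types and all 30
relation types; the giant component keeps 99.8% of edge rows (the planted
isolated pocket — two phenotype terms linked only to each other — is
excluded). `build/` now holds `kg_raw.csv`, `kg_giant.csv`,
`kg_giant_nodes.csv`, `assembly_report.json` and the rewire/drop audit
logs. A proximity test against the built graph:

```bash
medkg proximity-test --kg build/kg_giant.csv --pairs pairs.csv \
    --n-perm 200 --seed 7 --out prox.csv
```

```
drug,disease,has_indication_edge,shortest_distance,randomized_distance,p_raw,adjusted_p
DB00001,MONDO:0000016,False,3.0,2.98 (2.96–3.00),1.0,1.0
```

Here the candidate pair sits at 3 hops while a random non-indicated
disease averages 2.98 hops — no closer than chance, so the pair is not a
repurposing signal (p = 1.0). A drug planted 2 hops from its disease
against a ≥ 4-hop background yields p_raw = 1/(n+1), significant after
Bonferroni correction.

The same operations are available as a library:

```python
from medkg import build_kg, proximity_test, ProximityConfig
result = build_kg("bundle/manifest.json")
result.kg_giant.n_nodes        # 313
result.report.lcc              # component counts and edge retention
```

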