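# Methods and design notes

## Repository model

The metadata repository is a star-schema data mart: an Item fact table
(one row per processed genomic data file), dimension tables Donor,
Biosample, Replicate, Project, CaseStudy, ExperimentType and Dataset, two
many-to-many bridges (Replicate2Item, Case2Item) and an unstructured
table of raw `(item, key, value)` pairs holding whatever source metadata
did not map into the structured schema. Each of Donor, Biosample,
Replicate, CaseStudy and Item also carries a unique source accession
(`*_source_id`) for backlinks. Ten attributes are semantically enriched
and carry an optional term id into the knowledge base: ethnicity and
species (Donor); disease, tissue and cell (Biosample); technique, feature
and target (ExperimentType); platform and content_type (Item).

Normalization: every stored string is lower-cased with trimmed and
collapsed whitespace at load time, and every query string passes through
the same function, which makes all comparisons case-insensitive. Original
casing is not preserved. Ages are stored as integer days; user-facing
years convert at 365 days/year (30 years → 10 950 days).
`is_healthy` is tri-state (`true` / `false` / null); the null state
participates in `n/d` selection like any other null.

The backing store is a set of in-memory pandas DataFrames. Nothing in the
contract depends on that choice — any indexed store reproducing the
logical schema would do — and the query engine only ever reads the
*denormalized* view: one row per (item × replicate-chain × case-chain)
join path, carrying every core attribute exactly once. An item with R
replicates and C cases contributes R·C rows; items missing either bridge
are null-padded to one row so that purely annotational items (no
biological dimension) remain searchable. The view is rebuilt from scratch
whenever a repository is constructed; repositories are treated as
immutable afterwards, so it is cached per instance.

Interchange format: one UTF-8 TSV per table with a header row, empty
cells for nulls, and a `manifest.json` naming the files. On load,
internal ids are reassigned sequentially in file order and foreign keys
remapped; an unresolvable key aborts the load naming the offending row,
while softer invariant breaches (duplicate accessions, dangling
references, illegal tri-state values, negative ages, unresolvable term
ids) are reported as data by the content-consistency check
(`validate_repository`), which is exercised for soundness and
completeness by seeded corruption injection.

## Knowledge base and closure

Ontology fragments are stored as four relational tables (vocabulary,
synonym, reference, relationship) plus a curated annotation map from
(attribute, raw value) to term id. A convenience reader ingests OBO flat
files through `obonet`, keeping `is_a` and `relationship: part_of` edges.

The relationship closure is unfolded ahead of query time: for every term,
all ancestors reachable within `max_depth` hops (default 3, configurable)
are materialized with their minimum hop distance, traversing `is_a` and
`part_of` interchangeably; the per-edge type is kept only for explanation
output. Fragments must be acyclic — a cycle aborts unfolding with one
offending cycle named. On tied shortest paths the explanation module
breaks ties lexicographically on the intermediate ontology codes, so
rendered deduction chains are deterministic. Cross-references are carried
and exported but never influence matching.

## Matching semantics

Three design points deserve explicit justification:

* **Expansion descends only.** The expanded level matches items annotated
  to the searched concept or its *descendants*; ancestor-annotated items
  are excluded. The worked examples force this reading: the expanded
  count for a leaf concept (endometrium) equals its synonym count, which
  would be impossible if searching a part pulled in the whole organ's
  items.
* **Substring vs. equality.** Faceted (drop-down) matching is exact
  equality on normalized strings — `cervical` does not equal `cervix`.
  Keyword search at level 2 is raw substring containment (`brain` matches
  `smooth muscle cell of the brain vasculature`), not word-boundary
  matching; the two behaviours are deliberately different because the
  drop-down enumerates known values while keyword search explores.
* **`n/d` is always a null test.** No ontology applies to a null, so the
  `n/d` disjunct is evaluated as a plain is-null predicate at every
  semantic level rather than being rejected when combined with concrete
  values at synonym/expanded level. This keeps mixed selections
  well-defined while honouring the reason for the restriction.

Deduplication is global set semantics: an item reachable via several
replicates, cases or deduction chains counts once in every total. Facet
counts use self-exclusion (the attribute's own selections are ignored
when counting its values) and are recomputed from the denormalized view
on every query change; at desk scale no incremental caching is needed.

Keyword-search levels are cumulative (raw pairs; + core-attribute
substrings; + vocabulary label matches; + bounded hierarchical
expansion), so level k results are supersets of level k−1. Results are
grouped by deduction-chain signature; one item may legitimately appear
under several signatures — e.g. a value that both contains the keyword as
a substring and is annotated to a matching concept shows up under its
level-2 and level-3 chains — and `explain(item, keyword, level)` returns
every chain, enumerating all bounded relationship paths, with
`explain ≠ []` exactly when the item is in the keyword-search union.

Result summaries partition a result set by origin source and by dataset.
The dataset is functional per item; where an item belongs to several
projects the lexicographically smallest source is used so the buckets
remain a partition whose counts sum to the result cardinality.

## Query dialect and service surface

The JSON dialect has a `gcm` block (attribute → value list, one faceted
step), a `type` (semantic level, defaulting to `original`) and a `kv`
object whose entries each become one key-value step; steps conjoin, and
predicates inside a step disjoin. Strict JSON only. Serialization emits
`gcm` keys in the fixed registry order (dimension-grouped, alphabetical
within dimension) and the parse→serialize round trip is a fixed point,
property-tested by fuzzing. kv entry names are treated as
insertion-ordered labels with no further semantics. The human-readable
"Selected query" line renders attributes in registry order with values
comma-joined in selection order.

The service layer exposes the endpoint behaviours (field counts within a
payload context, paginated result listing, chain explanation, link and
CSV table exports) as pure functions of (repository, knowledge base,
payload) returning JSON-ready structures; repeated calls are
byte-identical. No HTTP server is bundled — the functions are
framework-agnostic and the click CLI fronts them directly. Field-count
responses report values sorted by count descending with ties broken by
value ascending, and the result-table pagination is capped at 1000 rows
per page; the `aggregated` table mode pipe-joins sorted distinct values
per item, the `replicated` mode shows one row per join path.

## Fixtures and what the tests show

The worked-example fixtures rebuild published search scenarios from their
printed inputs: each raw-value group receives its stated multiplicity,
its annotation, and a full synthetic chain (own donor, biosample,
replicate; one shared project/case/dataset per fixture), so every count
is unambiguous and order-invariant — the acceptance script's seed only
permutes group insertion order. Concepts whose ontology codes the
scenarios do not state (the eye / photoreceptor-array / retina subtree)
get synthetic placeholder codes in a reserved `TEST` namespace. Fixture
groups are generated disjoint, so per-chain group counts equal the
printed numbers even though a production repository need not be disjoint.

The seeded random generator emulates the *structure* of real metadata
(annotated and unannotated values, nulls, multi-replicate and multi-case
items, raw key-value pairs, a random DAG ontology with synonyms) and
records ground truth computed by an independent plain-Python brute force
at generation time. It does not emulate realistic vocabulary sizes,
value-frequency skew, or cross-source inconsistencies; passing these
tests therefore shows the engine implements the declared semantics
exactly, not that the semantics capture every quirk of real source
dumps. Default problem sizes — 25-term ontologies, repositories of
50–10 000 items, 100 seeds for the oracle-equivalence sweep — keep the
whole suite in the low minutes on one CPU while covering the size range
where set semantics, null padding and bridge multiplicity interact.

## Known limitations

* No ranking, fuzzy matching or stemming: matching is exact equality or
  raw substring by design.
* Ancestor expansion (hypernym matching of items) is intentionally not
  performed; only the browsed vocabulary, not the item match, widens
  upward.
* The annotation map is a curated input; no automatic free-text
  annotation against ontology services is attempted.
* Ontology versioning and cross-reference-based matching are out of
  scope; references are carried as data only.
* The in-memory backend targets desk-scale repositories (≤ a few hundred
  thousand denormalized rows); a database backend would be needed beyond
  that.
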