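# genofacet

Faceted, ontology-aware semantic search over integrated genomic-experiment
metadata.

Public consortia (TCGA/GDC, ENCODE, Roadmap Epigenomics, GENCODE, RefSeq)
describe their processed data files with metadata that is heterogeneous in
structure and vocabulary: one source says `uterus`, another `uterus nos`,
a third `corpus uteri`. `genofacet` is for bioinformaticians and data
engineers who need to locate comparable data files *across* such sources:
it models a consolidated metadata repository as a star-schema data mart,
attaches a multi-ontology knowledge base to ten semantically enriched
attributes, and answers faceted, key-value and keyword queries at three
levels of semantic matching.

## The model

**Repository.** A fact table of *items* (one per processed genomic data
file) with four dimensions — Biology (Donor, Biosample, Replicate),
Management (Project, CaseStudy), Technology (ExperimentType) and
Extraction (Dataset) — plus two many-to-many bridges (item↔replicate,
item↔case) and the original source metadata preserved as
`(item, key, value)` raw pairs. Queries read a denormalized join with one
row per (item × replicate-chain × case-chain) path; an item with *R*
replicates and *C* cases yields *R·C* rows, null-padded when a bridge is
empty so annotation items stay searchable.

**Knowledge base.** Vocabulary terms (e.g. `UBERON_0000995` *uterus*) with
synonyms, cross-references and directed `is_a` / `part_of` edges. The edge
set is unfolded into a materialized closure bounded by a configurable
depth *d* (default 3): pair (a, t) is stored with the minimum hop distance
whenever a mixed `is_a`/`part_of` path of length ≤ *d* climbs from t to a.
Curated annotation maps link raw attribute values to terms.

**Semantic matching.** For an attribute value query *v* at level

* `original`: items whose stored value equals *v* (case-insensitive);
* `synonym`: additionally items annotated to any term whose preferred
  label or synonym equals *v*;
* `expanded`: additionally items annotated to any descendant of those
  terms within the depth bound.

Results are sets (an item reachable through several join paths counts
once) and levels are monotone: original ⊆ synonym ⊆ expanded. Facet
counts per attribute value are computed under the query restricted to all
*other* attributes, so selecting a value never empties its own drop-down.
Keyword search works in four cumulative levels (raw pairs → core-attribute
substrings → vocabulary labels → hierarchical expansion) and each match is
reported with its *deduction chain* — the FK, annotation and relationship
hops that justify it.

## Worked example

The uterus concept area: eight raw tissue labels, five Uberon concepts,
`part_of` edges `body of uterus / uterine cervix / uterine wall → uterus`
and `endometrium → uterine wall`.

```python
from genofacet import SemanticLevel, match_items
from genofacet.fixtures import build_worked_example

repo, kb = build_worked_example("uterus")
for level in SemanticLevel:
    n = len(match_items(repo, kb, "tissue", "uterus", level))
    print(level.name, n)
```

prints

```
ORIGINAL 57
SYNONYM 1708
EXPANDED 16851
```

57 items carry the literal label `uterus`; the synonym level adds the 1651
`uterus nos` items annotated to the same concept; the expanded level pulls
in every item annotated to a concept at most three hops below `uterus`
(16 851 = the whole concept area). The API-shaped field-count service on
a cohort of 4821 GRCh38 prostate-adenocarcinoma items:

```python
from genofacet.service import field_counts
repo, kb = build_worked_example("prostate")
payload = {"gcm": {"disease": ["prostate adenocarcinoma"],
                   "assembly": ["grch38"]}, "type": "original", "kv": {}}
print(field_counts(repo, kb, payload, "is_healthy"))
```

```
{'values': [{'value': False, 'count': 3543}, {'value': True, 'count': 1278}],
 'info': {'shown_count': 2, 'total_count': 2, 'item_count': 4821}}
```

i.e. roughly 75 % tumoral and 25 % healthy samples.

A command-line front end covers loading, validation, search, facets,
key/value exploration, deduction-chain explanation, fixture generation and
exports — see `genofacet --help`. Ten predefined query documents live in
`examples/queries/`.

## Layout

```
src/genofacet/
  model.py     star schema, loading, validation, denormalization
  kb.py        vocabulary, synonyms, relationships, closure, OBO reader
  engine.py    matching levels, facets, sessions, keywords, chains
  queryio.py   JSON query dialect + "Selected query" rendering
  service.py   API-shaped pure functions (field counts, exports)
  cli.py       click command-line front end
  fixtures.py  worked examples + seeded random repositories with oracle
docs/methods.md  design notes and assumptions
```
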