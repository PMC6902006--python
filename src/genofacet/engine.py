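"""Faceted and keyword search over the denormalized metadata repository.

Three semantic matching levels apply to attribute search:

* ``ORIGINAL`` — exact (case-insensitive) equality with the raw value a
  source provided;
* ``SYNONYM``  — additionally, items whose value is annotated to any
  ontology term whose preferred label or synonym equals the query string;
* ``EXPANDED`` — additionally, items annotated to any depth-bounded
  sub-concept (``is_a`` / ``part_of`` descendant) of those terms.

Matching is monotone: every Original match is a Synonym match, every
Synonym match an Expanded match.  Expansion deliberately descends only —
searching a term never pulls in items annotated to its *ancestors*,
otherwise a query for a leaf concept would return its whole organ.

Faceted queries combine selected values disjunctively within an attribute
and conjunctively across attributes; the special ``n/d`` value selects
items whose attribute is null and is always evaluated as a plain null test
(no ontology applies to a null).  Key-value search filters on the raw
(key, value) pairs imported verbatim from the sources.  A query session is
an ordered conjunction of such steps.

Keyword search works in four cumulative levels (raw pairs, core-attribute
substrings, vocabulary labels, hierarchical expansion) and returns its
results grouped by *deduction chain* — the path of FK, annotation and
relationship hops that links each item to the place the keyword matched.
"""

from __future__ import annotations

import enum
import json
import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .kb import IS_A, PART_OF, KnowledgeBase, resolve_label
from .model import (ATTRIBUTE_TABLE, ENRICHED_ATTRIBUTES, ENTITY_PATHS, ND,
                    SEARCHABLE_ATTRIBUTES, Repository, norm)

__all__ = [
    "SemanticLevel",
    "FacetedQuery",
    "KeyValuePredicate",
    "FacetedStep",
    "KeyValueStep",
    "QuerySession",
    "ResultSet",
    "DeductionChain",
    "UnknownAttributeError",
    "match_items",
    "evaluate_query",
    "facet_counts",
    "evaluate_kv_step",
    "evaluate_session",
    "key_search",
    "value_search",
    "keyword_search",
    "explain",
    "summarize",
    "render_result_table",
]

logger = logging.getLogger("genofacet.queries")

MAX_PAGE_SIZE = 1000


class UnknownAttributeError(KeyError):
    pass


class SemanticLevel(enum.IntEnum):
    ORIGINAL = 1
    SYNONYM = 2
    EXPANDED = 3

    @classmethod
    def from_string(cls, s: str) -> "SemanticLevel":
        try:
            return cls[str(s).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown semantic level {s!r}; expected "
                             f"original, synonym or expanded") from None


@dataclass(frozen=True)
class FacetedQuery:
    """Map attribute -> selected values (values within one attribute are
    alternatives; attributes combine conjunctively)."""

    selections: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normed = {}
        for attr, values in self.selections.items():
            if attr not in SEARCHABLE_ATTRIBUTES:
                raise UnknownAttributeError(attr)
            if not values:
                raise ValueError(f"empty value list for attribute {attr!r}")
            normed[attr] = [ND if norm(v) == ND else norm(v) for v in values]
        object.__setattr__(self, "selections", normed)

    def without(self, attribute: str) -> "FacetedQuery":
        return FacetedQuery({a: list(v) for a, v in self.selections.items()
                             if a != attribute})


@dataclass(frozen=True)
class KeyValuePredicate:
    """One key-value filter: an item satisfies it iff the item carries a raw
    pair whose key equals one of the selected keys and whose value matches
    one of the accepted values for that key (exact equality or substring
    containment per the ``exact`` flag, both case-insensitive).  ``mode``
    records whether the pairs were found through a key or a value search;
    it does not change evaluation."""

    name: str
    mode: str = "key"          # "key" | "value"
    exact: bool = True
    pairs: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("key", "value"):
            raise ValueError(f"mode must be 'key' or 'value', got {self.mode!r}")
        normed = {norm(k): [norm(v) for v in vs]
                  for k, vs in self.pairs.items()}
        object.__setattr__(self, "pairs", normed)


@dataclass(frozen=True)
class FacetedStep:
    query: FacetedQuery


@dataclass(frozen=True)
class KeyValueStep:
    predicates: tuple[KeyValuePredicate, ...]
    name: str = ""
    context_gcm: tuple = ()    # preserved verbatim for JSON round trips


@dataclass(frozen=True)
class QuerySession:
    """Ordered conjunction of faceted and key-value steps at one semantic
    level; steps may be removed in any order and the result is order-
    independent."""

    steps: tuple = ()
    level: SemanticLevel = SemanticLevel.ORIGINAL

    def without_step(self, index: int) -> "QuerySession":
        steps = tuple(s for i, s in enumerate(self.steps) if i != index)
        return QuerySession(steps=steps, level=self.level)


@dataclass(frozen=True)
class ResultSet:
    item_ids: frozenset[int] = frozenset()

    def __len__(self) -> int:
        return len(self.item_ids)

    def __iter__(self):
        return iter(sorted(self.item_ids))

    def __contains__(self, item: int) -> bool:
        return item in self.item_ids

    def intersect(self, other: "ResultSet") -> "ResultSet":
        return ResultSet(self.item_ids & other.item_ids)

    def union(self, other: "ResultSet") -> "ResultSet":
        return ResultSet(self.item_ids | other.item_ids)


# --------------------------------------------------------------------------
# Attribute matching
# --------------------------------------------------------------------------

def _col_str(den: pd.DataFrame, attribute: str) -> pd.Series:
    """Attribute column as normalized strings (ints render without sign)."""
    s = den[attribute]
    if str(s.dtype) == "Int64":
        return s.map(lambda v: None if pd.isna(v) else str(int(v)))
    return s


def _check_attribute(attribute: str) -> None:
    if attribute not in SEARCHABLE_ATTRIBUTES:
        raise UnknownAttributeError(attribute)


def match_items(repo: Repository, kb: KnowledgeBase, attribute: str,
                value: str, level: SemanticLevel) -> frozenset[int]:
    """Item ids matching one attribute/value probe at the given level.

    Set semantics: an item reachable through several replicate or case
    paths counts once.  The ``n/d`` value selects items whose attribute is
    null on some join path, regardless of level.
    """
    _check_attribute(attribute)
    den = repo.denormalized()
    if den.empty:
        return frozenset()
    v = norm(value)
    col = _col_str(den, attribute)
    if v == ND or v is None:
        mask = col.isna()
        return frozenset(int(i) for i in den.loc[mask, "item_id"])

    mask = col == v
    if level >= SemanticLevel.SYNONYM and attribute in ENRICHED_ATTRIBUTES:
        tids = resolve_label(kb, v)
        if level >= SemanticLevel.EXPANDED and tids:
            clo = kb.closure()
            expanded = set(tids)
            for t in tids:
                if t in clo.nodes:
                    expanded |= clo.descendants(t)
            tids = expanded
        if tids:
            tid_col = den[f"{attribute}_tid"]
            mask = mask | tid_col.isin(list(tids))
    return frozenset(int(i) for i in den.loc[mask, "item_id"])


def evaluate_query(repo: Repository, kb: KnowledgeBase, q: FacetedQuery,
                   level: SemanticLevel) -> ResultSet:
    """Evaluate a faceted query: per attribute the union over its selected
    values, across attributes the intersection; the empty query matches the
    whole repository."""
    result = repo.all_item_ids()
    for attr, values in q.selections.items():
        hits: set[int] = set()
        for v in values:
            hits |= match_items(repo, kb, attr, v, level)
        result &= hits
    logger.info(json.dumps({"op": "evaluate_query",
                            "query": q.selections,
                            "level": level.name.lower(),
                            "n_items": len(result)}))
    return ResultSet(frozenset(result))


def facet_counts(repo: Repository, kb: KnowledgeBase, q: FacetedQuery,
                 level: SemanticLevel, attribute: str) -> dict[str, int]:
    """Distinct-item counts per raw value of ``attribute`` under the query
    restricted to all *other* attributes (self-exclusion: the attribute's
    own selections never narrow its own drop-down).  Null cells are counted
    under the ``n/d`` key."""
    _check_attribute(attribute)
    base = evaluate_query(repo, kb, q.without(attribute), level)
    den = repo.denormalized()
    sub = den[den["item_id"].isin(base.item_ids)]
    col = _col_str(sub, attribute)
    counts: dict[str, int] = {}
    grouped = (sub.assign(_v=col).dropna(subset=["_v"])
               .groupby("_v")["item_id"].nunique())
    for v, n in grouped.items():
        counts[str(v)] = int(n)
    nd = sub.loc[col.isna(), "item_id"].nunique()
    if nd:
        counts[ND] = int(nd)
    return counts


# --------------------------------------------------------------------------
# Key-value search
# --------------------------------------------------------------------------

def _pair_matches(rp: pd.DataFrame, key: str, values: list[str],
                  exact: bool) -> pd.Series:
    mask = rp["key"] == key
    if exact:
        vmask = rp["value"].isin(values)
    else:
        vmask = pd.Series(False, index=rp.index)
        for v in values:
            vmask = vmask | rp["value"].str.contains(re.escape(v), na=False)
    return mask & vmask


def evaluate_kv_step(repo: Repository, predicates) -> ResultSet:
    """Evaluate one key-value step: predicates in the step are OR-ed."""
    rp = repo.raw_pairs
    hits: set[int] = set()
    for pred in predicates:
        if not pred.pairs:
            raise ValueError(f"predicate {pred.name!r} has no selected pairs")
        for key, values in pred.pairs.items():
            m = _pair_matches(rp, key, values, pred.exact)
            hits |= set(int(i) for i in rp.loc[m, "item_id"])
    logger.info(json.dumps({"op": "evaluate_kv_step",
                            "n_predicates": len(list(predicates)),
                            "n_items": len(hits)}))
    return ResultSet(frozenset(hits))


def evaluate_session(repo: Repository, kb: KnowledgeBase,
                     session: QuerySession) -> ResultSet:
    """Intersection of the per-step results (order-independent)."""
    result = repo.all_item_ids()
    for step in session.steps:
        if isinstance(step, FacetedStep):
            part = evaluate_query(repo, kb, step.query, session.level)
        else:
            part = evaluate_kv_step(repo, step.predicates)
        result &= part.item_ids
    return ResultSet(frozenset(result))


# --------------------------------------------------------------------------
# Key / value exploration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreKeyMatch:
    attribute: str
    distinct_values: int
    examples: tuple[str, ...]


@dataclass(frozen=True)
class RawKeyMatch:
    key: str
    distinct_values: int


@dataclass(frozen=True)
class KeySearchResult:
    core: tuple[CoreKeyMatch, ...]
    raw: tuple[RawKeyMatch, ...]


@dataclass(frozen=True)
class CoreValueMatch:
    attribute: str
    value: str
    item_count: int


@dataclass(frozen=True)
class RawValueMatch:
    key: str
    value: str
    item_count: int


@dataclass(frozen=True)
class ValueSearchResult:
    core: tuple[CoreValueMatch, ...]
    raw: tuple[RawValueMatch, ...]


def _name_matches(name: str, pattern: str, exact: bool) -> bool:
    return name == pattern if exact else pattern in name


def key_search(repo: Repository, pattern: str, exact: bool = False,
               n_examples: int = 5) -> KeySearchResult:
    """Search attribute names: core attributes come back with their
    distinct-value count and a few example values, raw keys with their
    distinct-value count."""
    pattern = norm(pattern)
    if not pattern:
        raise ValueError("pattern must be non-empty")
    den = repo.denormalized()
    core = []
    for attr in SEARCHABLE_ATTRIBUTES:
        if not _name_matches(attr, pattern, exact):
            continue
        col = _col_str(den, attr).dropna() if not den.empty else pd.Series(dtype=object)
        values = sorted(set(col))
        core.append(CoreKeyMatch(attr, len(values),
                                 tuple(values[:n_examples])))
    raw = []
    rp = repo.raw_pairs
    if not rp.empty:
        grouped = rp.groupby("key")["value"].nunique()
        for key, n in sorted(grouped.items()):
            if _name_matches(str(key), pattern, exact):
                raw.append(RawKeyMatch(str(key), int(n)))
    return KeySearchResult(tuple(core), tuple(raw))


def raw_values_for_key(repo: Repository, key: str) -> list[str]:
    """Distinct values available for a raw key (for drop-down selection)."""
    rp = repo.raw_pairs
    return sorted(set(rp.loc[rp["key"] == norm(key), "value"].dropna()))


def value_search(repo: Repository, pattern: str,
                 exact: bool = False) -> ValueSearchResult:
    """Search attribute *values*, over core attributes and raw pairs alike;
    returns (key, value) candidates ready for selection."""
    pattern = norm(pattern)
    if not pattern:
        raise ValueError("pattern must be non-empty")
    den = repo.denormalized()
    core = []
    for attr in SEARCHABLE_ATTRIBUTES:
        if den.empty:
            break
        col = _col_str(den, attr)
        mask = (col == pattern) if exact else col.str.contains(
            re.escape(pattern), na=False)
        if not mask.any():
            continue
        grouped = (den[mask].assign(_v=col[mask])
                   .groupby("_v")["item_id"].nunique())
        for v, n in sorted(grouped.items()):
            core.append(CoreValueMatch(attr, str(v), int(n)))
    raw = []
    rp = repo.raw_pairs
    if not rp.empty:
        mask = (rp["value"] == pattern) if exact else rp["value"].str.contains(
            re.escape(pattern), na=False)
        grouped = (rp[mask].groupby(["key", "value"])["item_id"].nunique())
        for (k, v), n in sorted(grouped.items()):
            raw.append(RawValueMatch(str(k), str(v), int(n)))
    return ValueSearchResult(tuple(core), tuple(raw))


# --------------------------------------------------------------------------
# Keyword search with deduction chains
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemHop:
    def render(self) -> str:
        return "<Item>"


@dataclass(frozen=True)
class EntityHop:
    entity: str

    def render(self) -> str:
        return f"<{self.entity}>"


@dataclass(frozen=True)
class RawPairHop:
    key: str
    value: str

    def render(self) -> str:
        return f"<Key: {self.key}, Value: {self.value}>"


@dataclass(frozen=True)
class EntityAttrHop:
    entity: str
    attribute: str
    value: str

    def render(self) -> str:
        return f"<{self.entity}.{self.attribute}: {self.value}>"


@dataclass(frozen=True)
class TermHop:
    code: str
    label: str

    def render(self) -> str:
        return f"<Vocabulary: {self.label}, {self.code}>"


@dataclass(frozen=True)
class DeductionChain:
    """The explained inference path from an item to the matched keyword:
    hops joined by edges labelled FK, ANNOTATED-BY, SYNONYM-OF, IS_A or
    PART_OF.  The first hop is always the Item."""

    hops: tuple
    edges: tuple[str, ...]

    def render(self) -> str:
        parts = [self.hops[0].render()]
        for hop, edge in zip(self.hops[1:], self.edges):
            if edge in (IS_A.upper(), PART_OF.upper()):
                parts.append(f" -[{edge}]- ")
            else:
                parts.append(" - ")
            parts.append(hop.render())
        return "".join(parts)


def _attr_chain_prefix(attribute: str, value: str):
    """ITEM + FK hops down to the entity owning ``attribute``."""
    table = ATTRIBUTE_TABLE[attribute]
    path = ENTITY_PATHS[table]
    hops: list = [ItemHop()]
    edges: list[str] = []
    for ent in path[1:-1] if len(path) > 1 else []:
        hops.append(EntityHop(ent))
        edges.append("FK")
    hops.append(EntityAttrHop(path[-1], attribute, value))
    # item-level attributes hang off the Item itself rather than an FK hop
    edges.append("FK" if len(path) > 1 else "ATTRIBUTE")
    return hops, edges


def _term_hop(kb: KnowledgeBase, tid: int) -> TermHop:
    t = kb.term(tid)
    return TermHop(code=str(t["code"]).upper(), label=str(t["pref_label"]))


def _chain_for_path(kb: KnowledgeBase, attribute: str, value: str,
                    path: list[tuple[int, str | None]]) -> DeductionChain:
    hops, edges = _attr_chain_prefix(attribute, value)
    first = True
    for tid, rel in path:
        hops.append(_term_hop(kb, tid))
        edges.append("ANNOTATED-BY" if first else rel.upper())
        first = False
    return DeductionChain(tuple(hops), tuple(edges))


def _keyword_routes(repo: Repository, kb: KnowledgeBase, keyword: str,
                    level: int, all_paths: bool = False):
    """Yield (DeductionChain, frozenset of item ids) for every distinct
    match route of ``keyword`` at the cumulative search level (1..4)."""
    kw = norm(keyword)
    if not kw:
        raise ValueError("keyword must be non-empty")
    if level not in (1, 2, 3, 4):
        raise ValueError("level must be in 1..4")
    pat = re.escape(kw)
    den = repo.denormalized()

    # Level 1: raw key-value pairs whose key or value contains the keyword.
    rp = repo.raw_pairs
    if not rp.empty:
        mask = (rp["key"].str.contains(pat, na=False)
                | rp["value"].str.contains(pat, na=False))
        for (k, v), grp in rp[mask].groupby(["key", "value"]):
            chain = DeductionChain(
                (ItemHop(), RawPairHop(str(k), str(v))), ("RAW",))
            yield chain, frozenset(int(i) for i in grp["item_id"])

    # Level 2: core attribute values containing the keyword.
    if level >= 2 and not den.empty:
        for attr in SEARCHABLE_ATTRIBUTES:
            col = _col_str(den, attr)
            mask = col.str.contains(pat, na=False)
            if not mask.any():
                continue
            for v, grp in den[mask].assign(_v=col[mask]).groupby("_v"):
                hops, edges = _attr_chain_prefix(attr, str(v))
                yield (DeductionChain(tuple(hops), tuple(edges)),
                       frozenset(int(i) for i in grp["item_id"]))

    # Levels 3-4: vocabulary labels and bounded hierarchical expansion.
    if level >= 3:
        tids = resolve_label(kb, kw)
        clo = kb.closure() if level >= 4 else None
        for attr in ENRICHED_ATTRIBUTES:
            if den.empty:
                break
            tid_col = den[f"{attr}_tid"]
            col = _col_str(den, attr)
            for t in sorted(tids):
                mask = tid_col == t
                if mask.any():
                    for v, grp in den[mask].assign(_v=col[mask]).groupby("_v"):
                        yield (_chain_for_path(kb, attr, str(v), [(t, None)]),
                               frozenset(int(i) for i in grp["item_id"]))
                if level >= 4 and t in clo.nodes:
                    for d in sorted(clo.descendants(t)):
                        dmask = tid_col == d
                        if not dmask.any():
                            continue
                        paths = kb.upward_paths(d, t)
                        if not all_paths:
                            paths = paths[:1]
                        for v, grp in (den[dmask].assign(_v=col[dmask])
                                       .groupby("_v")):
                            ids = frozenset(int(i) for i in grp["item_id"])
                            for p in paths:
                                yield (_chain_for_path(kb, attr, str(v), p),
                                       ids)


def keyword_search(repo: Repository, kb: KnowledgeBase, keyword: str,
                   level: int) -> dict[str, frozenset[int]]:
    """Keyword search at cumulative level 1..4, grouped by deduction-chain
    signature (the rendered chain shape).  An item may appear under several
    signatures but is deduplicated in any total taken over the union."""
    groups: dict[str, set[int]] = {}
    for chain, ids in _keyword_routes(repo, kb, keyword, level):
        groups.setdefault(chain.render(), set()).update(ids)
    out = {sig: frozenset(ids) for sig, ids in groups.items()}
    logger.info(json.dumps({"op": "keyword_search", "keyword": norm(keyword),
                            "level": level, "n_groups": len(out),
                            "n_items": len(frozenset().union(*out.values()))
                            if out else 0}))
    return out


def explain(repo: Repository, kb: KnowledgeBase, item_id: int, keyword: str,
            level: int) -> list[DeductionChain]:
    """All deduction chains (bounded by the closure depth) linking one item
    to the keyword at the given level; empty iff the item is not in the
    keyword-search result."""
    if item_id not in repo.all_item_ids():
        raise KeyError(f"unknown item id {item_id}")
    chains = []
    seen = set()
    for chain, ids in _keyword_routes(repo, kb, keyword, level,
                                      all_paths=True):
        if item_id in ids and chain not in seen:
            seen.add(chain)
            chains.append(chain)
    return chains


# --------------------------------------------------------------------------
# Result summarization and rendering
# --------------------------------------------------------------------------

def summarize(repo: Repository, result: ResultSet
              ) -> tuple[dict[str, int], dict[str, int]]:
    """Per-source and per-dataset item counts for a result set.  Both maps
    partition the result (each item lands in exactly one bucket; items with
    no source or dataset fall under ``n/d``), so bucket counts sum to the
    result cardinality."""
    den = repo.denormalized()
    sub = den[den["item_id"].isin(result.item_ids)]

    def partition(colname: str) -> dict[str, int]:
        per_item: dict[int, str] = {}
        for iid, v in zip(sub["item_id"], sub[colname]):
            iid = int(iid)
            v = None if pd.isna(v) else str(v)
            if v is not None and (iid not in per_item or v < per_item[iid]):
                per_item[iid] = v
        counts: dict[str, int] = {}
        for iid in result.item_ids:
            bucket = per_item.get(int(iid), ND)
            counts[bucket] = counts.get(bucket, 0) + 1
        return counts

    if not result.item_ids:
        return {}, {}
    return partition("source"), partition("dataset_name")


def _result_frame(repo: Repository, result: ResultSet, mode: str,
                  sort_keys=None, columns=None) -> pd.DataFrame:
    mode = mode.lower()
    if mode not in ("replicated", "aggregated"):
        raise ValueError("mode must be 'replicated' or 'aggregated'")
    den = repo.denormalized()
    rows = den[den["item_id"].isin(result.item_ids)]
    if mode == "aggregated" and not rows.empty:
        def agg(series: pd.Series):
            vals = sorted({str(v) for v in series.dropna()})
            return "|".join(vals) if vals else None
        rows = rows.groupby("item_id", as_index=False).agg(agg)
    if columns:
        missing = [c for c in columns if c not in rows.columns]
        if missing:
            raise UnknownAttributeError(", ".join(missing))
        rows = rows[columns]
    if sort_keys:
        rows = rows.sort_values(list(sort_keys), kind="stable")
    else:
        sortable = [c for c in ("item_id", "item_source_id")
                    if c in rows.columns]
        if sortable:
            rows = rows.sort_values(sortable[:1], kind="stable")
    return rows.reset_index(drop=True)


def render_result_table(repo: Repository, result: ResultSet,
                        mode: str = "aggregated", sort_keys=None,
                        page_size: int = 100, page_index: int = 0,
                        columns=None) -> pd.DataFrame:
    """One page of the result table.

    ``replicated`` shows one row per denormalized join path; ``aggregated``
    one row per item with multi-valued fields pipe-joined over sorted
    distinct values.  The sort is stable and the page size is capped at
    1000 rows.
    """
    if not 1 <= page_size <= MAX_PAGE_SIZE:
        raise ValueError(f"page_size must be in [1, {MAX_PAGE_SIZE}]")
    if page_index < 0:
        raise ValueError("page_index must be >= 0")
    rows = _result_frame(repo, result, mode, sort_keys, columns)
    start = page_index * page_size
    return rows.iloc[start:start + page_size].reset_index(drop=True)
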