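"""Multi-ontology knowledge base: vocabulary, synonyms, cross-references,
is_a / part_of relationships and their depth-bounded unfolded closure.

Ontology fragments (UBERON, EFO, NCIT, OGG, ...) are stored relationally:
a *Vocabulary* table of terms, a *Synonym* table of alternative labels, a
*Reference* table of equivalent terms in other ontologies and a
*Relationship* table of directed edges, each either a generalization
(``is_a``) or a containment (``part_of``).  For query expansion the edge
set is *unfolded* into a materialized ancestor/descendant closure bounded
by a configurable depth (default 3 levels up or down), with the minimum
hop distance stored per pair.  ``is_a`` and ``part_of`` are traversed
interchangeably during unfolding; the per-edge type is retained only for
explanation output.

Curated *annotation maps* link raw attribute values of the repository's 10
enriched attributes to vocabulary terms.
"""

from __future__ import annotations

import json
import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .model import ENRICHED_ATTRIBUTES, norm

__all__ = [
    "IS_A",
    "PART_OF",
    "RelationshipEdge",
    "RelationshipClosure",
    "KnowledgeBase",
    "CycleError",
    "unfold",
    "resolve_label",
    "descendants",
    "ancestors",
    "annotate_value",
    "read_obo",
]

IS_A = "is_a"
PART_OF = "part_of"

#: Default traversal bound for the unfolded closure (hierarchy levels).
DEFAULT_MAX_DEPTH = 3


class CycleError(ValueError):
    """The relationship edges contain a directed cycle (fragments must be
    acyclic); the message names one offending cycle."""


@dataclass(frozen=True)
class RelationshipEdge:
    parent: int
    child: int
    rel_type: str  # IS_A or PART_OF


@dataclass
class RelationshipClosure:
    """Unfolded ancestor/descendant pairs with minimum hop distance."""

    max_depth: int
    pairs: dict[tuple[int, int], int]          # (ancestor, descendant) -> dist
    nodes: frozenset[int]
    _desc: dict[int, dict[int, int]] = field(default_factory=dict, repr=False)
    _anc: dict[int, dict[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for (a, d), dist in self.pairs.items():
            self._desc.setdefault(a, {})[d] = dist
            self._anc.setdefault(d, {})[a] = dist

    def descendants(self, tid: int, depth: int | None = None) -> set[int]:
        depth = self._check(tid, depth)
        return {d for d, dist in self._desc.get(tid, {}).items()
                if dist <= depth}

    def ancestors(self, tid: int, depth: int | None = None) -> set[int]:
        depth = self._check(tid, depth)
        return {a for a, dist in self._anc.get(tid, {}).items()
                if dist <= depth}

    def _check(self, tid: int, depth: int | None) -> int:
        if tid not in self.nodes:
            raise KeyError(f"unknown term id {tid}")
        if depth is None:
            depth = self.max_depth
        if not 1 <= depth <= self.max_depth:
            raise ValueError(
                f"depth must be in [1, {self.max_depth}], got {depth}")
        return depth


def unfold(edges, max_depth: int = DEFAULT_MAX_DEPTH) -> RelationshipClosure:
    """Materialize the depth-bounded transitive closure of the edge set.

    ``(a, d)`` is present iff a directed path of length <= ``max_depth``
    leads from descendant ``d`` up to ancestor ``a``, mixing ``is_a`` and
    ``part_of`` freely; the stored distance is the minimum such length.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    edges = list(edges)
    up: dict[int, list[int]] = {}
    nodes: set[int] = set()
    g = nx.DiGraph()
    for e in edges:
        if e.parent == e.child:
            raise CycleError(f"self edge on term {e.parent}")
        up.setdefault(e.child, []).append(e.parent)
        nodes.add(e.parent)
        nodes.add(e.child)
        g.add_edge(e.child, e.parent)
    try:
        cyc = nx.find_cycle(g)
        raise CycleError("relationship cycle: " +
                         " -> ".join(str(a) for a, _ in cyc))
    except nx.NetworkXNoCycle:
        pass

    pairs: dict[tuple[int, int], int] = {}
    for d in nodes:
        seen = {d: 0}
        q = deque([d])
        while q:
            cur = q.popleft()
            if seen[cur] >= max_depth:
                continue
            for p in up.get(cur, ()):
                if p not in seen:
                    seen[p] = seen[cur] + 1
                    pairs[(p, d)] = seen[p]
                    q.append(p)
    return RelationshipClosure(max_depth=max_depth, pairs=pairs,
                               nodes=frozenset(nodes))


def _empty(cols: list[str], int_cols: set[str] = frozenset()) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="Int64" if c in int_cols else "object")
                         for c in cols})


@dataclass
class KnowledgeBase:
    """Vocabulary + synonyms + references + relationships + annotation map."""

    vocabulary: pd.DataFrame = field(default_factory=lambda: _empty(
        ["tid", "ontology_source", "code", "pref_label", "description", "iri"],
        {"tid"}))
    synonyms: pd.DataFrame = field(default_factory=lambda: _empty(
        ["tid", "label", "syn_type"], {"tid"}))
    references: pd.DataFrame = field(default_factory=lambda: _empty(
        ["tid", "ext_source", "ext_code"], {"tid"}))
    relationships: pd.DataFrame = field(default_factory=lambda: _empty(
        ["parent", "child", "rel_type"], {"parent", "child"}))
    annotations: pd.DataFrame = field(default_factory=lambda: _empty(
        ["attribute", "raw_value", "tid"], {"tid"}))
    max_depth: int = DEFAULT_MAX_DEPTH

    # -- derived indexes (built lazily; the KB is immutable once built) ----

    def edges(self) -> list[RelationshipEdge]:
        return [RelationshipEdge(int(r.parent), int(r.child), str(r.rel_type))
                for r in self.relationships.itertuples()]

    def closure(self) -> RelationshipClosure:
        clo = getattr(self, "_closure", None)
        if clo is None:
            clo = unfold(self.edges(), self.max_depth)
            object.__setattr__(self, "_closure", clo)
        return clo

    def _label_index(self) -> dict[str, set[int]]:
        idx = getattr(self, "_labels", None)
        if idx is None:
            idx = {}
            for r in self.vocabulary.itertuples():
                lab = norm(r.pref_label)
                if lab:
                    idx.setdefault(lab, set()).add(int(r.tid))
            for r in self.synonyms.itertuples():
                lab = norm(r.label)
                if lab:
                    idx.setdefault(lab, set()).add(int(r.tid))
            object.__setattr__(self, "_labels", idx)
        return idx

    def _annotation_index(self) -> dict[tuple[str, str], int]:
        idx = getattr(self, "_ann", None)
        if idx is None:
            idx = {(str(r.attribute), norm(r.raw_value)): int(r.tid)
                   for r in self.annotations.itertuples()}
            object.__setattr__(self, "_ann", idx)
        return idx

    def tid_of(self, code: str) -> int:
        hits = self.vocabulary[self.vocabulary["code"] == norm(code)]
        if hits.empty:
            raise KeyError(f"unknown ontology code {code!r}")
        return int(hits.iloc[0]["tid"])

    def term(self, tid: int) -> dict:
        hits = self.vocabulary[self.vocabulary["tid"] == tid]
        if hits.empty:
            raise KeyError(f"unknown term id {tid}")
        return hits.iloc[0].to_dict()

    def upward_paths(self, start: int, goal: int,
                     max_len: int | None = None) -> list[list[tuple[int, str | None]]]:
        """All simple child->parent paths of length <= ``max_len`` from
        ``start`` up to ``goal``; each path is a list of ``(tid, rel)`` with
        ``rel`` the edge type taken into that node (None for the start).
        Paths are sorted by (length, intermediate codes) so ties break
        deterministically."""
        if max_len is None:
            max_len = self.max_depth
        up: dict[int, list[tuple[int, str]]] = {}
        for e in self.edges():
            up.setdefault(e.child, []).append((e.parent, e.rel_type))
        out: list[list[tuple[int, str | None]]] = []

        def walk(node: int, path: list[tuple[int, str | None]]) -> None:
            if node == goal and len(path) > 1:
                out.append(list(path))
                return
            if len(path) > max_len:
                return
            for parent, rel in sorted(up.get(node, ()),
                                      key=lambda pr: self.term(pr[0])["code"]):
                if any(parent == t for t, _ in path):
                    continue
                path.append((parent, rel))
                walk(parent, path)
                path.pop()

        walk(start, [(start, None)])
        out.sort(key=lambda p: (len(p),
                                tuple(self.term(t)["code"] for t, _ in p)))
        return out

    # -- persistence -------------------------------------------------------

    _FILES = {
        "vocabulary": "vocabulary.tsv", "synonyms": "synonym.tsv",
        "references": "reference.tsv", "relationships": "relationship.tsv",
        "annotations": "annotation.tsv",
    }

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            df = getattr(self, attr).copy()
            for c in df.columns:
                df[c] = df[c].map(lambda v: "" if pd.isna(v) else str(v))
            df.to_csv(directory / fname, sep="\t", index=False)
        meta = directory / "kb.json"
        meta.write_text(json.dumps({"max_depth": self.max_depth}))
        return meta

    @classmethod
    def load(cls, directory: str | Path) -> "KnowledgeBase":
        directory = Path(directory)
        frames = {}
        for attr, fname in cls._FILES.items():
            path = directory / fname
            tmpl = getattr(cls(), attr)
            if not path.exists():
                frames[attr] = tmpl
                continue
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
            out = {}
            for c in tmpl.columns:
                if str(tmpl[c].dtype) == "Int64":
                    out[c] = pd.array(
                        [None if norm(v) is None else int(float(v))
                         for v in df[c]], dtype="Int64")
                else:
                    out[c] = pd.array([norm(v) for v in df[c]], dtype="object")
            frames[attr] = pd.DataFrame(out)
        meta = directory / "kb.json"
        depth = DEFAULT_MAX_DEPTH
        if meta.exists():
            depth = int(json.loads(meta.read_text()).get(
                "max_depth", DEFAULT_MAX_DEPTH))
        return cls(max_depth=depth, **frames)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def resolve_label(kb: KnowledgeBase, label: str) -> set[int]:
    """Term ids whose preferred label or any synonym equals the query label
    (case-insensitively, whitespace-normalized); empty set when none."""
    lab = norm(label)
    if lab is None:
        return set()
    return set(kb._label_index().get(lab, ()))


def descendants(closure: RelationshipClosure, tid: int,
                depth: int | None = None) -> set[int]:
    """All term ids at distance <= depth below the given term (excluded)."""
    return closure.descendants(tid, depth)


def ancestors(closure: RelationshipClosure, tid: int,
              depth: int | None = None) -> set[int]:
    """All term ids at distance <= depth above the given term (excluded)."""
    return closure.ancestors(tid, depth)


def annotate_value(kb: KnowledgeBase, attribute: str,
                   raw_value: str) -> int | None:
    """Curated-annotation lookup for an enriched attribute value; ``None``
    when the value is unmapped (the item then matches only at the Original
    level)."""
    if attribute not in ENRICHED_ATTRIBUTES:
        raise ValueError(f"attribute {attribute!r} is not semantically "
                         f"enriched")
    return kb._annotation_index().get((attribute, norm(raw_value)))


# --------------------------------------------------------------------------
# OBO convenience reader
# --------------------------------------------------------------------------

_SYN_RE = re.compile(r'"(?P<label>[^"]*)"\s*(?P<scope>[A-Z_]*)')


def read_obo(path: str | Path, max_depth: int = DEFAULT_MAX_DEPTH) -> KnowledgeBase:
    """Read an OBO flat file (via :mod:`obonet`) into a knowledge base,
    extracting term ids, names, synonyms, xrefs, ``is_a`` edges and
    ``relationship: part_of`` edges.  Annotation maps are curated inputs
    and load separately."""
    import obonet

    graph = obonet.read_obo(str(path))
    vocab, syns, refs, rels = [], [], [], []
    tid_by_curie: dict[str, int] = {}
    for i, (curie, data) in enumerate(sorted(graph.nodes(data=True)), start=1):
        source = curie.split(":", 1)[0]
        code = curie.replace(":", "_")
        tid_by_curie[curie] = i
        vocab.append({"tid": i, "ontology_source": norm(source),
                      "code": norm(code),
                      "pref_label": norm(data.get("name", code)),
                      "description": norm(data.get("def")),
                      "iri": None})
        for s in data.get("synonym", ()):
            m = _SYN_RE.match(s)
            if m:
                syns.append({"tid": i, "label": norm(m.group("label")),
                             "syn_type": norm(m.group("scope")) or "related"})
        for x in data.get("xref", ()):
            src, _, cde = x.partition(":")
            refs.append({"tid": i, "ext_source": norm(src),
                         "ext_code": norm(cde)})
    # obonet edges run child -> parent with the relation as key
    for child, parent, rel in graph.edges(keys=True):
        if rel not in (IS_A, PART_OF):
            continue
        if child in tid_by_curie and parent in tid_by_curie:
            rels.append({"parent": tid_by_curie[parent],
                         "child": tid_by_curie[child], "rel_type": rel})

    def frame(rows, cols, int_cols):
        if not rows:
            return _empty(cols, int_cols)
        df = pd.DataFrame(rows, columns=cols)
        for c in int_cols:
            df[c] = df[c].astype("Int64")
        return df

    return KnowledgeBase(
        vocabulary=frame(vocab, ["tid", "ontology_source", "code",
                                 "pref_label", "description", "iri"], {"tid"}),
        synonyms=frame(syns, ["tid", "label", "syn_type"], {"tid"}),
        references=frame(refs, ["tid", "ext_source", "ext_code"], {"tid"}),
        relationships=frame(rels, ["parent", "child", "rel_type"],
                            {"parent", "child"}),
        max_depth=max_depth,
    )
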