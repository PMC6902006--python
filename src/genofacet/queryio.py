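"""JSON query dialect and the human-readable "Selected query" rendering.

A query document looks like::

    {"gcm":  {"disease": ["prostate adenocarcinoma"], "assembly": ["grch38"]},
     "type": "original",
     "kv":   {"fdr_0": {"type_query": "key", "exact": false,
                        "query": {"gcm": {},
                                  "pairs": {"manually_curated__fdr_threshold":
                                            ["0.01"]}}}}}

The ``gcm`` block becomes one faceted step, each ``kv`` entry one
key-value step, and ``type`` (defaulting to ``original``) sets the
semantic level of the whole session.  Strict JSON is emitted and accepted;
round trips are lossless up to key ordering and value normalization.
"""

from __future__ import annotations

import json

from .engine import (FacetedQuery, FacetedStep, KeyValuePredicate,
                     KeyValueStep, QuerySession, SemanticLevel,
                     UnknownAttributeError)
from .model import SEARCHABLE_ATTRIBUTES, norm

__all__ = [
    "QueryParseError",
    "parse_query",
    "serialize_query",
    "render_selected_query",
    "normalize_document",
]

_LEVELS = {"original": SemanticLevel.ORIGINAL,
           "synonym": SemanticLevel.SYNONYM,
           "expanded": SemanticLevel.EXPANDED}


class QueryParseError(ValueError):
    """Invalid query document; ``path`` locates the offending element."""

    def __init__(self, message: str, path: str):
        super().__init__(f"{path}: {message}")
        self.path = path


def _norm_values(values, path: str) -> list[str]:
    if not isinstance(values, list) or not values:
        raise QueryParseError("expected a non-empty list of values", path)
    return [norm(v) for v in values]


def parse_query(document: str | dict) -> QuerySession:
    """Parse a JSON query document (text or already-decoded object) into a
    query session."""
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise QueryParseError(f"invalid JSON: {exc}", "$") from None
    if not isinstance(document, dict):
        raise QueryParseError("expected a JSON object", "$")

    level_str = str(document.get("type", "original")).strip().lower()
    if level_str not in _LEVELS:
        raise QueryParseError(
            f"unknown level {level_str!r} (expected original, synonym or "
            f"expanded)", "type")
    level = _LEVELS[level_str]

    gcm = document.get("gcm", {})
    if not isinstance(gcm, dict):
        raise QueryParseError("expected an object", "gcm")
    steps: list = []
    if gcm:
        selections = {}
        for attr, values in gcm.items():
            if attr not in SEARCHABLE_ATTRIBUTES:
                raise QueryParseError(f"unknown attribute {attr!r}",
                                      f"gcm.{attr}")
            selections[attr] = _norm_values(values, f"gcm.{attr}")
        try:
            steps.append(FacetedStep(FacetedQuery(selections)))
        except UnknownAttributeError as exc:  # pragma: no cover - pre-checked
            raise QueryParseError(str(exc), "gcm") from None

    kv = document.get("kv", {})
    if not isinstance(kv, dict):
        raise QueryParseError("expected an object", "kv")
    for name, entry in kv.items():
        path = f"kv.{name}"
        if not isinstance(entry, dict):
            raise QueryParseError("expected an object", path)
        mode = str(entry.get("type_query", "key")).strip().lower()
        if mode not in ("key", "value"):
            raise QueryParseError(f"unknown type_query {mode!r}",
                                  f"{path}.type_query")
        exact = bool(entry.get("exact", True))
        query = entry.get("query", {})
        if not isinstance(query, dict):
            raise QueryParseError("expected an object", f"{path}.query")
        pairs_in = query.get("pairs", {})
        if not isinstance(pairs_in, dict):
            raise QueryParseError("expected an object", f"{path}.query.pairs")
        pairs = {norm(k): _norm_values(v, f"{path}.query.pairs.{k}")
                 for k, v in pairs_in.items()}
        ctx = query.get("gcm", {})
        if not isinstance(ctx, dict):
            raise QueryParseError("expected an object", f"{path}.query.gcm")
        ctx_t = tuple(sorted((norm(a), tuple(norm(v) for v in vs))
                             for a, vs in ctx.items()))
        pred = KeyValuePredicate(name=name, mode=mode, exact=exact,
                                 pairs=pairs)
        steps.append(KeyValueStep(predicates=(pred,), name=name,
                                  context_gcm=ctx_t))
    return QuerySession(steps=tuple(steps), level=level)


def serialize_query(session: QuerySession) -> str:
    """Inverse of :func:`parse_query` up to formatting: gcm keys come out in
    registry order, kv entries in insertion order."""
    gcm: dict[str, list[str]] = {}
    kv: dict[str, dict] = {}
    n_faceted = 0
    for step in session.steps:
        if isinstance(step, FacetedStep):
            n_faceted += 1
            if n_faceted > 1:
                raise ValueError("the JSON dialect carries a single gcm "
                                 "block; merge faceted steps first")
            for attr in SEARCHABLE_ATTRIBUTES:
                if attr in step.query.selections:
                    gcm[attr] = list(step.query.selections[attr])
        else:
            for pred in step.predicates:
                kv[step.name or pred.name] = {
                    "type_query": pred.mode,
                    "exact": pred.exact,
                    "query": {
                        "gcm": {a: list(vs) for a, vs in step.context_gcm},
                        "pairs": {k: list(vs)
                                  for k, vs in pred.pairs.items()},
                    },
                }
    doc = {"gcm": gcm,
           "type": session.level.name.lower(),
           "kv": kv}
    return json.dumps(doc, indent=1)


def normalize_document(document: str | dict) -> dict:
    """Canonical form of a query document (the fixed point of
    parse -> serialize), used to compare documents for equality."""
    return json.loads(serialize_query(parse_query(document)))


def render_selected_query(q: FacetedQuery | dict) -> str:
    """Render the running "Selected query" line, e.g.
    ``assembly: [grch38], data_type: [copy number segment, masked copy
    number segment], tissue: [kidney]``.  Attributes appear in fixed
    registry order; values keep their selection order."""
    if isinstance(q, dict):
        q = FacetedQuery(q)
    parts = []
    for attr in SEARCHABLE_ATTRIBUTES:
        if attr in q.selections:
            parts.append(f"{attr}: [{', '.join(q.selections[attr])}]")
    return ", ".join(parts)
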