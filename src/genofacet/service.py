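"""Service layer: the API-shaped operations behind the search front end.

Each function is a pure function of (repository, knowledge base, payload)
— repeated calls return identical output — and returns plain JSON-ready
dicts or text, mirroring the POST ``/field/{field_name}``, POST
``/query``, POST ``/explain`` and GET ``/download/{links|table}``
endpoints of the original deployment.  Any HTTP framework can wrap them;
the bundled command-line front end (:mod:`genofacet.cli`) calls them
directly.
"""

from __future__ import annotations

import io

import pandas as pd

from .engine import (QuerySession, ResultSet, UnknownAttributeError,
                     _result_frame, evaluate_session, explain,
                     render_result_table, summarize)
from .kb import KnowledgeBase
from .model import SEARCHABLE_ATTRIBUTES, Repository
from .queryio import parse_query

__all__ = [
    "field_counts",
    "export_links",
    "export_table",
    "post_field",
    "post_query",
    "post_explain",
    "download",
]


def _as_session(payload) -> QuerySession:
    if isinstance(payload, QuerySession):
        return payload
    return parse_query(payload)


def _json_value(field_name: str, value: str):
    """Present stored strings with their natural JSON type."""
    if value in ("true", "false"):
        return value == "true"
    try:
        return int(value)
    except (TypeError, ValueError):
        return value


def field_counts(repo: Repository, kb: KnowledgeBase, payload,
                 field_name: str, limit: int | None = None) -> dict:
    """Distinct-item counts of ``field_name``'s values within the result
    set established by the payload.

    Returns ``{"values": [{"value": v, "count": n}, ...], "info":
    {"shown_count", "total_count", "item_count"}}`` with values sorted by
    count descending, ties broken by value ascending.
    """
    if field_name not in SEARCHABLE_ATTRIBUTES:
        raise UnknownAttributeError(field_name)
    session = _as_session(payload)
    result = evaluate_session(repo, kb, session)
    den = repo.denormalized()
    sub = den[den["item_id"].isin(result.item_ids)]
    col = sub[field_name]
    if str(col.dtype) == "Int64":
        col = col.map(lambda v: None if pd.isna(v) else str(int(v)))
    grouped = (sub.assign(_v=col).dropna(subset=["_v"])
               .groupby("_v")["item_id"].nunique())
    entries = sorted(((str(v), int(n)) for v, n in grouped.items()),
                     key=lambda vn: (-vn[1], vn[0]))
    total = len(entries)
    if limit is not None:
        entries = entries[:limit]
    return {
        "values": [{"value": _json_value(field_name, v), "count": n}
                   for v, n in entries],
        "info": {
            "shown_count": len(entries),
            "total_count": total,
            "item_count": len(result),
        },
    }


def export_links(repo: Repository, result: ResultSet) -> str:
    """One download URL per line for every item in the result that has one
    (the repository-local URL is preferred over the source URL), in
    deterministic order by item source accession."""
    items = repo.items[repo.items["item_id"].isin(result.item_ids)]
    items = items.sort_values("item_source_id", kind="stable")
    lines = []
    for r in items.itertuples():
        url = r.local_url if isinstance(r.local_url, str) else None
        url = url or (r.source_url if isinstance(r.source_url, str) else None)
        if url:
            lines.append(url)
    return "\n".join(lines) + ("\n" if lines else "")


def export_table(repo: Repository, result: ResultSet,
                 mode: str = "aggregated", sort_keys=None,
                 columns=None) -> str:
    """The entire result table as CSV (RFC-4180 quoting via pandas)."""
    rows = _result_frame(repo, result, mode, sort_keys, columns)
    buf = io.StringIO()
    rows.to_csv(buf, index=False)
    return buf.getvalue()


# -- endpoint-shaped wrappers ----------------------------------------------

def post_field(repo: Repository, kb: KnowledgeBase, payload,
               field_name: str) -> dict:
    try:
        return field_counts(repo, kb, payload, field_name)
    except UnknownAttributeError as exc:
        return {"error": f"unknown field {exc.args[0]!r}"}


def post_query(repo: Repository, kb: KnowledgeBase, payload,
               mode: str = "aggregated", page_size: int = 100,
               page_index: int = 0, sort_keys=None) -> dict:
    session = _as_session(payload)
    result = evaluate_session(repo, kb, session)
    sources, datasets = summarize(repo, result)
    page = render_result_table(repo, result, mode=mode, sort_keys=sort_keys,
                               page_size=page_size, page_index=page_index)
    rows = page.astype(object).where(page.notna(), None)
    return {
        "total_items": len(result),
        "source_counts": sources,
        "dataset_counts": datasets,
        "page_index": page_index,
        "rows": rows.to_dict(orient="records"),
    }


def post_explain(repo: Repository, kb: KnowledgeBase, payload,
                 item_source_id: str, keyword: str, level: int) -> dict:
    session = _as_session(payload)
    result = evaluate_session(repo, kb, session)
    hits = repo.items[repo.items["item_source_id"] == item_source_id]
    if hits.empty:
        return {"error": f"unknown item {item_source_id!r}"}
    item_id = int(hits.iloc[0]["item_id"])
    if item_id not in result.item_ids:
        return {"item": item_source_id, "chains": []}
    chains = explain(repo, kb, item_id, keyword, level)
    return {"item": item_source_id,
            "chains": [c.render() for c in chains]}


def download(repo: Repository, kb: KnowledgeBase, payload,
             what: str = "links", mode: str = "aggregated") -> str:
    session = _as_session(payload)
    result = evaluate_session(repo, kb, session)
    if what == "links":
        return export_links(repo, result)
    if what == "table":
        return export_table(repo, result, mode=mode)
    raise ValueError("what must be 'links' or 'table'")
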