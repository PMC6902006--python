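"""Knowledge base: closure unfolding, label resolution, annotation, OBO."""

import numpy as np
import pytest

from genofacet.kb import (IS_A, PART_OF, CycleError, KnowledgeBase,
                          RelationshipEdge, annotate_value, descendants,
                          read_obo, resolve_label, unfold)
from genofacet.model import norm


def _edges(pairs):
    return [RelationshipEdge(p, c, r) for p, c, r in pairs]


def test_unfold_of_no_edges_is_empty():
    clo = unfold([], max_depth=3)
    assert clo.pairs == {}


def test_unfold_uterus_subtree_distances(uterus):
    _, kb = uterus
    clo = kb.closure()
    t_uterus = kb.tid_of("uberon_0000995")
    t_wall = kb.tid_of("uberon_0000459")
    t_endo = kb.tid_of("uberon_0001295")
    # endometrium is part of the uterine wall, itself part of the uterus
    assert clo.pairs[(t_uterus, t_endo)] == 2
    assert clo.pairs[(t_wall, t_endo)] == 1
    assert clo.descendants(t_uterus, 3) == {
        kb.tid_of("uberon_0009853"), kb.tid_of("uberon_0000002"),
        t_wall, t_endo}


def test_descendants_of_a_leaf_is_empty(uterus):
    _, kb = uterus
    clo = kb.closure()
    assert clo.descendants(kb.tid_of("uberon_0001295")) == set()


def test_descendants_rejects_unknown_term_and_bad_depth(uterus):
    _, kb = uterus
    clo = kb.closure()
    with pytest.raises(KeyError):
        descendants(clo, 12345)
    with pytest.raises(ValueError):
        clo.descendants(kb.tid_of("uberon_0000995"), 0)
    with pytest.raises(ValueError):
        clo.descendants(kb.tid_of("uberon_0000995"), 4)


def test_unfold_rejects_cycles():
    with pytest.raises(CycleError):
        unfold(_edges([(1, 2, IS_A), (2, 3, IS_A), (3, 1, PART_OF)]))
    with pytest.raises(CycleError):
        unfold(_edges([(1, 1, IS_A)]))


def _random_edges(seed, n_terms=20):
    rng = np.random.default_rng(seed)
    edges = []
    for child in range(1, n_terms):
        for p in rng.choice(child, size=min(int(rng.integers(0, 3)), child),
                            replace=False):
            rel = IS_A if rng.random() < 0.5 else PART_OF
            edges.append(RelationshipEdge(int(p), child, rel))
    return list(set(edges))


def _bfs_oracle(edges, max_depth):
    """Independent oracle: exhaustive path enumeration, min distance."""
    up = {}
    for e in edges:
        up.setdefault(e.child, set()).add(e.parent)
    best = {}

    def walk(origin, node, dist):
        if dist > max_depth:
            return
        if node != origin:
            key = (node, origin)
            if key in best and best[key] <= dist:
                return
            best[key] = dist
        for p in up.get(node, ()):
            walk(origin, p, dist + 1)

    nodes = {e.parent for e in edges} | {e.child for e in edges}
    for n in nodes:
        walk(n, n, 0)
    return best


@pytest.mark.parametrize("seed", range(10))
def test_closure_matches_path_enumeration_oracle(seed):
    edges = _random_edges(seed)
    for depth in (1, 2, 3):
        clo = unfold(edges, max_depth=depth)
        assert clo.pairs == _bfs_oracle(edges, depth)


@pytest.mark.parametrize("seed", range(5))
def test_closure_is_monotone_in_depth(seed):
    edges = _random_edges(seed)
    prev = set()
    for depth in (1, 2, 3, 4):
        cur = set(unfold(edges, max_depth=depth).pairs)
        assert prev <= cur
        prev = cur


@pytest.mark.parametrize("seed", range(5))
def test_closure_pairs_are_fixed_under_depth_one_reunfolding(seed):
    clo = unfold(_random_edges(seed), max_depth=3)
    implied = [RelationshipEdge(a, d, IS_A) for (a, d) in clo.pairs]
    again = unfold(implied, max_depth=1)
    assert set(again.pairs) == set(clo.pairs)
    assert all(v == 1 for v in again.pairs.values())


# -- label resolution ------------------------------------------------------


def test_resolve_label_examples(uterus, boris):
    _, kb = uterus
    assert resolve_label(kb, "corpus uteri") == {kb.tid_of("uberon_0009853")}
    assert resolve_label(kb, "  Corpus   UTERI ") == \
        {kb.tid_of("uberon_0009853")}
    assert resolve_label(kb, "no such thing") == set()
    _, kb_b = boris
    assert resolve_label(kb_b, "boris") == {kb_b.tid_of("ogg_3000140690")}


def test_resolve_label_agrees_with_linear_scan(small_random):
    _, kb, _ = small_random
    labels = set(kb.vocabulary["pref_label"]) | set(kb.synonyms["label"])
    for lab in sorted(labels):
        expected = set(
            int(r.tid) for r in kb.vocabulary.itertuples()
            if norm(r.pref_label) == norm(lab)) | set(
            int(r.tid) for r in kb.synonyms.itertuples()
            if norm(r.label) == norm(lab))
        assert resolve_label(kb, lab) == expected


# -- annotation map --------------------------------------------------------


def test_annotate_value_examples(uterus, k562):
    _, kb = uterus
    assert annotate_value(kb, "tissue", "uterus nos") == \
        kb.tid_of("uberon_0000995")
    assert annotate_value(kb, "tissue", "unmapped-value") is None
    _, kb_k = k562
    assert annotate_value(kb_k, "cell", "K562 Leukemia Cells") == \
        kb_k.tid_of("efo_0002067")


def test_annotate_value_rejects_non_enriched_attributes(uterus):
    _, kb = uterus
    with pytest.raises(ValueError):
        annotate_value(kb, "pipeline", "hotspot")


# -- OBO reader and persistence -------------------------------------------

_OBO = """format-version: 1.2

[Term]
id: UBERON:0000995
name: uterus
synonym: "uterus NOS" RELATED []

[Term]
id: UBERON:0000459
name: uterine wall
is_a: UBERON:0000995

[Term]
id: UBERON:0001295
name: endometrium
synonym: "endometrial" RELATED []
xref: NCIT:C12313
relationship: part_of UBERON:0000459
"""


def test_read_obo_extracts_terms_synonyms_and_edges(tmp_path):
    path = tmp_path / "frag.obo"
    path.write_text(_OBO)
    kb = read_obo(path)
    assert len(kb.vocabulary) == 3
    assert resolve_label(kb, "uterus nos") == {kb.tid_of("uberon_0000995")}
    rels = {(int(r.parent), int(r.child), r.rel_type)
            for r in kb.relationships.itertuples()}
    assert (kb.tid_of("uberon_0000995"), kb.tid_of("uberon_0000459"),
            IS_A) in rels
    assert (kb.tid_of("uberon_0000459"), kb.tid_of("uberon_0001295"),
            PART_OF) in rels
    assert kb.closure().descendants(kb.tid_of("uberon_0000995")) == {
        kb.tid_of("uberon_0000459"), kb.tid_of("uberon_0001295")}
    refs = {(r.ext_source, r.ext_code) for r in kb.references.itertuples()}
    assert ("ncit", "c12313") in refs


def test_kb_save_load_round_trip(tmp_path, uterus):
    _, kb = uterus
    kb.save(tmp_path)
    again = KnowledgeBase.load(tmp_path)
    assert again.max_depth == kb.max_depth
    for attr in ("vocabulary", "synonyms", "references", "relationships",
                 "annotations"):
        assert getattr(kb, attr).equals(getattr(again, attr)), attr
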