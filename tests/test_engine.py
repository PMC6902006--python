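"""Search engine: semantic matching, facets, sessions, keywords, chains."""

import pytest

from genofacet.engine import (FacetedQuery, FacetedStep, KeyValuePredicate,
                              KeyValueStep, QuerySession, ResultSet,
                              SemanticLevel, UnknownAttributeError,
                              evaluate_kv_step, evaluate_query,
                              evaluate_session, explain, facet_counts,
                              key_search, keyword_search, match_items,
                              render_result_table, summarize, value_search)
from genofacet.model import ND

ORIG, SYN, EXP = (SemanticLevel.ORIGINAL, SemanticLevel.SYNONYM,
                  SemanticLevel.EXPANDED)


# -- match_items -----------------------------------------------------------


def test_match_items_three_levels_on_uterus(uterus):
    repo, kb = uterus
    assert len(match_items(repo, kb, "tissue", "uterus", ORIG)) == 57
    assert len(match_items(repo, kb, "tissue", "uterus", SYN)) == 1708
    assert len(match_items(repo, kb, "tissue", "uterus", EXP)) == 16851
    assert match_items(repo, kb, "tissue", "nonexistent", EXP) == frozenset()


def test_match_items_is_case_insensitive(uterus):
    repo, kb = uterus
    assert len(match_items(repo, kb, "tissue", "  UTERUS ", ORIG)) == 57


def test_match_items_rejects_unknown_attribute(uterus):
    repo, kb = uterus
    with pytest.raises(UnknownAttributeError):
        match_items(repo, kb, "organ", "uterus", ORIG)


def test_nd_selects_null_valued_items(brain):
    repo, kb = brain
    nd = match_items(repo, kb, "tissue", ND, ORIG)
    den = repo.denormalized()
    assert nd == frozenset(int(i) for i in
                           den.loc[den["tissue"].isna(), "item_id"])
    # the null test does not change with the semantic level
    assert nd == match_items(repo, kb, "tissue", ND, EXP)


# -- evaluate_query --------------------------------------------------------


def test_empty_query_matches_all_items(uterus):
    repo, kb = uterus
    assert len(evaluate_query(repo, kb, FacetedQuery(), ORIG)) == 16851


def test_values_within_attribute_are_disjunctive(uterus):
    repo, kb = uterus
    q = FacetedQuery({"tissue": ["uterus", "uterus nos"]})
    assert len(evaluate_query(repo, kb, q, ORIG)) == 57 + 1651


def test_attributes_combine_conjunctively(prostate):
    repo, kb = prostate
    q = FacetedQuery({"disease": ["prostate adenocarcinoma"],
                      "is_healthy": ["true"]})
    assert len(evaluate_query(repo, kb, q, ORIG)) == 1278


# -- facet counts ----------------------------------------------------------

TABLE1_ORIGINAL = {
    "uterus": 57, "uterus nos": 1651, "corpus uteri": 9535,
    "cervix uteri": 5417, "cervix": 167, "cervical": 1,
    "endometrium": 21, "endometrial": 2,
}


def test_facet_counts_under_empty_query(uterus):
    repo, kb = uterus
    counts = facet_counts(repo, kb, FacetedQuery(), ORIG, "tissue")
    assert counts == TABLE1_ORIGINAL


def test_facet_counts_exclude_the_attributes_own_selection(uterus):
    repo, kb = uterus
    q = FacetedQuery({"tissue": ["uterus"]})
    assert facet_counts(repo, kb, q, ORIG, "tissue") == TABLE1_ORIGINAL


def test_facet_counts_narrow_under_other_attributes(prostate):
    repo, kb = prostate
    q = FacetedQuery({"is_healthy": ["true"]})
    counts = facet_counts(repo, kb, q, ORIG, "disease")
    assert counts == {"prostate adenocarcinoma": 1278}


def test_selecting_a_faceted_value_yields_its_facet_count(uterus):
    repo, kb = uterus
    counts = facet_counts(repo, kb, FacetedQuery(), SYN, "tissue")
    for value, n in counts.items():
        if value == ND:
            continue
        got = evaluate_query(repo, kb, FacetedQuery({"tissue": [value]}),
                             ORIG)
        assert len(got) == n, value


# -- key-value steps -------------------------------------------------------


def test_kv_step_exact_match(brain):
    repo, _ = brain
    pred = KeyValuePredicate(name="organ", pairs={
        "biosample__organ_slims": ["brain"]})
    assert len(evaluate_kv_step(repo, [pred])) == 789


def test_kv_step_predicates_are_disjunctive(brain):
    repo, _ = brain
    preds = [
        KeyValuePredicate(name="a", pairs={"biosample__organ_slims":
                                           ["brain"]}),
        KeyValuePredicate(name="b", pairs={
            "clinical__lgg__family_history_of_primary_brain_tumor": ["yes"]}),
    ]
    assert len(evaluate_kv_step(repo, preds)) == 789 + 126


def test_kv_step_containment_mode(brain):
    repo, _ = brain
    pred = KeyValuePredicate(name="g", exact=False, pairs={
        "gdc__project__disease_type": ["glioma"]})
    assert len(evaluate_kv_step(repo, [pred])) == 4670
    exact = KeyValuePredicate(name="g", exact=True, pairs={
        "gdc__project__disease_type": ["glioma"]})
    assert len(evaluate_kv_step(repo, [exact])) == 0


def test_kv_step_requires_selected_pairs(brain):
    repo, _ = brain
    with pytest.raises(ValueError):
        evaluate_kv_step(repo, [KeyValuePredicate(name="empty")])


# -- sessions --------------------------------------------------------------


def test_single_step_session_equals_the_step(prostate):
    repo, kb = prostate
    q = FacetedQuery({"is_healthy": ["false"]})
    session = QuerySession(steps=(FacetedStep(q),), level=ORIG)
    assert evaluate_session(repo, kb, session).item_ids == \
        evaluate_query(repo, kb, q, ORIG).item_ids


def test_session_steps_commute_and_are_removable(brain):
    repo, kb = brain
    step_a = FacetedStep(FacetedQuery({"tissue": ["brain"]}))
    step_b = KeyValueStep(predicates=(KeyValuePredicate(
        name="o", pairs={"biosample__organ_slims": ["brain"]}),))
    ab = evaluate_session(repo, kb, QuerySession((step_a, step_b), ORIG))
    ba = evaluate_session(repo, kb, QuerySession((step_b, step_a), ORIG))
    assert ab.item_ids == ba.item_ids
    # the fixture groups are disjoint, so the conjunction is empty
    assert len(ab) == 0
    only_a = QuerySession((step_a, step_b), ORIG).without_step(1)
    assert len(evaluate_session(repo, kb, only_a)) == 15714


# -- key / value exploration ----------------------------------------------


def test_key_search_matches_core_attributes_and_raw_keys(brain):
    repo, _ = brain
    res = key_search(repo, "disease")
    assert [c.attribute for c in res.core] == ["disease"]
    assert res.core[0].distinct_values == 1
    assert [r.key for r in res.raw] == ["gdc__project__disease_type"]
    assert res.raw[0].distinct_values == 1
    nothing = key_search(repo, "zzz-no-such-key")
    assert nothing.core == () and nothing.raw == ()


def test_key_search_exact_mode(brain):
    repo, _ = brain
    assert key_search(repo, "disease", exact=True).raw == ()


def test_value_search_scans_core_and_raw_values(brain):
    repo, _ = brain
    res = value_search(repo, "glioma")
    assert ("disease", "brain lower grade glioma", 9188) == (
        res.core[0].attribute, res.core[0].value, res.core[0].item_count)
    assert ("gdc__project__disease_type", "brain lower grade glioma",
            4670) == (res.raw[0].key, res.raw[0].value,
                      res.raw[0].item_count)


def _group_by_oracle(repo):
    keys = {}
    for r in repo.raw_pairs.itertuples():
        keys.setdefault(r.key, set()).add(r.value)
    return {k: len(v) for k, v in keys.items()}


def test_key_search_counts_equal_group_by_oracle(small_random):
    repo, _, _ = small_random
    oracle = _group_by_oracle(repo)
    res = key_search(repo, "meta__")
    assert {r.key: r.distinct_values for r in res.raw} == oracle


# -- keyword search and explanation ---------------------------------------


def test_keyword_search_level2_signature_counts(brain):
    repo, kb = brain
    groups = keyword_search(repo, kb, "brain", 2)
    assert len(groups["<Item> - <Replicate> - <Biosample.tissue: brain>"]) \
        == 15714
    assert len(groups["<Item> - <Key: biosample__organ_slims, "
                      "Value: brain>"]) == 789


def test_keyword_search_level4_includes_hyponym_groups(brain):
    repo, kb = brain
    groups = keyword_search(repo, kb, "brain", 4)
    pons_sig = ("<Item> - <Replicate> - <Biosample.tissue: pons> - "
                "<Vocabulary: pons, UBERON_0000988> -[IS_A]- "
                "<Vocabulary: regional part of brain, UBERON_0002616> "
                "-[PART_OF]- <Vocabulary: brain, UBERON_0000955>")
    assert len(groups[pons_sig]) == 10
    globus = [s for s in groups if "globus pallidus" in s
              and "Vocabulary" in s]
    assert len(groups[globus[0]]) == 8


def test_keyword_search_absent_keyword_is_empty(brain):
    repo, kb = brain
    assert keyword_search(repo, kb, "zebrafish", 4) == {}


def test_keyword_levels_are_cumulative(brain):
    repo, kb = brain
    prev = frozenset()
    for level in (1, 2, 3, 4):
        groups = keyword_search(repo, kb, "brain", level)
        total = frozenset().union(*groups.values()) if groups else frozenset()
        assert prev <= total
        prev = total


def test_explain_pons_item_shows_the_relationship_chain(brain):
    repo, kb = brain
    den = repo.denormalized()
    item = int(den.loc[den["tissue"] == "pons", "item_id"].iloc[0])
    chains = explain(repo, kb, item, "brain", 4)
    assert len(chains) == 1
    assert chains[0].render() == (
        "<Item> - <Replicate> - <Biosample.tissue: pons> - "
        "<Vocabulary: pons, UBERON_0000988> -[IS_A]- "
        "<Vocabulary: regional part of brain, UBERON_0002616> -[PART_OF]- "
        "<Vocabulary: brain, UBERON_0000955>")
    # the same item has nothing to show below the expansion level
    assert explain(repo, kb, item, "brain", 2) == []


def test_explain_direct_attribute_match_is_a_two_hop_chain(brain):
    repo, kb = brain
    den = repo.denormalized()
    item = int(den.loc[den["tissue"] == "brain", "item_id"].iloc[0])
    chains = explain(repo, kb, item, "brain", 2)
    assert [c.render() for c in chains] == [
        "<Item> - <Replicate> - <Biosample.tissue: brain>"]


def test_explain_unknown_item_raises(brain):
    repo, kb = brain
    with pytest.raises(KeyError):
        explain(repo, kb, 10**9, "brain", 2)


def test_explain_completeness_matches_keyword_search(small_random):
    repo, kb, _ = small_random
    keyword = "concept 003"
    for level in (2, 3, 4):
        groups = keyword_search(repo, kb, keyword, level)
        found = set().union(*groups.values()) if groups else set()
        for item in sorted(repo.all_item_ids()):
            chains = explain(repo, kb, item, keyword, level)
            assert (item in found) == bool(chains)


# -- summarization and rendering ------------------------------------------


def test_summarize_empty_result(brain):
    repo, _ = brain
    assert summarize(repo, ResultSet()) == ({}, {})


def test_summarize_partitions_patient_cohort(patient_cohort):
    repo, sizes = patient_cohort
    result = ResultSet(repo.all_item_ids())
    sources, datasets = summarize(repo, result)
    assert sources == {"tcga": sum(sizes)}
    assert len(datasets) == 7
    assert sorted(datasets.values()) == sorted(sizes)
    assert sum(datasets.values()) == len(result) == 401


def test_summarize_buckets_sum_to_result_size(small_random):
    repo, _, _ = small_random
    result = ResultSet(repo.all_item_ids())
    sources, datasets = summarize(repo, result)
    assert sum(sources.values()) == len(result)
    assert sum(datasets.values()) == len(result)


def test_replicated_and_aggregated_views(small_random):
    repo, _, _ = small_random
    result = ResultSet(repo.all_item_ids())
    replicated = render_result_table(repo, result, mode="replicated",
                                     page_size=1000)
    assert len(replicated) == min(1000, len(repo.denormalized()))
    aggregated = render_result_table(repo, result, mode="aggregated",
                                     page_size=1000)
    assert len(aggregated) == len(result)


def test_page_size_limits():
    from genofacet.model import Repository
    repo = Repository()
    with pytest.raises(ValueError):
        render_result_table(repo, ResultSet(), page_size=0)
    with pytest.raises(ValueError):
        render_result_table(repo, ResultSet(), page_size=1001)


def test_pagination_is_stable_and_disjoint(small_random):
    repo, _, _ = small_random
    result = ResultSet(repo.all_item_ids())
    p0 = render_result_table(repo, result, mode="aggregated", page_size=40,
                             page_index=0)
    p1 = render_result_table(repo, result, mode="aggregated", page_size=40,
                             page_index=1)
    assert len(p0) == 40
    assert set(p0["item_id"]).isdisjoint(set(p1["item_id"]))
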