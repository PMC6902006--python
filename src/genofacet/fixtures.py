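"""Programmatic test fixtures: worked-example repositories rebuilt from
printed counts, and seeded random repositories with brute-force ground
truth.

Every worked example reconstructs a published search scenario from the
item-group multiplicities and ontology fragments it quotes, so the whole
suite runs without downloading any real source dump.  Ontology codes are
real Uberon/EFO/OGG codes where the scenario states them; concepts whose
codes the scenario leaves unstated (the eye subtree) receive synthetic
placeholder codes in the reserved ``TEST`` namespace.

The random generator is fully deterministic per seed and records, at
generation time, an independently computed (plain-Python, brute-force)
ground truth for sampled probes; the search engine is tested against that
oracle, never against itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kb import DEFAULT_MAX_DEPTH, IS_A, PART_OF, KnowledgeBase
from .model import ND, TABLE_SCHEMAS, Repository, norm

__all__ = [
    "RepositoryBuilder",
    "KnowledgeBaseBuilder",
    "WORKED_EXAMPLES",
    "build_worked_example",
    "random_repository",
]

_INT_COLS = {t: {c for c, k in cols if k in ("id", "int")}
             for t, cols in TABLE_SCHEMAS.items()}


def _frame(table: str, rows: list[dict]) -> pd.DataFrame:
    cols = [c for c, _ in TABLE_SCHEMAS[table]]
    if not rows:
        return Repository().table(table)
    df = pd.DataFrame(rows, columns=cols)
    for c in cols:
        if c in _INT_COLS[table]:
            df[c] = df[c].astype("Int64")
        else:
            df[c] = df[c].astype(object).where(df[c].notna(), None)
    return df


class RepositoryBuilder:
    """Assemble a repository row by row; every string is normalized on the
    way in, ids are sequential in insertion order."""

    def __init__(self) -> None:
        self._rows: dict[str, list[dict]] = {t: [] for t in TABLE_SCHEMAS}

    def _next(self, table: str) -> int:
        return len(self._rows[table]) + 1

    def add_project(self, project_name: str, source: str) -> int:
        pid = self._next("project")
        self._rows["project"].append({"project_id": pid,
                                      "project_name": norm(project_name),
                                      "source": norm(source)})
        return pid

    def add_dataset(self, dataset_name: str, data_type: str = "peaks",
                    assembly: str = "grch38", file_format: str = "bed",
                    is_annotation: str = "false") -> int:
        did = self._next("dataset")
        self._rows["dataset"].append({
            "dataset_id": did, "dataset_name": norm(dataset_name),
            "data_type": norm(data_type), "assembly": norm(assembly),
            "file_format": norm(file_format),
            "is_annotation": norm(is_annotation)})
        return did

    def add_experiment_type(self, technique=None, feature=None, target=None,
                            antibody=None, technique_tid=None,
                            feature_tid=None, target_tid=None) -> int:
        eid = self._next("experiment_type")
        self._rows["experiment_type"].append({
            "experiment_type_id": eid, "technique": norm(technique),
            "technique_tid": technique_tid, "feature": norm(feature),
            "feature_tid": feature_tid, "target": norm(target),
            "target_tid": target_tid, "antibody": norm(antibody)})
        return eid

    def add_case(self, project_id: int, case_study_source_id=None,
                 source_site=None, external_reference=None) -> int:
        cid = self._next("case_study")
        self._rows["case_study"].append({
            "case_study_id": cid,
            "case_study_source_id": norm(case_study_source_id)
            or f"case-{cid}",
            "project_ref": project_id, "source_site": norm(source_site),
            "external_reference": norm(external_reference)})
        return cid

    def add_item_group(self, n: int, prefix: str, dataset_id: int,
                       experiment_type_id: int, case_ids=(),
                       tissue=None, tissue_tid=None, cell=None,
                       cell_tid=None, disease=None, disease_tid=None,
                       is_healthy=None, biosample_type=None, age=None,
                       gender=None, species=None, species_tid=None,
                       ethnicity=None, ethnicity_tid=None, raw_pairs=(),
                       replicate_numbers=(1,)) -> list[int]:
        """Add ``n`` items sharing one attribute assignment; each item gets
        its own donor/biosample chain, one replicate per entry of
        ``replicate_numbers`` and membership in every case of ``case_ids``.
        Returns the new item ids."""
        if n < 0:
            raise ValueError("multiplicity must be >= 0")
        species, gender, ethnicity = norm(species), norm(gender), norm(ethnicity)
        tissue, cell, disease = norm(tissue), norm(cell), norm(disease)
        biosample_type, is_healthy = norm(biosample_type), norm(is_healthy)
        raw_pairs = [(norm(k), norm(v)) for k, v in raw_pairs]
        item_ids = []
        for i in range(n):
            did = self._next("donor")
            self._rows["donor"].append({
                "donor_id": did, "donor_source_id": f"{prefix}-donor-{did}",
                "species": species, "species_tid": species_tid,
                "age": age, "gender": gender,
                "ethnicity": ethnicity, "ethnicity_tid": ethnicity_tid})
            bid = self._next("biosample")
            self._rows["biosample"].append({
                "biosample_id": bid,
                "biosample_source_id": f"{prefix}-bios-{bid}",
                "donor_ref": did, "biosample_type": biosample_type,
                "tissue": tissue, "tissue_tid": tissue_tid,
                "cell": cell, "cell_tid": cell_tid,
                "disease": disease, "disease_tid": disease_tid,
                "is_healthy": is_healthy})
            iid = self._next("item")
            self._rows["item"].append({
                "item_id": iid, "item_source_id": f"{prefix}-item-{iid}",
                "experiment_type_ref": experiment_type_id,
                "dataset_ref": dataset_id, "size": None, "date": None,
                "checksum": None, "content_type": None,
                "content_type_tid": None, "platform": None,
                "platform_tid": None, "pipeline": None,
                "source_url": f"https://source.example/{prefix}-item-{iid}",
                "local_url": None, "file_name": f"{prefix}-item-{iid}.bed",
                "source_page": None})
            for num in replicate_numbers:
                rid = self._next("replicate")
                self._rows["replicate"].append({
                    "replicate_id": rid,
                    "replicate_source_id": f"{prefix}-rep-{rid}",
                    "biosample_ref": bid,
                    "biological_replicate_number": num,
                    "technical_replicate_number": None})
                self._rows["replicate2item"].append(
                    {"item_id": iid, "replicate_id": rid})
            for cid in case_ids:
                self._rows["case2item"].append(
                    {"item_id": iid, "case_study_id": cid})
            for k, v in raw_pairs:
                self._rows["raw_pair"].append(
                    {"item_id": iid, "key": k, "value": v})
            item_ids.append(iid)
        return item_ids

    def build(self) -> Repository:
        from .model import _TABLE_ATTRS
        return Repository(**{_TABLE_ATTRS[t]: _frame(t, self._rows[t])
                             for t in TABLE_SCHEMAS})


class KnowledgeBaseBuilder:
    def __init__(self, max_depth: int = DEFAULT_MAX_DEPTH) -> None:
        self._vocab: list[dict] = []
        self._syn: list[dict] = []
        self._ref: list[dict] = []
        self._rel: list[dict] = []
        self._ann: list[dict] = []
        self.max_depth = max_depth

    def add_term(self, source: str, code: str, pref_label: str,
                 synonyms=(), description=None) -> int:
        tid = len(self._vocab) + 1
        self._vocab.append({"tid": tid, "ontology_source": norm(source),
                            "code": norm(code), "pref_label": norm(pref_label),
                            "description": norm(description), "iri": None})
        for s in synonyms:
            self.add_synonym(tid, s)
        return tid

    def add_synonym(self, tid: int, label: str,
                    syn_type: str = "alternative syntax") -> None:
        self._syn.append({"tid": tid, "label": norm(label),
                          "syn_type": norm(syn_type)})

    def add_reference(self, tid: int, ext_source: str, ext_code: str) -> None:
        self._ref.append({"tid": tid, "ext_source": norm(ext_source),
                          "ext_code": norm(ext_code)})

    def add_edge(self, parent: int, child: int, rel_type: str) -> None:
        self._rel.append({"parent": parent, "child": child,
                          "rel_type": rel_type})

    def annotate(self, attribute: str, raw_value: str, tid: int) -> None:
        self._ann.append({"attribute": attribute, "raw_value": norm(raw_value),
                          "tid": tid})

    def build(self) -> KnowledgeBase:
        def mk(rows, cols, ints):
            if not rows:
                df = pd.DataFrame({c: pd.Series(
                    dtype="Int64" if c in ints else "object") for c in cols})
                return df
            df = pd.DataFrame(rows, columns=cols)
            for c in ints:
                df[c] = df[c].astype("Int64")
            return df
        return KnowledgeBase(
            vocabulary=mk(self._vocab, ["tid", "ontology_source", "code",
                                        "pref_label", "description", "iri"],
                          {"tid"}),
            synonyms=mk(self._syn, ["tid", "label", "syn_type"], {"tid"}),
            references=mk(self._ref, ["tid", "ext_source", "ext_code"],
                          {"tid"}),
            relationships=mk(self._rel, ["parent", "child", "rel_type"],
                             {"parent", "child"}),
            annotations=mk(self._ann, ["attribute", "raw_value", "tid"],
                           {"tid"}),
            max_depth=self.max_depth,
        )


# --------------------------------------------------------------------------
# Worked examples
# --------------------------------------------------------------------------

WORKED_EXAMPLES = ("uterus", "k562", "boris", "eye", "brain", "prostate")


@dataclass
class _GroupSpec:
    count: int
    kwargs: dict = field(default_factory=dict)


def _assemble(name: str, groups: list[_GroupSpec], kb: KnowledgeBase,
              seed: int | None, source: str = "test source",
              assembly: str = "grch38") -> tuple[Repository, KnowledgeBase]:
    rb = RepositoryBuilder()
    pid = rb.add_project("fixture project", source)
    did = rb.add_dataset("fixture dataset", assembly=assembly)
    cid = rb.add_case(pid)
    default_etype = rb.add_experiment_type(technique="chip-seq")
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(groups))
        groups = [groups[i] for i in order]
    for gi, g in enumerate(groups):
        kwargs = dict(g.kwargs)
        etype = kwargs.pop("experiment_type", None)
        eid = rb.add_experiment_type(**etype) if etype else default_etype
        rb.add_item_group(g.count, prefix=f"{name}-{gi}", dataset_id=did,
                          experiment_type_id=eid, case_ids=(cid,), **kwargs)
    return rb.build(), kb


def _uterus() -> tuple[list[_GroupSpec], KnowledgeBase]:
    kbb = KnowledgeBaseBuilder()
    uterus = kbb.add_term("uberon", "UBERON_0000995", "uterus",
                          synonyms=["uterus nos"])
    body = kbb.add_term("uberon", "UBERON_0009853", "body of uterus",
                        synonyms=["corpus uteri"])
    cervix = kbb.add_term("uberon", "UBERON_0000002", "uterine cervix",
                          synonyms=["cervix uteri", "cervix", "cervical"])
    wall = kbb.add_term("uberon", "UBERON_0000459", "uterine wall")
    endo = kbb.add_term("uberon", "UBERON_0001295", "endometrium",
                        synonyms=["endometrial"])
    kbb.add_edge(uterus, body, PART_OF)
    kbb.add_edge(uterus, cervix, PART_OF)
    kbb.add_edge(uterus, wall, PART_OF)
    kbb.add_edge(wall, endo, PART_OF)
    groups = []
    for value, count, tid in [
        ("uterus", 57, uterus), ("uterus nos", 1651, uterus),
        ("corpus uteri", 9535, body),
        ("cervix uteri", 5417, cervix), ("cervix", 167, cervix),
        ("cervical", 1, cervix),
        ("endometrium", 21, endo), ("endometrial", 2, endo),
    ]:
        kbb.annotate("tissue", value, tid)
        groups.append(_GroupSpec(count, {"tissue": value, "tissue_tid": tid}))
    return groups, kbb.build()


def _k562() -> tuple[list[_GroupSpec], KnowledgeBase]:
    kbb = KnowledgeBaseBuilder()
    t = kbb.add_term("efo", "EFO_0002067", "k562",
                     synonyms=["k-562", "k562 cell", "k-562 cell",
                               "k562 leukemia cells"])
    kbb.annotate("cell", "k562", t)
    kbb.annotate("cell", "k562 leukemia cells", t)
    groups = [
        _GroupSpec(5942, {"cell": "k562", "cell_tid": t}),
        _GroupSpec(44, {"cell": "k562 leukemia cells", "cell_tid": t}),
    ]
    return groups, kbb.build()


def _boris() -> tuple[list[_GroupSpec], KnowledgeBase]:
    kbb = KnowledgeBaseBuilder()
    t = kbb.add_term("ogg", "OGG_3000140690", "ctcfl", synonyms=["boris"])
    kbb.annotate("target", "ctcfl", t)
    groups = [_GroupSpec(10, {"experiment_type": {
        "technique": "chip-seq", "target": "ctcfl", "target_tid": t}})]
    return groups, kbb.build()


def _eye() -> tuple[list[_GroupSpec], KnowledgeBase]:
    # Synthetic placeholder codes: the scenario names the concepts but not
    # their ontology codes, so they live in the reserved TEST namespace.
    kbb = KnowledgeBaseBuilder()
    eye = kbb.add_term("test", "TEST_0000001", "eye",
                       synonyms=["eye and adnexa"])
    photo = kbb.add_term("test", "TEST_0000002", "photoreceptor array")
    retina = kbb.add_term("test", "TEST_0000003", "retina")
    kbb.add_edge(eye, photo, PART_OF)
    kbb.add_edge(photo, retina, IS_A)
    kbb.annotate("tissue", "eye", eye)
    kbb.annotate("tissue", "eye and adnexa", eye)
    kbb.annotate("tissue", "retina", retina)
    groups = [
        _GroupSpec(13, {"tissue": "eye", "tissue_tid": eye}),
        _GroupSpec(1440, {"tissue": "eye and adnexa", "tissue_tid": eye}),
        _GroupSpec(20, {"tissue": "retina", "tissue_tid": retina}),
    ]
    return groups, kbb.build()


def _brain() -> tuple[list[_GroupSpec], KnowledgeBase]:
    kbb = KnowledgeBaseBuilder()
    brain = kbb.add_term("uberon", "UBERON_0000955", "brain",
                         synonyms=["fetal brain"])
    pons = kbb.add_term("uberon", "UBERON_0000988", "pons")
    regional = kbb.add_term("uberon", "UBERON_0002616",
                            "regional part of brain")
    globus = kbb.add_term("uberon", "UBERON_0001875", "globus pallidus")
    pallidum = kbb.add_term("uberon", "UBERON_0006514", "pallidum")
    gray = kbb.add_term("uberon", "UBERON_0003528", "brain gray matter")
    kbb.add_edge(regional, pons, IS_A)
    kbb.add_edge(brain, regional, PART_OF)
    kbb.add_edge(pallidum, globus, PART_OF)
    kbb.add_edge(gray, pallidum, IS_A)
    kbb.add_edge(brain, gray, PART_OF)
    kbb.annotate("tissue", "brain", brain)
    kbb.annotate("cell", "fetal brain", brain)
    kbb.annotate("tissue", "pons", pons)
    kbb.annotate("tissue", "globus pallidus", globus)
    groups = [
        # raw-pair-only groups (level-1 matches)
        _GroupSpec(789, {"raw_pairs": [("biosample__organ_slims", "brain")]}),
        _GroupSpec(4670, {"raw_pairs": [("gdc__project__disease_type",
                                         "brain lower grade glioma")]}),
        _GroupSpec(126, {"raw_pairs": [
            ("clinical__lgg__family_history_of_primary_brain_tumor", "yes")]}),
        _GroupSpec(2463, {"raw_pairs": [
            ("clinical_patient__history_lgg_dx_of_brain_tissue", "no")]}),
        # core-attribute groups (levels 2-4)
        _GroupSpec(15714, {"tissue": "brain", "tissue_tid": brain}),
        _GroupSpec(9188, {"disease": "brain lower grade glioma"}),
        _GroupSpec(10, {"cell": "smooth muscle cell of the brain "
                                "vasculature"}),
        _GroupSpec(13, {"cell": "fetal brain", "cell_tid": brain}),
        _GroupSpec(10, {"tissue": "pons", "tissue_tid": pons}),
        _GroupSpec(8, {"tissue": "globus pallidus", "tissue_tid": globus}),
    ]
    return groups, kbb.build()


def _prostate() -> tuple[list[_GroupSpec], KnowledgeBase]:
    kbb = KnowledgeBaseBuilder()
    groups = [
        _GroupSpec(3543, {"disease": "prostate adenocarcinoma",
                          "is_healthy": "false"}),
        _GroupSpec(1278, {"disease": "prostate adenocarcinoma",
                          "is_healthy": "true"}),
    ]
    return groups, kbb.build()


_BUILDERS = {"uterus": _uterus, "k562": _k562, "boris": _boris,
             "eye": _eye, "brain": _brain, "prostate": _prostate}


def build_worked_example(name: str,
                         seed: int | None = None
                         ) -> tuple[Repository, KnowledgeBase]:
    """Build one of the worked-example fixtures.  ``seed``, when given,
    permutes the insertion order of the item groups (all reported counts
    are invariant to input order)."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown worked example {name!r}; expected one of "
                         f"{', '.join(WORKED_EXAMPLES)}")
    groups, kb = _BUILDERS[name]()
    return _assemble(name, groups, kb, seed)


# --------------------------------------------------------------------------
# Seeded random repositories with brute-force ground truth
# --------------------------------------------------------------------------

_RANDOM_ATTRS = ("tissue", "cell", "disease", "target")


def _naive_reachable(children: dict[int, list[int]], root: int,
                     budget: int) -> set[int]:
    """Depth-limited DFS; revisits nodes when a larger budget remains so
    every node within ``budget`` edges of the root is found."""
    best: dict[int, int] = {}

    def walk(node: int, remaining: int) -> None:
        for ch in children.get(node, ()):
            if best.get(ch, -1) < remaining - 1:
                best[ch] = remaining - 1
                if remaining - 1 >= 0:
                    walk(ch, remaining - 1)

    walk(root, budget)
    best.pop(root, None)
    return set(best)


def _brute_match(records: list[dict], onto: dict, attribute: str,
                 value: str, level: int) -> list[int]:
    v = norm(value)
    if v == ND:
        return sorted(r["item_id"] for r in records if r[attribute] is None)
    ids = {r["item_id"] for r in records if r[attribute] == v}
    if level >= 2:
        tids = {t for t in onto["labels"]
                if onto["labels"][t] == v or v in onto["synonyms"][t]}
        if level >= 3:
            expanded = set(tids)
            for t in tids:
                expanded |= _naive_reachable(onto["children"], t,
                                             DEFAULT_MAX_DEPTH)
            tids = expanded
        ids |= {r["item_id"] for r in records
                if r.get(f"{attribute}_tid") in tids}
    return sorted(ids)


def random_repository(seed: int, n_items: int = 200, n_terms: int = 25,
                      annotation_rate: float = 0.7,
                      corruption_count: int = 0, n_probes: int = 8
                      ) -> tuple[Repository, KnowledgeBase, dict]:
    """Deterministic random repository + knowledge base + ground truth.

    The ground truth holds, for sampled (attribute, value, level) probes
    plus one faceted query, one key-value predicate and one facet-count
    table, the exact answers computed by an independent brute-force pass
    over the generation records.  When ``corruption_count`` > 0 the
    repository is corrupted after generation (each corruption yields
    exactly one validation violation) and only the corruption count is
    recorded.
    """
    rng = np.random.default_rng(seed)

    # -- ontology fragment -------------------------------------------------
    kbb = KnowledgeBaseBuilder()
    labels: dict[int, str] = {}
    synonyms: dict[int, set[str]] = {}
    children: dict[int, list[int]] = {}
    for i in range(n_terms):
        label = f"concept {i:03d}"
        syns = [f"concept {i:03d} alt{j}"
                for j in range(int(rng.integers(0, 3)))]
        tid = kbb.add_term("rndo", f"RNDO_{i:07d}", label, synonyms=syns)
        labels[tid] = label
        synonyms[tid] = set(syns)
        if i > 0:
            n_parents = int(rng.choice([1, 1, 1, 2]))
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            for p in parents:
                ptid = int(p) + 1
                rel = IS_A if rng.random() < 0.5 else PART_OF
                kbb.add_edge(ptid, tid, rel)
                children.setdefault(ptid, []).append(tid)
    onto = {"labels": labels, "synonyms": synonyms, "children": children}

    # -- annotated value pools --------------------------------------------
    pools: dict[str, list[tuple[str, int | None]]] = {}
    for attr in _RANDOM_ATTRS:
        pool = []
        for j in range(8):
            value = f"{attr} value {j:02d}"
            tid = (int(rng.integers(1, n_terms + 1))
                   if rng.random() < annotation_rate else None)
            if tid is not None:
                kbb.annotate(attr, value, tid)
            pool.append((value, tid))
        pools[attr] = pool
    kb = kbb.build()

    # -- structural pools --------------------------------------------------
    rb = RepositoryBuilder()
    projects = [rb.add_project(f"project {j}", f"source {j % 2}")
                for j in range(2)]
    datasets = [rb.add_dataset(f"dataset {j}",
                               data_type=f"type {j % 3}",
                               assembly=["hg19", "grch38"][j % 2])
                for j in range(3)]
    etypes = []
    for j in range(6):
        target, target_tid = pools["target"][j]
        etypes.append((rb.add_experiment_type(
            technique=f"technique {j % 3}", feature=f"feature {j % 2}",
            target=target, target_tid=target_tid), target, target_tid))
    cases = [rb.add_case(int(rng.choice(projects)))
             for _ in range(max(1, n_items // 5))]
    kv_keys = [f"meta__key_{j}" for j in range(6)]
    kv_values = [f"val {j}" for j in range(8)]

    records: list[dict] = []
    for _ in range(n_items):
        rec: dict = {}
        kwargs: dict = {}
        for attr in ("tissue", "cell", "disease"):
            if rng.random() < 0.15:
                rec[attr], rec[f"{attr}_tid"] = None, None
            else:
                value, tid = pools[attr][int(rng.integers(0, 8))]
                rec[attr], rec[f"{attr}_tid"] = value, tid
                kwargs[attr] = value
                kwargs[f"{attr}_tid"] = tid
        eid, target, target_tid = etypes[int(rng.integers(0, len(etypes)))]
        rec["target"], rec["target_tid"] = target, target_tid
        did = datasets[int(rng.integers(0, len(datasets)))]
        healthy = [None, "true", "false"][int(rng.integers(0, 3))]
        kwargs["is_healthy"] = healthy
        kwargs["gender"] = ["male", "female"][int(rng.integers(0, 2))]
        if rng.random() < 0.5:
            kwargs["age"] = int(rng.integers(0, 30000))
        n_pairs = int(rng.integers(0, 4))
        pair_set = set()
        while len(pair_set) < n_pairs:
            pair_set.add((kv_keys[int(rng.integers(0, len(kv_keys)))],
                          kv_values[int(rng.integers(0, len(kv_values)))]))
        rec["pairs"] = pair_set
        n_cases = int(rng.integers(1, 3))
        case_ids = [cases[int(c)] for c in
                    rng.choice(len(cases), size=min(n_cases, len(cases)),
                               replace=False)]
        reps = tuple(range(1, int(rng.integers(1, 3)) + 1))
        ids = rb.add_item_group(
            1, prefix=f"rnd{len(records)}", dataset_id=did,
            experiment_type_id=eid, case_ids=case_ids,
            raw_pairs=sorted(pair_set), replicate_numbers=reps, **kwargs)
        rec["item_id"] = ids[0]
        records.append(rec)
    repo = rb.build()

    if corruption_count:
        _corrupt(repo, rng, corruption_count)
        return repo, kb, {"corruptions": corruption_count}

    truth: dict = {"corruptions": 0, "probes": [], "n_items": n_items}
    syn_pool = sorted(s for ss in synonyms.values() for s in ss)
    for _ in range(n_probes):
        attr = _RANDOM_ATTRS[int(rng.integers(0, len(_RANDOM_ATTRS)))]
        kind = rng.random()
        if kind < 0.5:
            value = pools[attr][int(rng.integers(0, 8))][0]
        elif kind < 0.7 and syn_pool:
            value = syn_pool[int(rng.integers(0, len(syn_pool)))]
        elif kind < 0.9:
            value = labels[int(rng.integers(1, n_terms + 1))]
        else:
            value = ND
        level = int(rng.integers(1, 4))
        truth["probes"].append({
            "attribute": attr, "value": value, "level": level,
            "items": _brute_match(records, onto, attr, value, level)})

    # one random conjunctive faceted query
    attrs = list(rng.choice(_RANDOM_ATTRS, size=2, replace=False))
    level = int(rng.integers(1, 4))
    selections = {}
    expected: set[int] | None = None
    for attr in attrs:
        values = [pools[attr][int(rng.integers(0, 8))][0]
                  for _ in range(int(rng.integers(1, 3)))]
        selections[attr] = sorted(set(values))
        hits: set[int] = set()
        for v in selections[attr]:
            hits |= set(_brute_match(records, onto, attr, v, level))
        expected = hits if expected is None else expected & hits
    truth["query"] = {"selections": selections, "level": level,
                      "items": sorted(expected or set())}

    # one key-value predicate
    key = kv_keys[int(rng.integers(0, len(kv_keys)))]
    accepted = sorted({kv_values[int(rng.integers(0, len(kv_values)))]
                       for _ in range(2)})
    exact = bool(rng.random() < 0.5)
    kv_hits = []
    for rec in records:
        for k, v in rec["pairs"]:
            if k == key and any((v == a) if exact else (a in v)
                                for a in accepted):
                kv_hits.append(rec["item_id"])
                break
    truth["kv"] = {"key": key, "values": accepted, "exact": exact,
                   "items": sorted(kv_hits)}

    # facet counts for one attribute under the empty query
    attr = _RANDOM_ATTRS[int(rng.integers(0, len(_RANDOM_ATTRS)))]
    counts: dict[str, int] = {}
    for rec in records:
        v = rec[attr] if rec[attr] is not None else ND
        counts[v] = counts.get(v, 0) + 1
    truth["facet"] = {"attribute": attr, "counts": counts}
    return repo, kb, truth


def _corrupt(repo: Repository, rng, count: int) -> None:
    """Inject ``count`` independent invariant violations (cycling through
    four kinds); each yields exactly one validation finding."""
    n_donors = len(repo.donors)
    n_reps = len(repo.replicates)
    n_bios = len(repo.biosamples)
    used_donor_rows: set[int] = set()
    for k in range(count):
        kind = k % 4
        if kind == 0 and n_donors >= 2:
            row = 1 + (k // 4) % (n_donors - 1)
            repo.donors.loc[row, "donor_source_id"] = \
                repo.donors.loc[0, "donor_source_id"]
        elif kind == 1 and n_reps:
            row = (k // 4) % n_reps
            repo.replicates.loc[row, "biosample_ref"] = n_bios + 1000 + k
        elif kind == 2 and n_bios:
            row = (k // 4) % n_bios
            repo.biosamples.loc[row, "is_healthy"] = "maybe"
        elif n_donors:
            row = (k // 4) % n_donors
            while row in used_donor_rows:
                row = (row + 1) % n_donors
            used_donor_rows.add(row)
            repo.donors.loc[row, "age"] = -1 - k
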