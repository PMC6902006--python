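"""Star-schema repository of genomic-data-file metadata.

The repository is a classic data mart centred on the *Item* fact table (one
row per processed genomic data file) surrounded by four dimensions:

* Biology   — Donor, Biosample, Replicate (+ the Replicate2Item bridge);
* Management — Project, CaseStudy (+ the Case2Item bridge);
* Technology — ExperimentType;
* Extraction — Dataset.

Items relate many-to-many with both Replicates and CaseStudies.  Source
metadata that does not fit the structured schema is preserved verbatim as
``(item, key, value)`` raw pairs.  Ten attributes (ethnicity, species,
disease, tissue, cell, technique, feature, target, platform, content_type)
are *semantically enriched*: each carries an optional term id pointing into
the ontology knowledge base (see :mod:`genofacet.kb`).

The physical store is a set of in-memory :class:`pandas.DataFrame` tables;
any indexed store reproducing this logical schema would be conformant.  The
query engine only ever reads the denormalized join produced by
:func:`denormalize`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ND",
    "ENRICHED_ATTRIBUTES",
    "SEARCHABLE_ATTRIBUTES",
    "ATTRIBUTE_TABLE",
    "ENTITY_PATHS",
    "Repository",
    "ValidationReport",
    "Violation",
    "FormatError",
    "IntegrityError",
    "load_repository",
    "validate_repository",
    "denormalize",
    "norm",
    "years_to_days",
]

_WS = re.compile(r"\s+")

#: Sentinel selecting items whose attribute is null ("not determined").
ND = "n/d"

#: Days per year used when converting user-facing ages to the stored unit.
DAYS_PER_YEAR = 365


def norm(value: object) -> str | None:
    """Normalize a metadata value: lower case, trimmed, collapsed whitespace.

    All stored string attributes and all query strings pass through this
    function, which makes every comparison in the engine case-insensitive.
    Empty strings and ``None`` normalize to ``None`` (a null cell).
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = _WS.sub(" ", str(value)).strip().lower()
    return s if s else None


def years_to_days(years: float) -> int:
    """Convert an age expressed in years to the stored unit (integer days)."""
    return int(round(years * DAYS_PER_YEAR))


# --------------------------------------------------------------------------
# Schema description
# --------------------------------------------------------------------------

_ID, _INT, _STR = "id", "int", "str"

#: Column layout of every table; the TSV interchange files use exactly these
#: headers.  ``*_tid`` columns are the ontology-term links of the enriched
#: attributes.
TABLE_SCHEMAS: dict[str, list[tuple[str, str]]] = {
    "donor": [
        ("donor_id", _ID), ("donor_source_id", _STR), ("species", _STR),
        ("species_tid", _INT), ("age", _INT), ("gender", _STR),
        ("ethnicity", _STR), ("ethnicity_tid", _INT),
    ],
    "biosample": [
        ("biosample_id", _ID), ("biosample_source_id", _STR),
        ("donor_ref", _INT), ("biosample_type", _STR), ("tissue", _STR),
        ("tissue_tid", _INT), ("cell", _STR), ("cell_tid", _INT),
        ("disease", _STR), ("disease_tid", _INT), ("is_healthy", _STR),
    ],
    "replicate": [
        ("replicate_id", _ID), ("replicate_source_id", _STR),
        ("biosample_ref", _INT), ("biological_replicate_number", _INT),
        ("technical_replicate_number", _INT),
    ],
    "experiment_type": [
        ("experiment_type_id", _ID), ("technique", _STR),
        ("technique_tid", _INT), ("feature", _STR), ("feature_tid", _INT),
        ("target", _STR), ("target_tid", _INT), ("antibody", _STR),
    ],
    "dataset": [
        ("dataset_id", _ID), ("dataset_name", _STR), ("data_type", _STR),
        ("assembly", _STR), ("file_format", _STR), ("is_annotation", _STR),
    ],
    "project": [
        ("project_id", _ID), ("project_name", _STR), ("source", _STR),
    ],
    "case_study": [
        ("case_study_id", _ID), ("case_study_source_id", _STR),
        ("project_ref", _INT), ("source_site", _STR),
        ("external_reference", _STR),
    ],
    "item": [
        ("item_id", _ID), ("item_source_id", _STR),
        ("experiment_type_ref", _INT), ("dataset_ref", _INT), ("size", _INT),
        ("date", _STR), ("checksum", _STR), ("content_type", _STR),
        ("content_type_tid", _INT), ("platform", _STR), ("platform_tid", _INT),
        ("pipeline", _STR), ("source_url", _STR), ("local_url", _STR),
        ("file_name", _STR), ("source_page", _STR),
    ],
    "replicate2item": [("item_id", _INT), ("replicate_id", _INT)],
    "case2item": [("item_id", _INT), ("case_study_id", _INT)],
    "raw_pair": [("item_id", _INT), ("key", _STR), ("value", _STR)],
}

_ENTITY_TABLES = (
    "donor", "biosample", "replicate", "experiment_type", "dataset",
    "project", "case_study", "item",
)

_TABLE_ATTRS = {
    "donor": "donors", "biosample": "biosamples", "replicate": "replicates",
    "experiment_type": "experiment_types", "dataset": "datasets",
    "project": "projects", "case_study": "case_studies", "item": "items",
    "replicate2item": "replicate2item", "case2item": "case2item",
    "raw_pair": "raw_pairs",
}

#: Secondary (source-accession) unique keys per entity table.
_SOURCE_ID_COLS = {
    "donor": "donor_source_id",
    "biosample": "biosample_source_id",
    "replicate": "replicate_source_id",
    "case_study": "case_study_source_id",
    "item": "item_source_id",
}

#: The 10 semantically enriched attributes and the table each lives in.
ENRICHED_ATTRIBUTES: dict[str, str] = {
    "ethnicity": "donor", "species": "donor",
    "disease": "biosample", "tissue": "biosample", "cell": "biosample",
    "technique": "experiment_type", "feature": "experiment_type",
    "target": "experiment_type",
    "platform": "item", "content_type": "item",
}

# Searchable-attribute registry, grouped by dimension (Management,
# Extraction, Biology, Technology) and alphabetical within each; this fixed
# order also drives the rendering of the human-readable "Selected query".
_MANAGEMENT = ["external_reference", "project_name", "source", "source_site"]
_EXTRACTION = ["assembly", "data_type", "dataset_name", "file_format",
               "is_annotation"]
_BIOLOGY = ["age", "biological_replicate_number", "biosample_type", "cell",
            "disease", "ethnicity", "gender", "is_healthy", "species",
            "technical_replicate_number", "tissue"]
_TECHNOLOGY = ["antibody", "content_type", "feature", "pipeline", "platform",
               "target", "technique"]

SEARCHABLE_ATTRIBUTES: list[str] = _MANAGEMENT + _EXTRACTION + _BIOLOGY + _TECHNOLOGY

ATTRIBUTE_TABLE: dict[str, str] = {
    "external_reference": "case_study", "project_name": "project",
    "source": "project", "source_site": "case_study",
    "assembly": "dataset", "data_type": "dataset", "dataset_name": "dataset",
    "file_format": "dataset", "is_annotation": "dataset",
    "age": "donor", "ethnicity": "donor", "gender": "donor",
    "species": "donor",
    "biological_replicate_number": "replicate",
    "technical_replicate_number": "replicate",
    "biosample_type": "biosample", "cell": "biosample",
    "disease": "biosample", "is_healthy": "biosample", "tissue": "biosample",
    "antibody": "experiment_type", "feature": "experiment_type",
    "target": "experiment_type", "technique": "experiment_type",
    "content_type": "item", "pipeline": "item", "platform": "item",
}

#: FK path from the Item fact table to the entity holding each attribute,
#: used when rendering deduction chains.
ENTITY_PATHS: dict[str, list[str]] = {
    "item": ["Item"],
    "dataset": ["Item", "Dataset"],
    "experiment_type": ["Item", "ExperimentType"],
    "replicate": ["Item", "Replicate"],
    "biosample": ["Item", "Replicate", "Biosample"],
    "donor": ["Item", "Replicate", "Biosample", "Donor"],
    "case_study": ["Item", "CaseStudy"],
    "project": ["Item", "CaseStudy", "Project"],
}

_ENTITY_DISPLAY = {
    "item": "Item", "dataset": "Dataset",
    "experiment_type": "ExperimentType", "replicate": "Replicate",
    "biosample": "Biosample", "donor": "Donor", "case_study": "CaseStudy",
    "project": "Project",
}


class FormatError(ValueError):
    """A table file does not follow the documented column layout."""


class IntegrityError(ValueError):
    """A foreign key in a table file cannot be resolved."""


def _empty_frame(table: str) -> pd.DataFrame:
    cols = {}
    for col, kind in TABLE_SCHEMAS[table]:
        if kind in (_ID, _INT):
            cols[col] = pd.Series(dtype="Int64")
        else:
            cols[col] = pd.Series(dtype="object")
    return pd.DataFrame(cols)


def _coerce_frame(table: str, df: pd.DataFrame, origin: str = "") -> pd.DataFrame:
    """Coerce a raw string frame to the schema dtypes, normalizing strings."""
    out = {}
    for col, kind in TABLE_SCHEMAS[table]:
        if col not in df.columns:
            raise FormatError(
                f"table '{table}'{origin}: missing mandatory column '{col}'")
        s = df[col]
        if kind in (_ID, _INT):
            s = s.map(lambda v: None if norm(v) is None else int(float(v)))
            out[col] = pd.array(s, dtype="Int64")
        else:
            out[col] = pd.array([norm(v) for v in s], dtype="object")
    return pd.DataFrame(out)


@dataclass
class Repository:
    """The full metadata repository: eight entity tables, two bridges and
    the raw key-value pairs.  Frames follow :data:`TABLE_SCHEMAS`."""

    donors: pd.DataFrame = field(default_factory=lambda: _empty_frame("donor"))
    biosamples: pd.DataFrame = field(default_factory=lambda: _empty_frame("biosample"))
    replicates: pd.DataFrame = field(default_factory=lambda: _empty_frame("replicate"))
    experiment_types: pd.DataFrame = field(default_factory=lambda: _empty_frame("experiment_type"))
    datasets: pd.DataFrame = field(default_factory=lambda: _empty_frame("dataset"))
    projects: pd.DataFrame = field(default_factory=lambda: _empty_frame("project"))
    case_studies: pd.DataFrame = field(default_factory=lambda: _empty_frame("case_study"))
    items: pd.DataFrame = field(default_factory=lambda: _empty_frame("item"))
    replicate2item: pd.DataFrame = field(default_factory=lambda: _empty_frame("replicate2item"))
    case2item: pd.DataFrame = field(default_factory=lambda: _empty_frame("case2item"))
    raw_pairs: pd.DataFrame = field(default_factory=lambda: _empty_frame("raw_pair"))

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, _TABLE_ATTRS[name])

    @property
    def n_items(self) -> int:
        return len(self.items)

    def all_item_ids(self) -> frozenset[int]:
        return frozenset(int(i) for i in self.items["item_id"])

    # -- denormalized view -------------------------------------------------

    def denormalized(self) -> pd.DataFrame:
        """Cached denormalized join; the repository is treated as immutable
        once built, so the view is computed at most once per instance."""
        den = getattr(self, "_den", None)
        if den is None:
            den = denormalize(self)
            object.__setattr__(self, "_den", den)
        return den

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        """Write one TSV per table plus a ``manifest.json`` naming them."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"tables": {}}
        for tname, attr in _TABLE_ATTRS.items():
            fname = f"{tname}.tsv"
            df = getattr(self, attr).copy()
            for col, kind in TABLE_SCHEMAS[tname]:
                if kind in (_ID, _INT):
                    df[col] = df[col].astype(object)
                df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(v))
            df.to_csv(directory / fname, sep="\t", index=False)
            manifest["tables"][tname] = fname
        mpath = directory / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1))
        return mpath

    def equals(self, other: "Repository") -> bool:
        return all(
            self.table(t).reset_index(drop=True).equals(
                other.table(t).reset_index(drop=True))
            for t in TABLE_SCHEMAS
        )


def load_repository(manifest_path: str | Path) -> Repository:
    """Load a repository from a manifest naming one TSV file per table.

    Internal numeric ids are reassigned deterministically in file order
    (1..n per table); foreign keys are remapped from the ids written in the
    files.  Tables absent from the manifest load empty.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    raw: dict[str, pd.DataFrame] = {}
    for tname in TABLE_SCHEMAS:
        fname = manifest.get("tables", {}).get(tname)
        if fname is None:
            raw[tname] = _empty_frame(tname)
            continue
        df = pd.read_csv(base / fname, sep="\t", dtype=str,
                         keep_default_na=False)
        raw[tname] = _coerce_frame(tname, df, origin=f" ({fname})")

    # Reassign internal ids in file order and remember old -> new maps.
    idmaps: dict[str, dict[int, int]] = {}
    for tname in _ENTITY_TABLES:
        idcol = TABLE_SCHEMAS[tname][0][0]
        df = raw[tname]
        old = list(df[idcol])
        if any(pd.isna(v) for v in old):
            raise FormatError(f"table '{tname}': empty id in column {idcol}")
        if len(set(old)) != len(old):
            raise FormatError(f"table '{tname}': duplicate ids in {idcol}")
        idmaps[tname] = {int(o): i + 1 for i, o in enumerate(old)}
        df[idcol] = pd.array(range(1, len(df) + 1), dtype="Int64")

    def remap(tname: str, col: str, target: str) -> None:
        df = raw[tname]
        m = idmaps[target]
        new = []
        for rowno, v in enumerate(df[col]):
            if pd.isna(v):
                new.append(None)
            elif int(v) in m:
                new.append(m[int(v)])
            else:
                raise IntegrityError(
                    f"table '{tname}' row {rowno}: {col}={int(v)} does not "
                    f"resolve in '{target}'")
        df[col] = pd.array(new, dtype="Int64")

    remap("biosample", "donor_ref", "donor")
    remap("replicate", "biosample_ref", "biosample")
    remap("item", "experiment_type_ref", "experiment_type")
    remap("item", "dataset_ref", "dataset")
    remap("case_study", "project_ref", "project")
    remap("replicate2item", "item_id", "item")
    remap("replicate2item", "replicate_id", "replicate")
    remap("case2item", "item_id", "item")
    remap("case2item", "case_study_id", "case_study")
    remap("raw_pair", "item_id", "item")

    return Repository(**{_TABLE_ATTRS[t]: raw[t] for t in TABLE_SCHEMAS})


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    kind: str
    table: str
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def kinds(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.violations:
            out[v.kind] = out.get(v.kind, 0) + 1
        return out


def validate_repository(repo: Repository, kb=None) -> ValidationReport:
    """Content-consistency check: report every violation of the schema
    invariants (duplicate secondary ids, dangling FKs, illegal tri-state
    values, negative ages, unresolvable term ids when a knowledge base is
    supplied).  Violations are data, not exceptions."""
    out: list[Violation] = []

    def dup_check(table: str, cols: list[str], kind: str) -> None:
        df = repo.table(table)
        sub = df[cols].dropna(how="all")
        dup = sub[sub.duplicated(keep="first")]
        for _, row in dup.iterrows():
            out.append(Violation(kind, table,
                                 "duplicate " + ", ".join(
                                     f"{c}={row[c]}" for c in cols)))

    for table, col in _SOURCE_ID_COLS.items():
        dup_check(table, [col], "duplicate_source_id")
    dup_check("project", ["project_name"], "duplicate_key")
    dup_check("dataset", ["dataset_name"], "duplicate_key")
    dup_check("experiment_type", ["technique", "feature", "target"],
              "duplicate_key")
    dup_check("replicate2item", ["item_id", "replicate_id"], "duplicate_pair")
    dup_check("case2item", ["item_id", "case_study_id"], "duplicate_pair")
    dup_check("raw_pair", ["item_id", "key", "value"], "duplicate_pair")

    def fk_check(table: str, col: str, target: str) -> None:
        df = repo.table(table)
        idcol = TABLE_SCHEMAS[target][0][0]
        valid = set(repo.table(target)[idcol].dropna().astype(int))
        for rowno, v in enumerate(df[col]):
            if pd.isna(v):
                continue
            if int(v) not in valid:
                out.append(Violation("dangling_fk", table,
                                     f"row {rowno}: {col}={int(v)}"))

    fk_check("biosample", "donor_ref", "donor")
    fk_check("replicate", "biosample_ref", "biosample")
    fk_check("item", "experiment_type_ref", "experiment_type")
    fk_check("item", "dataset_ref", "dataset")
    fk_check("case_study", "project_ref", "project")
    fk_check("replicate2item", "item_id", "item")
    fk_check("replicate2item", "replicate_id", "replicate")
    fk_check("case2item", "item_id", "item")
    fk_check("case2item", "case_study_id", "case_study")
    fk_check("raw_pair", "item_id", "item")

    bad = repo.biosamples["is_healthy"].map(
        lambda v: not (pd.isna(v) or v in ("true", "false")))
    for rowno in repo.biosamples.index[bad]:
        out.append(Violation("illegal_tristate", "biosample",
                             f"row {rowno}: is_healthy="
                             f"{repo.biosamples.loc[rowno, 'is_healthy']}"))

    neg = repo.donors["age"].map(lambda v: not pd.isna(v) and int(v) < 0)
    for rowno in repo.donors.index[neg]:
        out.append(Violation("negative_age", "donor",
                             f"row {rowno}: age={repo.donors.loc[rowno, 'age']}"))

    if kb is not None:
        known = set(int(t) for t in kb.vocabulary["tid"])
        for attr, table in ENRICHED_ATTRIBUTES.items():
            col = f"{attr}_tid"
            df = repo.table(table)
            for rowno, v in enumerate(df[col]):
                if not pd.isna(v) and int(v) not in known:
                    out.append(Violation("unknown_term", table,
                                         f"row {rowno}: {col}={int(v)}"))
    return ValidationReport(out)


# --------------------------------------------------------------------------
# Denormalization
# --------------------------------------------------------------------------

def denormalize(repo: Repository) -> pd.DataFrame:
    """Flatten the star schema into one row per (item x replicate-chain x
    case-chain) join path.

    An item with R linked replicates and C linked cases yields R*C rows;
    items lacking either bridge are padded with nulls so they remain
    searchable (annotation items have no biological dimension).  Every core
    attribute appears exactly once per row.
    """
    items = (repo.items
             .merge(repo.experiment_types, left_on="experiment_type_ref",
                    right_on="experiment_type_id", how="left")
             .merge(repo.datasets, left_on="dataset_ref",
                    right_on="dataset_id", how="left"))
    bio = (repo.replicate2item
           .merge(repo.replicates, on="replicate_id", how="left")
           .merge(repo.biosamples, left_on="biosample_ref",
                  right_on="biosample_id", how="left")
           .merge(repo.donors, left_on="donor_ref", right_on="donor_id",
                  how="left"))
    mgmt = (repo.case2item
            .merge(repo.case_studies, on="case_study_id", how="left")
            .merge(repo.projects, left_on="project_ref",
                   right_on="project_id", how="left"))
    den = (items
           .merge(bio, on="item_id", how="left")
           .merge(mgmt, on="item_id", how="left"))
    return den.reset_index(drop=True)
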