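"""Project configuration and study data dictionaries.

Everything study-specific — table schemas, allowable codes, lookup
recodings, QC severities, bucket layout, report definitions — lives in a
single project-wide YAML file. Code in the rest of the package is generic
and is steered entirely by the :class:`ProjectConfig` produced here, so a
study can be re-dictionaried, re-bucketed or re-reported without touching
source.

The dictionary dialect is a YAML sub-schema::

    study_id: my_study
    dictionaries:
      donor:
        level: 1
        fields:
          - {name: donor_id, type: text, max_length: 12, required: true,
             key: primary}
          - {name: race, type: code, codes: [W, B, A, U]}
    lookups:
      - name: race_group
        source: [donor, race]
        versions:
          1: {W: White, B: Black, A: Asian, U: Unknown}
    buckets: [...]
    reports: [...]

Field attributes: ``type`` (text | integer | decimal | date | datetime |
code), ``max_length``, ``codes`` (enumerated types only), ``required``,
``key`` (primary | foreign), ``references`` ([table, field] for foreign
keys), ``pii`` (none | indirect | direct), ``date_bounds`` ([min, max]),
``privacy`` ({transform, applied_at}).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigConsistencyError, ConfigSyntaxError, UsageError

#: The closed vocabulary of QC issue kinds.
KINDS = (
    "TYPE",
    "LENGTH",
    "DATE",
    "ENUM",
    "REQUIRED",
    "DUP_KEY",
    "FK_ORPHAN",
    "UNKNOWN_COLUMN",
    "MISSING_COLUMN",
)

#: Default per-kind severity. Everything rejects a submission except an
#: unexpected extra column, which is tolerated with a warning so that
#: submitters may carry convenience columns the study ignores.
DEFAULT_QC_POLICY: dict[str, str] = {k: "reject" for k in KINDS}
DEFAULT_QC_POLICY["UNKNOWN_COLUMN"] = "warn"

#: Sentinel study-group value for lookup inputs with no mapping.
#: Unknown source values are data, not errors; they surface as this.
UNMAPPED = "__unmapped__"

SemanticType = Literal["text", "integer", "decimal", "date", "datetime", "code"]
KeyRole = Literal["none", "primary", "foreign"]
PiiClass = Literal["none", "indirect", "direct"]


class PrivacyDecl(BaseModel):
    """Privacy-minimization transform declared on a field."""

    transform: Literal[
        "truncate-date-to-month", "truncate-zip-to-3", "drop", "pass"
    ]
    applied_at: Literal["import", "report", "both"] = "import"
    #: Explicit, recorded opt-out from the "direct PII must be dropped" rule.
    override: bool = False

    model_config = {"frozen": True}


class FieldSpec(BaseModel):
    """One data-dictionary entry: the full constraint set for a field."""

    name: str
    semantic_type: SemanticType = Field(alias="type")
    max_length: Optional[int] = None
    allowed_codes: Optional[tuple[str, ...]] = Field(default=None, alias="codes")
    required: bool = False
    key_role: KeyRole = Field(default="none", alias="key")
    foreign_target: Optional[tuple[str, str]] = Field(
        default=None, alias="references"
    )
    pii_class: PiiClass = Field(default="none", alias="pii")
    date_bounds: Optional[tuple[_dt.date, _dt.date]] = None
    privacy: Optional[PrivacyDecl] = None

    model_config = {"populate_by_name": True, "frozen": True}

    @field_validator("allowed_codes", mode="before")
    @classmethod
    def _codes_as_tuple(cls, v):
        if v is None:
            return None
        return tuple(str(c) for c in v)

    @field_validator("date_bounds", mode="before")
    @classmethod
    def _bounds_as_dates(cls, v):
        if v is None:
            return None
        lo, hi = v
        return (_as_date(lo), _as_date(hi))

    @model_validator(mode="after")
    def _invariants(self):
        if (self.semantic_type == "code") != bool(self.allowed_codes):
            raise ValueError(
                f"field {self.name!r}: allowed codes and type 'code' imply "
                "each other"
            )
        if self.max_length is not None and self.max_length < 1:
            raise ValueError(f"field {self.name!r}: max_length must be >= 1")
        if self.key_role == "foreign" and self.foreign_target is None:
            raise ValueError(
                f"field {self.name!r}: foreign key without a referenced "
                "(table, field)"
            )
        if self.date_bounds is not None and self.semantic_type not in (
            "date",
            "datetime",
        ):
            raise ValueError(
                f"field {self.name!r}: date_bounds on a non-date field"
            )
        return self

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"name": self.name, "type": self.semantic_type}
        if self.max_length is not None:
            d["max_length"] = self.max_length
        if self.allowed_codes:
            d["codes"] = list(self.allowed_codes)
        if self.required:
            d["required"] = True
        if self.key_role != "none":
            d["key"] = self.key_role
        if self.foreign_target:
            d["references"] = list(self.foreign_target)
        if self.pii_class != "none":
            d["pii"] = self.pii_class
        if self.date_bounds:
            d["date_bounds"] = [b.isoformat() for b in self.date_bounds]
        if self.privacy:
            d["privacy"] = self.privacy.model_dump(exclude_defaults=True)
        return d


def _as_date(v) -> _dt.date:
    if isinstance(v, _dt.datetime):
        return v.date()
    if isinstance(v, _dt.date):
        return v
    return _dt.date.fromisoformat(str(v))


class TableSchema(BaseModel):
    """A table of the study dictionary: ordered fields plus a dependency level.

    Lower levels are parents; a level-2 table may hold foreign keys into
    level-1 tables, and intake processes levels in ascending order.
    """

    name: str
    fields: tuple[FieldSpec, ...]
    level: int = 1

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _invariants(self):
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"table {self.name!r}: duplicate fields {dupes}")
        if not any(f.key_role == "primary" for f in self.fields):
            raise ValueError(f"table {self.name!r}: no primary key declared")
        return self

    @property
    def field_map(self) -> dict[str, FieldSpec]:
        return {f.name: f for f in self.fields}

    @property
    def primary_key(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields if f.key_role == "primary")

    @property
    def foreign_keys(self) -> tuple[FieldSpec, ...]:
        return tuple(f for f in self.fields if f.key_role == "foreign")

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "fields": [f.to_dict() for f in self.fields],
        }


class LookupTable(BaseModel):
    """Versioned mapping from source values to study-specific groupings.

    Originals are never overwritten: the store keeps the source column and
    writes the grouping into a derived column, so stakeholders can revise
    groupings by publishing a new version.
    """

    name: str
    source_field: tuple[str, str] = Field(alias="source")
    versions: dict[int, dict[str, str]]

    model_config = {"populate_by_name": True, "frozen": True}

    @model_validator(mode="after")
    def _invariants(self):
        if not self.versions:
            raise ValueError(f"lookup {self.name!r}: no versions")
        if any(v < 1 for v in self.versions):
            raise ValueError(f"lookup {self.name!r}: versions start at 1")
        return self

    @property
    def latest_version(self) -> int:
        return max(self.versions)

    @property
    def mapping(self) -> dict[str, str]:
        return self.versions[self.latest_version]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "source": list(self.source_field),
            "versions": {v: dict(m) for v, m in sorted(self.versions.items())},
        }


def resolve_lookup(
    lookup: LookupTable, value: str, version: int | None = None
) -> str:
    """Map a source value to its study group under a lookup version.

    Returns :data:`UNMAPPED` for values absent from the mapping — unknown
    source codes are a data finding, never an exception.
    """
    if version is None:
        version = lookup.latest_version
    if version not in lookup.versions:
        raise UsageError(
            f"lookup {lookup.name!r} has no version {version}"
        )
    return lookup.versions[version].get(value, UNMAPPED)


class BucketConfig(BaseModel):
    """Per-organization exchange area definition.

    ``root`` is resolved against the runtime working directory; the three
    lifecycle directories (upload, download, archive) live beneath it.
    """

    org_id: str
    root: str
    expected_tables: tuple[str, ...]
    schedule: str = "monthly"

    model_config = {"frozen": True}

    def to_dict(self) -> dict:
        return {
            "org_id": self.org_id,
            "root": self.root,
            "expected_tables": list(self.expected_tables),
            "schedule": self.schedule,
        }


class SourceSelect(BaseModel):
    table: str
    fields: tuple[str, ...]

    model_config = {"frozen": True}


class QcHook(BaseModel):
    """Cross-field predicate: ``require`` must be non-empty on rows where
    ``when`` equals ``equals``."""

    require: str
    when: str
    equals: str

    model_config = {"frozen": True}


class ReportSpec(BaseModel):
    """Configuration-driven outbound report definition.

    Transforms form a small closed vocabulary (rename, lookup recode,
    constant, cross-field map, privacy) applied in declared order; order is
    part of the spec's identity (see :meth:`digest`).
    """

    name: str
    source: tuple[SourceSelect, ...]
    transforms: tuple[dict, ...] = ()
    target_schema: TableSchema
    qc_hooks: tuple[QcHook, ...] = ()
    destination: Optional[str] = None

    model_config = {"frozen": True}

    _OPS = {"rename", "lookup", "constant", "cross_field", "privacy"}

    @model_validator(mode="after")
    def _invariants(self):
        for t in self.transforms:
            op = t.get("op")
            if op not in self._OPS:
                raise ValueError(
                    f"report {self.name!r}: unknown transform op {op!r}"
                )
        return self

    def digest(self) -> str:
        """Order-sensitive fingerprint; permuting transforms changes it."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "source": [
                {"table": s.table, "fields": list(s.fields)} for s in self.source
            ],
            "transforms": [dict(t) for t in self.transforms],
            "target_schema": {
                "name": self.target_schema.name,
                **self.target_schema.to_dict(),
            },
            "qc_hooks": [h.model_dump() for h in self.qc_hooks],
            **({"destination": self.destination} if self.destination else {}),
        }


class ProjectConfig(BaseModel):
    """The fully-resolved project configuration."""

    study_id: str
    dictionaries: dict[str, TableSchema]
    lookups: tuple[LookupTable, ...] = ()
    qc_policy: dict[str, str] = Field(default_factory=dict)
    buckets: tuple[BucketConfig, ...] = ()
    reports: tuple[ReportSpec, ...] = ()
    #: Opaque pass-through settings (paths, credentials, connection strings);
    #: resolved by the transport layer, never interpreted here.
    settings: dict[str, Any] = Field(default_factory=dict)

    model_config = {"frozen": False}

    def severity(self, kind: str) -> str:
        return self.qc_policy.get(kind, DEFAULT_QC_POLICY[kind])

    def lookup(self, name: str) -> LookupTable:
        for lk in self.lookups:
            if lk.name == name:
                return lk
        raise UsageError(f"no lookup named {name!r}")

    def report_spec(self, name: str) -> ReportSpec:
        for r in self.reports:
            if r.name == name:
                return r
        raise UsageError(f"no report named {name!r}")

    def tables_by_level(self) -> list[TableSchema]:
        return sorted(
            self.dictionaries.values(), key=lambda t: (t.level, t.name)
        )

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "study_id": self.study_id,
            "dictionaries": {
                name: schema.to_dict()
                for name, schema in self.dictionaries.items()
            },
        }
        if self.lookups:
            d["lookups"] = [lk.to_dict() for lk in self.lookups]
        if self.qc_policy:
            d["qc_policy"] = dict(self.qc_policy)
        if self.buckets:
            d["buckets"] = [b.to_dict() for b in self.buckets]
        if self.reports:
            d["reports"] = [r.to_dict() for r in self.reports]
        if self.settings:
            d["settings"] = dict(self.settings)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


_TOP_LEVEL_KEYS = {
    "study_id",
    "dictionaries",
    "lookups",
    "qc_policy",
    "buckets",
    "reports",
    "settings",
}


def parse_config(raw: dict) -> ProjectConfig:
    """Build and cross-validate a :class:`ProjectConfig` from a mapping.

    All dangling references are collected and reported together in a single
    :class:`ConfigConsistencyError`; a config author fixes one pass, not one
    error at a time. Unknown top-level keys warn instead of failing so that
    older configuration files keep running on newer code.
    """
    if not isinstance(raw, dict):
        raise ConfigSyntaxError("configuration root must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        warnings.warn(
            f"ignoring unknown configuration keys: {sorted(unknown)}",
            stacklevel=2,
        )

    problems: list[str] = []

    dictionaries: dict[str, TableSchema] = {}
    for tname, tdef in (raw.get("dictionaries") or {}).items():
        fields = [FieldSpec(**f) for f in tdef.get("fields", [])]
        dictionaries[tname] = TableSchema(
            name=tname, fields=tuple(fields), level=tdef.get("level", 1)
        )

    lookups = tuple(LookupTable(**lk) for lk in raw.get("lookups") or ())
    buckets = tuple(BucketConfig(**b) for b in raw.get("buckets") or ())

    reports = []
    for rdef in raw.get("reports") or ():
        tdef = rdef.get("target_schema", {})
        target = TableSchema(
            name=tdef.get("name", rdef["name"]),
            fields=tuple(FieldSpec(**f) for f in tdef.get("fields", [])),
            level=tdef.get("level", 1),
        )
        reports.append(
            ReportSpec(
                name=rdef["name"],
                source=tuple(SourceSelect(**s) for s in rdef.get("source", [])),
                transforms=tuple(rdef.get("transforms", ())),
                target_schema=target,
                qc_hooks=tuple(QcHook(**h) for h in rdef.get("qc_hooks", ())),
                destination=rdef.get("destination"),
            )
        )

    qc_policy = dict(raw.get("qc_policy") or {})
    for kind, sev in qc_policy.items():
        if kind not in KINDS:
            problems.append(f"qc_policy names unknown check kind {kind!r}")
        elif sev not in ("reject", "warn"):
            problems.append(f"qc_policy[{kind}] must be reject or warn")

    # -- cross-reference validation: collect every dangling item -----------
    for tname, schema in dictionaries.items():
        for f in schema.fields:
            if f.key_role == "foreign":
                tgt_table, tgt_field = f.foreign_target
                tgt = dictionaries.get(tgt_table)
                if tgt is None:
                    problems.append(
                        f"('{tname}', '{f.name}') references missing table "
                        f"'{tgt_table}'"
                    )
                elif tgt_field not in tgt.field_map:
                    problems.append(
                        f"('{tname}', '{f.name}') references missing field "
                        f"('{tgt_table}', '{tgt_field}')"
                    )
            if (
                f.pii_class == "direct"
                and not (
                    f.privacy
                    and (f.privacy.transform == "drop" or f.privacy.override)
                )
            ):
                problems.append(
                    f"('{tname}', '{f.name}') is direct PII without a drop "
                    "transform or a recorded override"
                )

    for lk in lookups:
        st, sf = lk.source_field
        if st not in dictionaries:
            problems.append(
                f"lookup '{lk.name}' sources missing table '{st}'"
            )
        elif sf not in dictionaries[st].field_map:
            problems.append(
                f"lookup '{lk.name}' sources missing field ('{st}', '{sf}')"
            )

    for b in buckets:
        for t in b.expected_tables:
            if t not in dictionaries:
                problems.append(
                    f"bucket '{b.org_id}' expects missing table '{t}'"
                )

    lookup_names = {lk.name for lk in lookups}
    for r in reports:
        produced: dict[str, int] = {}
        for sel in r.source:
            if sel.table not in dictionaries:
                problems.append(
                    f"report '{r.name}' selects from missing table "
                    f"'{sel.table}'"
                )
                continue
            fm = dictionaries[sel.table].field_map
            for fld in sel.fields:
                if fld not in fm:
                    problems.append(
                        f"report '{r.name}' selects missing field "
                        f"('{sel.table}', '{fld}')"
                    )
                produced[fld] = produced.get(fld, 0) + 1
        for t in r.transforms:
            if t.get("op") == "lookup" and t.get("lookup") not in lookup_names:
                problems.append(
                    f"report '{r.name}' recodes via missing lookup "
                    f"'{t.get('lookup')}'"
                )
            tgt = t.get("target")
            if tgt:
                produced[tgt] = produced.get(tgt, 0) + 1
            if t.get("op") == "rename" and t.get("field") in produced:
                # a rename consumes its source column
                produced[t["field"]] -= 1
        for f in r.target_schema.fields:
            n = produced.get(f.name, 0)
            if n == 0:
                problems.append(
                    f"report '{r.name}' target field '{f.name}' is produced "
                    "by no selection or transform"
                )
            elif n > 1:
                problems.append(
                    f"report '{r.name}' target field '{f.name}' is produced "
                    f"{n} times"
                )

    if problems:
        raise ConfigConsistencyError(problems)

    return ProjectConfig(
        study_id=raw.get("study_id", "unnamed_study"),
        dictionaries=dictionaries,
        lookups=lookups,
        qc_policy=qc_policy,
        buckets=buckets,
        reports=tuple(reports),
        settings=dict(raw.get("settings") or {}),
    )


def load_config(
    path: str | Path, user_config: str | Path | None = None
) -> ProjectConfig:
    """Load the project configuration, optionally overlaying a per-user file.

    The user file shallow-merges over the project file: a top-level key
    present in the user file replaces the project one wholesale. This keeps
    individual configurations (e.g. local paths, credentials) out of the
    shared project file without any deep-merge ambiguity.
    """
    raw = _read_yaml(path)
    if user_config is not None:
        overlay = _read_yaml(user_config)
        raw = {**raw, **overlay}
    return parse_config(raw)


def _read_yaml(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise ConfigSyntaxError(f"configuration file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        line = None
        mark = getattr(exc, "problem_mark", None)
        if mark is not None:
            line = mark.line + 1
        raise ConfigSyntaxError(
            f"cannot parse {p}: {exc}", line=line
        ) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigSyntaxError(f"{p}: configuration root must be a mapping")
    return raw


# --------------------------------------------------------------------------
# dictionary diffing


class SchemaChange(BaseModel):
    """One entry of a dictionary change-list.

    ``action`` is added/removed/modified; modified entries name the single
    attribute that changed, so a field whose length and codes both changed
    contributes two entries.
    """

    action: Literal["added", "removed", "modified"]
    field: str
    attribute: Optional[str] = None
    old_value: Any = None
    new_value: Any = None
    #: Full spec for added fields, plus its position in the new schema,
    #: so a change-list is sufficient to reconstruct the new schema.
    spec: Optional[FieldSpec] = None
    index: Optional[int] = None

    model_config = {"frozen": True}


_DIFF_ATTRS = (
    "semantic_type",
    "max_length",
    "allowed_codes",
    "required",
    "key_role",
    "foreign_target",
    "pii_class",
    "date_bounds",
    "privacy",
)


def diff_dictionaries(old: TableSchema, new: TableSchema) -> list[SchemaChange]:
    """Itemize field-level differences between two versions of a table schema.

    Empty iff the schemas are identical. Applying the result to ``old`` with
    :func:`apply_changes` reproduces ``new``.
    """
    if old.name != new.name:
        raise UsageError(
            f"cannot diff schemas of different tables: {old.name!r} vs "
            f"{new.name!r}"
        )
    changes: list[SchemaChange] = []
    old_map, new_map = old.field_map, new.field_map
    for idx, f in enumerate(new.fields):
        if f.name not in old_map:
            changes.append(
                SchemaChange(action="added", field=f.name, spec=f, index=idx)
            )
    for f in old.fields:
        if f.name not in new_map:
            changes.append(SchemaChange(action="removed", field=f.name))
    for name, nf in new_map.items():
        of = old_map.get(name)
        if of is None:
            continue
        for attr in _DIFF_ATTRS:
            ov, nv = getattr(of, attr), getattr(nf, attr)
            if ov != nv:
                changes.append(
                    SchemaChange(
                        action="modified",
                        field=name,
                        attribute=attr,
                        old_value=ov,
                        new_value=nv,
                    )
                )
    return changes


def apply_changes(
    old: TableSchema, changes: list[SchemaChange]
) -> TableSchema:
    """Replay a change-list from :func:`diff_dictionaries` onto a schema."""
    fields: list[FieldSpec | None] = [
        f for f in old.fields
        if f.name not in {c.field for c in changes if c.action == "removed"}
    ]
    mods: dict[str, dict[str, Any]] = {}
    for c in changes:
        if c.action == "modified":
            mods.setdefault(c.field, {})[c.attribute] = c.new_value
    fields = [
        f.model_copy(update=mods[f.name]) if f.name in mods else f
        for f in fields
    ]
    for c in sorted(
        (c for c in changes if c.action == "added"), key=lambda c: c.index
    ):
        fields.insert(min(c.index, len(fields)), c.spec)
    return TableSchema(name=old.name, fields=tuple(fields), level=old.level)


def demo_config_path() -> Path:
    """Path of the demo study configuration shipped with the package."""
    return Path(__file__).parent / "data" / "demo_config.yaml"


def load_demo_config() -> ProjectConfig:
    return load_config(demo_config_path())
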