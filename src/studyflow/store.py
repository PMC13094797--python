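"""The canonical study database.

The relational schema is derived mechanically from the data dictionary,
and the dictionary's constraints are materialized in SQL — STRICT column
types, NOT NULL for required fields, CHECK constraints for lengths and
enumerated codes, primary and foreign keys — so the database itself
refuses dictionary-violating rows. This makes the store a redundant QC
line: even a row that slipped past (or was deliberately waved through)
the rule-based engine is stopped at the door.

Imports are all-or-nothing: an accepted submission is written in a single
transaction and a mid-import constraint violation rolls the whole
submission back, so the store never holds half a submission. Imports are
idempotent on the submission id (a content digest), which makes the
archive replayable for audit.

Privacy minimization happens at import for fields so declared: the store
only ever holds the minimized form (month-level dates, 3-digit ZIP
prefixes), and column checks are relaxed to the minimized domain.
"""

from __future__ import annotations

import csv
import datetime as _dt
import sqlite3
from pathlib import Path
from typing import Mapping, Optional

from pydantic import BaseModel

from .config import UNMAPPED, FieldSpec, LookupTable, ProjectConfig, TableSchema
from .errors import (
    DataIntegrityError,
    MigrationError,
    UsageError,
)
from .privacy import apply_privacy, rules_from_config
from .qc import ValidationReport, read_delimited


class ImportResult(BaseModel):
    submission_id: str
    rows_attempted: int
    rows_written: int
    outcome: str  # committed | rolled_back
    error: Optional[str] = None

    model_config = {"frozen": True}


class RecodeReport(BaseModel):
    table: str
    field: str
    lookup: str
    version: int
    rows: int
    mapped: int
    unmapped: int
    changed: int

    model_config = {"frozen": True}


def _sql_type(spec: FieldSpec) -> str:
    if spec.semantic_type == "integer":
        return "INTEGER"
    if spec.semantic_type == "decimal":
        return "REAL"
    return "TEXT"


_DATE_GLOB = "[0-9][0-9][0-9][0-9]-[0-9][0-9]-[0-9][0-9]"
_MONTH_GLOB = "[0-9][0-9][0-9][0-9]-[0-9][0-9]"
_ZIP3_GLOB = "[0-9][0-9][0-9]"


def _column_ddl(spec: FieldSpec, import_transform: str | None) -> str:
    parts = [f'"{spec.name}" {_sql_type(spec)}']
    if spec.required:
        parts.append("NOT NULL")
    checks: list[str] = []
    col = f'"{spec.name}"'
    eff_len = spec.max_length
    if import_transform == "truncate-zip-to-3":
        checks.append(f"({col} IS NULL OR {col} GLOB '{_ZIP3_GLOB}')")
        eff_len = None
    elif import_transform == "truncate-date-to-month":
        checks.append(f"({col} IS NULL OR {col} GLOB '{_MONTH_GLOB}')")
        eff_len = None
    elif spec.semantic_type == "date":
        checks.append(f"({col} IS NULL OR {col} GLOB '{_DATE_GLOB}*')")
    if eff_len is not None and spec.semantic_type != "decimal":
        checks.append(
            f"({col} IS NULL OR length(CAST({col} AS TEXT)) <= {eff_len})"
        )
    if spec.allowed_codes:
        codes = ",".join("'" + c.replace("'", "''") + "'" for c in spec.allowed_codes)
        checks.append(f"({col} IS NULL OR {col} IN ({codes}))")
    for c in checks:
        parts.append(f"CHECK {c}")
    return " ".join(parts)


def table_ddl(schema: TableSchema, import_rules: Mapping[tuple[str, str], object]) -> str:
    cols = []
    for f in schema.fields:
        rule = import_rules.get((schema.name, f.name))
        transform = getattr(rule, "transform", None)
        cols.append(_column_ddl(f, transform))
    pk = ", ".join(f'"{n}"' for n in schema.primary_key)
    cols.append(f"PRIMARY KEY ({pk})")
    for fk in schema.foreign_keys:
        t, f = fk.foreign_target
        cols.append(
            f'FOREIGN KEY ("{fk.name}") REFERENCES "{t}" ("{f}")'
        )
    body = ",\n  ".join(cols)
    return f'CREATE TABLE "{schema.name}" (\n  {body}\n) STRICT'


_INFRA_DDL = {
    "identifier_change": (
        'CREATE TABLE "identifier_change" (\n'
        "  tbl TEXT NOT NULL, old_id TEXT NOT NULL, new_id TEXT NOT NULL,\n"
        "  effective_date TEXT NOT NULL,\n"
        "  PRIMARY KEY (tbl, old_id)\n) STRICT"
    ),
    "_submissions": (
        'CREATE TABLE "_submissions" (\n'
        "  submission_id TEXT PRIMARY KEY, tables TEXT NOT NULL,\n"
        "  rows_written INTEGER NOT NULL, imported_at TEXT NOT NULL\n) STRICT"
    ),
    "_intake_log": (
        'CREATE TABLE "_intake_log" (\n'
        "  org TEXT NOT NULL, file TEXT NOT NULL, digest TEXT NOT NULL,\n"
        "  disposition TEXT NOT NULL, processed_at TEXT NOT NULL\n) STRICT"
    ),
    "_row_audit": (
        'CREATE TABLE "_row_audit" (\n'
        "  tbl TEXT NOT NULL, pk TEXT NOT NULL, field TEXT NOT NULL,\n"
        "  old_value TEXT, new_value TEXT, submission_id TEXT NOT NULL\n) STRICT"
    ),
}


class StudyStore:
    """Thin handle over the embedded relational engine.

    The backend is abstracted behind this class: everything upstream talks
    schemas, submissions and key sets, never SQL, so a different relational
    engine could implement the same surface.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        if self.path != ":memory:":
            Path(self.path).parent.mkdir(parents=True, exist_ok=True)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self._config: ProjectConfig | None = None

    def close(self) -> None:
        self.conn.close()

    # -- schema ------------------------------------------------------------

    def create_schema(self, config: ProjectConfig) -> None:
        """Materialize the dictionary: one relation per table plus one per
        lookup, the identifier-change trail, and bookkeeping relations.

        Raises :class:`MigrationError` if the store already holds an
        incompatible relation of the same name.
        """
        if not config.dictionaries:
            raise UsageError("a study must define at least one table")
        self._config = config
        import_rules = rules_from_config(config, stage="import")
        existing = dict(
            self.conn.execute(
                "SELECT name, sql FROM sqlite_master WHERE type='table'"
            ).fetchall()
        )
        stmts: dict[str, str] = {}
        for schema in config.tables_by_level():
            stmts[schema.name] = table_ddl(schema, import_rules)
        for lk in config.lookups:
            stmts[f"lookup_{lk.name}"] = (
                f'CREATE TABLE "lookup_{lk.name}" (\n'
                "  version INTEGER NOT NULL, original TEXT NOT NULL,\n"
                "  study_group TEXT NOT NULL,\n"
                "  PRIMARY KEY (version, original)\n) STRICT"
            )
        stmts.update(_INFRA_DDL)
        for name, sql in stmts.items():
            if name in existing:
                if _normalize_sql(existing[name]) != _normalize_sql(sql):
                    raise MigrationError(
                        f"existing relation {name!r} is incompatible with "
                        "the current dictionary"
                    )
                continue
            self.conn.execute(sql)
        for lk in config.lookups:
            self._load_lookup_rows(lk)
        self.conn.commit()

    def _load_lookup_rows(self, lk: LookupTable) -> None:
        for version, mapping in lk.versions.items():
            for original, group in mapping.items():
                self.conn.execute(
                    f'INSERT OR REPLACE INTO "lookup_{lk.name}" '
                    "(version, original, study_group) VALUES (?,?,?)",
                    (version, original, group),
                )

    def ddl_dump(self) -> str:
        rows = self.conn.execute(
            "SELECT sql FROM sqlite_master WHERE type IN ('table','trigger') "
            "AND sql IS NOT NULL ORDER BY name"
        ).fetchall()
        return ";\n".join(r[0] for r in rows) + ";\n"

    def relation_names(self) -> list[str]:
        return [
            r[0]
            for r in self.conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table' "
                "ORDER BY name"
            )
        ]

    # -- import ------------------------------------------------------------

    def import_submission(
        self,
        files: Mapping[str, str | Path],
        report: ValidationReport,
        config: ProjectConfig | None = None,
    ) -> ImportResult:
        """Write an accepted submission in one transaction.

        Re-importing an already-archived submission id is a committed no-op.
        A mid-import constraint violation rolls everything back and names
        the violating row. Rows whose foreign keys reference a changed
        identifier are stored under the canonical id; the original survives
        in the identifier-change trail.
        """
        config = config or self._require_config()
        if not report.accepted:
            raise UsageError(
                "import_submission requires an accepted validation report"
            )
        sid = report.submission_id
        already = self.conn.execute(
            "SELECT 1 FROM _submissions WHERE submission_id=?", (sid,)
        ).fetchone()
        if already:
            return ImportResult(
                submission_id=sid,
                rows_attempted=0,
                rows_written=0,
                outcome="committed",
            )

        import_rules = rules_from_config(config, stage="import")
        order = sorted(
            files.keys(), key=lambda t: (config.dictionaries[t].level, t)
        )
        attempted = 0
        written = 0
        cur = self.conn.cursor()
        try:
            cur.execute("BEGIN")
            for tname in order:
                schema = config.dictionaries[tname]
                _, rows = read_delimited(files[tname])
                attempted += len(rows)
                for ordinal, row in enumerate(rows, start=1):
                    values = self._prepare_row(
                        tname, schema, row, import_rules
                    )
                    try:
                        self._upsert(cur, schema, values, sid)
                    except sqlite3.IntegrityError as exc:
                        cur.execute("ROLLBACK")
                        return ImportResult(
                            submission_id=sid,
                            rows_attempted=attempted,
                            rows_written=0,
                            outcome="rolled_back",
                            error=(
                                f"constraint violation at table {tname!r} "
                                f"row {ordinal}: {exc}"
                            ),
                        )
                    written += 1
            cur.execute(
                "INSERT INTO _submissions "
                "(submission_id, tables, rows_written, imported_at) "
                "VALUES (?,?,?,?)",
                (
                    sid,
                    ",".join(order),
                    written,
                    _dt.datetime.now().isoformat(timespec="seconds"),
                ),
            )
            cur.execute("COMMIT")
        except Exception:
            try:
                cur.execute("ROLLBACK")
            except sqlite3.OperationalError:
                pass
            raise
        return ImportResult(
            submission_id=sid,
            rows_attempted=attempted,
            rows_written=written,
            outcome="committed",
        )

    def _prepare_row(
        self,
        tname: str,
        schema: TableSchema,
        row: Mapping[str, str],
        import_rules,
    ) -> dict[str, object]:
        values: dict[str, object] = {}
        for f in schema.fields:
            v: object = row.get(f.name, "")
            rule = import_rules.get((tname, f.name))
            if rule is not None and isinstance(v, str):
                v = apply_privacy(v, rule)
            if v == "":
                v = None
            elif f.semantic_type == "integer":
                v = int(v)
            elif f.semantic_type == "decimal":
                v = float(v)
            if (
                v is not None
                and f.key_role == "foreign"
                and self._has_changes(f.foreign_target[0])
            ):
                v = self.resolve_identifier(f.foreign_target[0], str(v))
            values[f.name] = v
        return values

    def _upsert(self, cur, schema: TableSchema, values: dict, sid: str) -> None:
        """Insert, or update-with-audit when the primary key already exists
        (periodic refreshes of parent-level data are updates, and every
        overwritten value is recorded)."""
        cols = list(values)
        pk = schema.primary_key
        key = tuple(values[k] for k in pk)
        where = " AND ".join(f'"{k}"=?' for k in pk)
        existing = None
        if all(k is not None for k in key):
            existing = cur.execute(
                f'SELECT {", ".join(chr(34)+c+chr(34) for c in cols)} '
                f'FROM "{schema.name}" WHERE {where}',
                key,
            ).fetchone()
        if existing is None:
            placeholders = ",".join("?" for _ in cols)
            collist = ",".join(f'"{c}"' for c in cols)
            cur.execute(
                f'INSERT INTO "{schema.name}" ({collist}) '
                f"VALUES ({placeholders})",
                [values[c] for c in cols],
            )
            return
        old = dict(zip(cols, existing))
        changed = {c: values[c] for c in cols if old[c] != values[c]}
        if not changed:
            return
        setlist = ", ".join(f'"{c}"=?' for c in changed)
        cur.execute(
            f'UPDATE "{schema.name}" SET {setlist} WHERE {where}',
            [changed[c] for c in changed] + list(key),
        )
        for c, newv in changed.items():
            cur.execute(
                "INSERT INTO _row_audit "
                "(tbl, pk, field, old_value, new_value, submission_id) "
                "VALUES (?,?,?,?,?,?)",
                (
                    schema.name,
                    "|".join(str(k) for k in key),
                    c,
                    None if old[c] is None else str(old[c]),
                    None if newv is None else str(newv),
                    sid,
                ),
            )

    # -- recoding ----------------------------------------------------------

    def recode(
        self,
        table: str,
        field: str,
        lookup: LookupTable,
        version: int | None = None,
    ) -> RecodeReport:
        """Write/refresh the derived study-grouping column for a lookup.

        The original column is never touched; the grouping lands in a
        derived column named after the lookup. Unmapped source values get
        the unmapped sentinel and are counted.
        """
        if tuple(lookup.source_field) != (table, field):
            raise UsageError(
                f"lookup {lookup.name!r} sources "
                f"{lookup.source_field}, not ({table!r}, {field!r})"
            )
        version = version or lookup.latest_version
        mapping = lookup.versions.get(version)
        if mapping is None:
            raise UsageError(f"lookup {lookup.name!r}: no version {version}")
        cols = [
            r[1]
            for r in self.conn.execute(f'PRAGMA table_info("{table}")')
        ]
        if field not in cols:
            raise UsageError(f"no column {field!r} in table {table!r}")
        derived = lookup.name
        if derived not in cols:
            self.conn.execute(
                f'ALTER TABLE "{table}" ADD COLUMN "{derived}" TEXT'
            )
        schema = self._require_config().dictionaries[table]
        pk = schema.primary_key
        pklist = ", ".join(f'"{k}"' for k in pk)
        rows = self.conn.execute(
            f'SELECT {pklist}, "{field}", "{derived}" FROM "{table}"'
        ).fetchall()
        mapped = unmapped = changed = 0
        updates = []
        for r in rows:
            key, source, old_derived = r[: len(pk)], r[len(pk)], r[len(pk) + 1]
            if source is None:
                new = None
            elif str(source) in mapping:
                new = mapping[str(source)]
                mapped += 1
            else:
                new = UNMAPPED
                unmapped += 1
            if new != old_derived:
                changed += 1
                updates.append((new, *key))
        where = " AND ".join(f'"{k}"=?' for k in pk)
        self.conn.executemany(
            f'UPDATE "{table}" SET "{derived}"=? WHERE {where}', updates
        )
        self.conn.commit()
        return RecodeReport(
            table=table,
            field=field,
            lookup=lookup.name,
            version=version,
            rows=len(rows),
            mapped=mapped,
            unmapped=unmapped,
            changed=changed,
        )

    # -- identifier changes --------------------------------------------------

    def record_identifier_change(
        self, table: str, old_id: str, new_id: str, effective_date: str
    ) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO identifier_change "
            "(tbl, old_id, new_id, effective_date) VALUES (?,?,?,?)",
            (table, old_id, new_id, effective_date),
        )
        self.conn.commit()

    def _has_changes(self, table: str) -> bool:
        r = self.conn.execute(
            "SELECT 1 FROM identifier_change WHERE tbl=? LIMIT 1", (table,)
        ).fetchone()
        return r is not None

    def resolve_identifier(self, table: str, id: str) -> str:
        """Follow the identifier-change chain to its terminus; identity when
        no change is recorded. A cycle is a data-integrity error."""
        seen = {id}
        current = id
        while True:
            r = self.conn.execute(
                "SELECT new_id FROM identifier_change WHERE tbl=? AND old_id=?",
                (table, current),
            ).fetchone()
            if r is None:
                return current
            current = r[0]
            if current in seen:
                raise DataIntegrityError(
                    f"identifier-change cycle in table {table!r} at "
                    f"{current!r}"
                )
            seen.add(current)

    # -- queries -----------------------------------------------------------

    def row_count(self, table: str) -> int:
        return self.conn.execute(
            f'SELECT COUNT(*) FROM "{table}"'
        ).fetchone()[0]

    def primary_key_set(self, table: str) -> set:
        schema = self._require_config().dictionaries[table]
        pk = schema.primary_key
        pklist = ", ".join(f'"{k}"' for k in pk)
        rows = self.conn.execute(f'SELECT {pklist} FROM "{table}"').fetchall()
        if len(pk) == 1:
            return {str(r[0]) for r in rows}
        return {tuple(str(v) for v in r) for r in rows}

    def key_context(self) -> dict[str, set]:
        """Primary-key sets of every dictionary table, for QC key checks."""
        return {
            t: self.primary_key_set(t)
            for t in self._require_config().dictionaries
        }

    def export_csv(self, table: str, path: str | Path) -> None:
        cols = [
            r[1]
            for r in self.conn.execute(f'PRAGMA table_info("{table}")')
        ]
        rows = self.conn.execute(
            f'SELECT {", ".join(chr(34)+c+chr(34) for c in cols)} '
            f'FROM "{table}"'
        ).fetchall()
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(cols)
            for r in rows:
                w.writerow(["" if v is None else v for v in r])

    def raw_insert(self, table: str, row: Mapping[str, str]) -> None:
        """Insert raw submission strings directly, bypassing the QC engine.

        Exists so the redundant-QC property is testable: the materialized
        constraints must refuse what the rule engine would reject.
        """
        values = {k: (None if v == "" else v) for k, v in row.items()}
        cols = list(values)
        collist = ",".join(f'"{c}"' for c in cols)
        placeholders = ",".join("?" for _ in cols)
        with self.conn:
            self.conn.execute(
                f'INSERT INTO "{table}" ({collist}) VALUES ({placeholders})',
                [values[c] for c in cols],
            )

    # -- intake bookkeeping --------------------------------------------------

    def processed_digests(self) -> set[str]:
        return {
            r[0]
            for r in self.conn.execute("SELECT digest FROM _intake_log")
        }

    def record_intake(
        self, org: str, file: str, digest: str, disposition: str
    ) -> None:
        self.conn.execute(
            "INSERT INTO _intake_log "
            "(org, file, digest, disposition, processed_at) VALUES (?,?,?,?,?)",
            (
                org,
                file,
                digest,
                disposition,
                _dt.datetime.now().isoformat(timespec="seconds"),
            ),
        )
        self.conn.commit()

    # ------------------------------------------------------------------------

    def attach_config(self, config: ProjectConfig) -> None:
        self._config = config

    def _require_config(self) -> ProjectConfig:
        if self._config is None:
            raise UsageError(
                "store has no schema: call create_schema(config) first"
            )
        return self._config


def _normalize_sql(sql: str) -> str:
    return " ".join(sql.split())


def open_store(path: str | Path, config: ProjectConfig) -> StudyStore:
    """Open (creating if needed) a study store for a configuration."""
    store = StudyStore(path)
    store.create_schema(config)
    return store
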