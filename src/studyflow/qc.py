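"""Rule-based validation of tabular submissions against the data dictionary.

A submission (one or more delimited files) is checked cell by cell against
its :class:`~studyflow.config.TableSchema` — data type, length, calendar
validity and bounds of dates, enumerated codes, required fields — and row
by row for key integrity (duplicate primary keys, orphaned foreign keys),
plus table-level header reconciliation. The result is an itemized
:class:`ValidationReport` with an atomic accepted/rejected verdict: a
submission is either imported whole or returned whole to the submitter
with the itemized list for correction and resubmission.

Checking discipline
-------------------
* One root cause per cell: a failed TYPE check suppresses that cell's
  LENGTH/DATE/ENUM checks, so submitters see the actionable problem once.
* An empty cell on a required field is REQUIRED and nothing else; empty
  optional cells are not checked further.
* Dates must be ISO-8601 (``YYYY-MM-DD``); a value of that shape that is
  not a real calendar date (e.g. ``2020-02-30``), or falls outside the
  field's declared bounds, is a DATE finding. Anything else is TYPE.
* Issues are ordered (table, row, field), making reports byte-reproducible
  for a given submission.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional

from pydantic import BaseModel

from .config import (
    FieldSpec,
    ProjectConfig,
    TableSchema,
)
from .errors import TransportError, UsageError

_INT_RE = re.compile(r"^[+-]?[0-9]+$")
_DEC_RE = re.compile(r"^[+-]?([0-9]+(\.[0-9]*)?|\.[0-9]+)$")
_DATE_RE = re.compile(r"^[0-9]{4}-[0-9]{2}-[0-9]{2}$")
_DATETIME_RE = re.compile(
    r"^[0-9]{4}-[0-9]{2}-[0-9]{2}[T ][0-9]{2}:[0-9]{2}(:[0-9]{2})?$"
)


class ValidationIssue(BaseModel):
    kind: str
    table: str
    row: int  # 1-based data row; 0 for table-level findings
    field: str  # empty for table-level findings without a field
    observed: str
    expected: str
    severity: str = "reject"

    model_config = {"frozen": True}

    def key(self) -> tuple[str, str, int, str]:
        """Identity used for ledger comparison: (kind, table, row, field)."""
        return (self.kind, self.table, self.row, self.field)


class ValidationReport(BaseModel):
    submission_id: str
    issues: tuple[ValidationIssue, ...]
    verdict: str  # accepted | rejected
    counts: dict[str, int]
    checked_rows: int

    model_config = {"frozen": True}

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


def finalize_report(
    submission_id: str,
    issues: Iterable[ValidationIssue],
    checked_rows: int,
) -> ValidationReport:
    """Sort issues into canonical (table, row, field) order and derive the
    verdict: rejected iff any issue carries reject severity."""
    ordered = tuple(
        sorted(issues, key=lambda i: (i.table, i.row, i.field, i.kind))
    )
    counts: dict[str, int] = {}
    for i in ordered:
        counts[i.kind] = counts.get(i.kind, 0) + 1
    verdict = (
        "rejected"
        if any(i.severity == "reject" for i in ordered)
        else "accepted"
    )
    return ValidationReport(
        submission_id=submission_id,
        issues=ordered,
        verdict=verdict,
        counts=counts,
        checked_rows=checked_rows,
    )


def _type_ok(value: str, spec: FieldSpec) -> bool:
    if spec.semantic_type == "integer":
        return bool(_INT_RE.match(value))
    if spec.semantic_type == "decimal":
        return bool(_DEC_RE.match(value))
    if spec.semantic_type == "date":
        return bool(_DATE_RE.match(value))
    if spec.semantic_type == "datetime":
        return bool(_DATETIME_RE.match(value))
    return True  # text and code are free-form strings at the type level


def _parse_date(value: str) -> Optional[_dt.date]:
    try:
        return _dt.date.fromisoformat(value[:10])
    except ValueError:
        return None


def check_row(
    row: Mapping[str, str],
    schema: TableSchema,
    row_ordinal: int,
    policy=None,
) -> list[ValidationIssue]:
    """Check one parsed row; emit one issue per violated constraint per
    field, in dictionary field order. Missing cells are empty strings."""
    sev = policy or (lambda kind: "reject" if kind != "UNKNOWN_COLUMN" else "warn")
    issues: list[ValidationIssue] = []

    def issue(kind: str, field: str, observed: str, expected: str):
        issues.append(
            ValidationIssue(
                kind=kind,
                table=schema.name,
                row=row_ordinal,
                field=field,
                observed=observed,
                expected=expected,
                severity=sev(kind),
            )
        )

    for spec in schema.fields:
        if spec.name not in row:
            continue  # header reconciliation owns missing columns
        value = row.get(spec.name, "")
        if value == "":
            if spec.required:
                issue("REQUIRED", spec.name, "", "non-empty value")
            continue
        if not _type_ok(value, spec):
            issue(
                "TYPE",
                spec.name,
                value,
                f"value of type {spec.semantic_type}",
            )
            continue  # one root cause per cell
        if spec.max_length is not None and len(value) > spec.max_length:
            issue(
                "LENGTH",
                spec.name,
                value,
                f"at most {spec.max_length} characters",
            )
        if spec.semantic_type in ("date", "datetime"):
            d = _parse_date(value)
            if d is None:
                issue("DATE", spec.name, value, "a real calendar date")
            elif spec.date_bounds is not None:
                lo, hi = spec.date_bounds
                if not (lo <= d <= hi):
                    issue(
                        "DATE",
                        spec.name,
                        value,
                        f"date within [{lo.isoformat()}, {hi.isoformat()}]",
                    )
        if spec.semantic_type == "code" and value not in spec.allowed_codes:
            issue(
                "ENUM",
                spec.name,
                value,
                "one of {" + ",".join(spec.allowed_codes) + "}",
            )
    return issues


def check_keys(
    rows: list[Mapping[str, str]],
    schema: TableSchema,
    context: Mapping[str, set] | None = None,
    policy=None,
    append_only: bool = False,
) -> list[ValidationIssue]:
    """Key-integrity pass over a whole table.

    ``context`` maps table name -> set of primary-key tuples (or scalar
    strings for single-column keys) of previously accepted data. The first
    occurrence of a duplicated key is never flagged; each later one is.
    Foreign keys are checked against the referenced table's key set when
    that set is present in context; empty FK cells are a REQUIRED concern,
    not an orphan.
    """
    if not schema.primary_key:
        raise UsageError(f"table {schema.name!r} declares no primary key")
    context = context or {}
    sev = policy or (lambda kind: "reject")
    issues: list[ValidationIssue] = []
    pk_fields = schema.primary_key
    pk_label = pk_fields[0]

    prior = {_norm_keyset_entry(k, pk_fields) for k in context.get(schema.name, set())} if append_only else set()
    seen: set = set(prior)
    for ordinal, row in enumerate(rows, start=1):
        key = tuple(row.get(f, "") for f in pk_fields)
        if any(v == "" for v in key):
            continue  # incomplete key: REQUIRED covers it
        if key in seen:
            issues.append(
                ValidationIssue(
                    kind="DUP_KEY",
                    table=schema.name,
                    row=ordinal,
                    field=pk_label,
                    observed=",".join(key),
                    expected="unique primary key",
                    severity=sev("DUP_KEY"),
                )
            )
        else:
            seen.add(key)
        for fk in schema.foreign_keys:
            value = row.get(fk.name, "")
            if value == "":
                continue
            tgt_table, _ = fk.foreign_target
            refset = context.get(tgt_table)
            if refset is None:
                continue
            if value not in refset:
                issues.append(
                    ValidationIssue(
                        kind="FK_ORPHAN",
                        table=schema.name,
                        row=ordinal,
                        field=fk.name,
                        observed=value,
                        expected=f"existing {tgt_table}.{fk.foreign_target[1]}",
                        severity=sev("FK_ORPHAN"),
                    )
                )
    return issues


def _norm_keyset_entry(entry, pk_fields):
    if isinstance(entry, tuple):
        return entry
    if isinstance(entry, str):
        return (entry,)
    return tuple(entry)


def read_delimited(path: str | Path) -> tuple[list[str], list[dict[str, str]]]:
    """Read an RFC-4180 CSV with a mandatory header row into raw strings.

    Returns (header, rows); rows are dicts keyed by header with missing
    trailing cells as empty strings. Raises :class:`TransportError` for
    unreadable or empty files — transport problems are distinct from
    validation rejections.
    """
    p = Path(path)
    try:
        text = p.read_text(encoding="utf-8")
    except OSError as exc:
        raise TransportError(f"cannot read {p}: {exc}") from exc
    if text.strip() == "":
        raise TransportError(f"{p}: empty file (no header row)")
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:  # pragma: no cover - guarded by strip() above
        raise TransportError(f"{p}: empty file (no header row)")
    rows = []
    for raw in reader:
        if not raw:
            continue
        row = {
            h: (raw[i] if i < len(raw) else "") for i, h in enumerate(header)
        }
        rows.append(row)
    return header, rows


def validate_submission(
    files: Mapping[str, str | Path],
    config: ProjectConfig,
    context: Mapping[str, set] | None = None,
    submission_id: str = "submission",
) -> ValidationReport:
    """Validate a whole submission (one file per table) against the study
    dictionary.

    Tables are checked in ascending dependency level; each table's primary
    keys join the key context before its children are checked, so a parent
    and child submitted together cross-validate. ``context`` seeds the key
    sets with previously accepted data (typically from the study store).
    """
    ctx: dict[str, set] = {k: set(v) for k, v in (context or {}).items()}
    issues: list[ValidationIssue] = []
    checked = 0
    sev = config.severity

    order = sorted(
        files.keys(),
        key=lambda t: (
            config.dictionaries[t].level if t in config.dictionaries else 99,
            t,
        ),
    )
    for tname in order:
        if tname not in config.dictionaries:
            raise UsageError(f"submission names undefined table {tname!r}")
        schema = config.dictionaries[tname]
        header, rows = read_delimited(files[tname])
        declared = [f.name for f in schema.fields]
        for f in declared:
            if f not in header:
                issues.append(
                    ValidationIssue(
                        kind="MISSING_COLUMN",
                        table=tname,
                        row=0,
                        field=f,
                        observed="",
                        expected=f"column {f!r} present",
                        severity=sev("MISSING_COLUMN"),
                    )
                )
        for h in header:
            if h not in declared:
                issues.append(
                    ValidationIssue(
                        kind="UNKNOWN_COLUMN",
                        table=tname,
                        row=0,
                        field=h,
                        observed=h,
                        expected="only dictionary columns",
                        severity=sev("UNKNOWN_COLUMN"),
                    )
                )
        for ordinal, row in enumerate(rows, start=1):
            issues.extend(check_row(row, schema, ordinal, policy=sev))
        issues.extend(check_keys(rows, schema, ctx, policy=sev))
        checked += len(rows)
        # this table's keys become context for its children
        pk = schema.primary_key
        own = ctx.setdefault(tname, set())
        for row in rows:
            key = tuple(row.get(f, "") for f in pk)
            if all(v != "" for v in key):
                own.add(key[0] if len(pk) == 1 else key)
    return finalize_report(submission_id, issues, checked)


# --------------------------------------------------------------------------
# report rendering

_REPORT_COLUMNS = (
    "submission_id",
    "verdict",
    "kind",
    "table",
    "row",
    "field",
    "observed",
    "expected",
    "severity",
)


def render_report(report: ValidationReport, format: str = "delimited") -> str:
    """Render a finalized report.

    ``delimited``: one CSV line per issue carrying every issue attribute
    plus the submission id and verdict; parseable back losslessly with
    :func:`parse_report`. ``human``: grouped by table then kind with
    counts, for the rejection notification body.
    """
    if format == "delimited":
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(_REPORT_COLUMNS)
        for i in report.issues:
            w.writerow(
                [
                    report.submission_id,
                    report.verdict,
                    i.kind,
                    i.table,
                    i.row,
                    i.field,
                    i.observed,
                    i.expected,
                    i.severity,
                ]
            )
        return buf.getvalue()
    if format == "human":
        lines = [
            f"Submission {report.submission_id}: {report.verdict.upper()}",
            f"Rows checked: {report.checked_rows}; issues: {len(report.issues)}",
        ]
        by_table: dict[str, dict[str, list[ValidationIssue]]] = {}
        for i in report.issues:
            by_table.setdefault(i.table, {}).setdefault(i.kind, []).append(i)
        for table in sorted(by_table):
            lines.append(f"\nTable {table}:")
            for kind in sorted(by_table[table]):
                items = by_table[table][kind]
                lines.append(f"  {kind} ({len(items)}):")
                for i in items:
                    where = f"row {i.row}" if i.row else "table level"
                    lines.append(
                        f"    {where}, field {i.field or '-'}: "
                        f"got {i.observed!r}, expected {i.expected}"
                    )
        return "\n".join(lines) + "\n"
    raise UsageError(f"unknown report format {format!r}")


def parse_report(text: str) -> ValidationReport:
    """Parse the delimited rendering back into a report (lossless for
    non-empty reports; counts and ordering are recomputed)."""
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    if header != list(_REPORT_COLUMNS):
        raise UsageError("not a rendered validation report")
    issues = []
    submission_id, verdict = "", "accepted"
    for raw in reader:
        if not raw:
            continue
        submission_id, verdict = raw[0], raw[1]
        issues.append(
            ValidationIssue(
                kind=raw[2],
                table=raw[3],
                row=int(raw[4]),
                field=raw[5],
                observed=raw[6],
                expected=raw[7],
                severity=raw[8],
            )
        )
    report = finalize_report(submission_id or "submission", issues, 0)
    return report
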