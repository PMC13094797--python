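"""Configuration-driven outbound reporting.

A report spec names which fields to pull from which store tables, an
ordered list of transforms (rename, lookup recode, constant, cross-field
map, privacy minimization), a target schema the outbound file must
satisfy, and report-specific cross-field QC hooks. Built rows are
validated against the target schema with the same engine used for inbound
submissions — an emitted report is itself a valid submission, mirroring
the second QC stage performed downstream at the coordinating center. A
report with any reject-severity finding is withheld, never emitted.
"""

from __future__ import annotations

import csv
import hashlib
import io
from pathlib import Path
from typing import Optional

from pydantic import BaseModel

from .config import UNMAPPED, ProjectConfig, ReportSpec, resolve_lookup
from .errors import TransportError, UsageError
from .privacy import apply_privacy
from .qc import (
    ValidationIssue,
    ValidationReport,
    check_keys,
    check_row,
    finalize_report,
)
from .store import StudyStore


class FileReceipt(BaseModel):
    path: str
    digest: str
    rows: int

    model_config = {"frozen": True}


def _extract(spec: ReportSpec, store: StudyStore) -> list[dict[str, str]]:
    """Pull the selected columns. Multi-table selections join on the shared
    foreign-key column when present; the demo reports are single-table."""
    if len(spec.source) != 1:
        raise UsageError(
            f"report {spec.name!r}: exactly one source selection is "
            "supported per report"
        )
    sel = spec.source[0]
    collist = ", ".join(f'"{c}"' for c in sel.fields)
    rows = store.conn.execute(
        f'SELECT {collist} FROM "{sel.table}"'
    ).fetchall()
    return [
        {c: ("" if v is None else str(v)) for c, v in zip(sel.fields, r)}
        for r in rows
    ]


def _apply_transforms(
    rows: list[dict[str, str]], spec: ReportSpec, config: ProjectConfig
) -> list[dict[str, str]]:
    for t in spec.transforms:
        op = t["op"]
        if op == "rename":
            src, tgt = t["field"], t["target"]
            for row in rows:
                row[tgt] = row.pop(src, "")
        elif op == "lookup":
            lk = config.lookup(t["lookup"])
            src, tgt = t["field"], t["target"]
            version = t.get("version")
            for row in rows:
                v = row.get(src, "")
                row[tgt] = (
                    "" if v == "" else resolve_lookup(lk, v, version)
                )
        elif op == "constant":
            for row in rows:
                row[t["target"]] = str(t["value"])
        elif op == "cross_field":
            # target = rules matched on another field's value, else default
            tgt = t["target"]
            src = t["field"]
            mapping = t.get("map", {})
            default = t.get("default", "")
            for row in rows:
                row[tgt] = str(mapping.get(row.get(src, ""), default))
        elif op == "privacy":
            src = t["field"]
            for row in rows:
                row[src] = apply_privacy(row.get(src, ""), t["transform"])
        else:  # pragma: no cover - rejected at config parse
            raise UsageError(f"unknown transform op {op!r}")
    return rows


def build_report(
    spec: ReportSpec,
    store: StudyStore,
    config: ProjectConfig,
) -> tuple[list[dict[str, str]], ValidationReport]:
    """Extract, transform and validate a report.

    Hook fields are verified against the working schema before any row is
    processed, so a bad spec fails at build start, not mid-run. Rows are
    returned only alongside an accepted validation verdict; callers must
    not write a rejected report.
    """
    target = spec.target_schema
    target_fields = [f.name for f in target.fields]
    for h in spec.qc_hooks:
        for fld in (h.require, h.when):
            if fld not in target_fields:
                raise UsageError(
                    f"report {spec.name!r}: hook references field {fld!r} "
                    "absent from the target schema"
                )

    rows = _apply_transforms(_extract(spec, store), spec, config)
    out_rows = [
        {f: row.get(f, "") for f in target_fields} for row in rows
    ]

    issues: list[ValidationIssue] = []
    for ordinal, row in enumerate(out_rows, start=1):
        issues.extend(check_row(row, target, ordinal, policy=config.severity))
        for h in spec.qc_hooks:
            if row.get(h.when, "") == h.equals and row.get(h.require, "") == "":
                issues.append(
                    ValidationIssue(
                        kind="REQUIRED",
                        table=target.name,
                        row=ordinal,
                        field=h.require,
                        observed="",
                        expected=(
                            f"{h.require} required when {h.when} = "
                            f"{h.equals}"
                        ),
                        severity="reject",
                    )
                )
        for f in target_fields:
            if row.get(f, "") == UNMAPPED:
                issues.append(
                    ValidationIssue(
                        kind="ENUM",
                        table=target.name,
                        row=ordinal,
                        field=f,
                        observed=UNMAPPED,
                        expected="a mapped study group",
                        severity="reject",
                    )
                )
    issues.extend(check_keys(out_rows, target, policy=config.severity))
    report = finalize_report(f"report:{spec.name}", issues, len(out_rows))
    return out_rows, report


def render_rows(rows: list[dict[str, str]], spec: ReportSpec) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    cols = [f.name for f in spec.target_schema.fields]
    w.writerow(cols)
    for row in rows:
        w.writerow([row.get(c, "") for c in cols])
    return buf.getvalue()


def write_report(
    rows: list[dict[str, str]],
    spec: ReportSpec,
    destination: str | Path,
    verdict: Optional[ValidationReport] = None,
) -> FileReceipt:
    """Write validated report rows as CSV in target-schema column order.

    ``destination`` is a directory (a bucket download directory models the
    onward transfer to the coordinating center) or an explicit file path.
    Write-then-rename: a partial file is never visible.
    """
    if verdict is not None and not verdict.accepted:
        raise UsageError(
            f"report {spec.name!r} failed its own validation; not writing"
        )
    dest = Path(destination)
    if dest.is_dir():
        dest = dest / f"{spec.name}.csv"
    payload = render_rows(rows, spec).encode("utf-8")
    try:
        tmp = dest.with_suffix(dest.suffix + ".part")
        tmp.parent.mkdir(parents=True, exist_ok=True)
        tmp.write_bytes(payload)
        tmp.replace(dest)
    except OSError as exc:
        raise TransportError(f"cannot write report to {dest}: {exc}") from exc
    return FileReceipt(
        path=str(dest),
        digest=hashlib.sha256(payload).hexdigest(),
        rows=len(rows),
    )
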