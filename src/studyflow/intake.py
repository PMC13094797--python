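"""Per-organization bucket lifecycle: detect, validate, route, notify.

Each submitting organization exchanges files through a bucket with three
directories: ``upload`` (submitter drops files), ``download`` (submitter
retrieves validation reports and returned rejected files), ``archive``
(accepted submissions, kept as a replayable audit trail). A polling scan
detects new files by content digest, so re-drops of already-processed
content are ignored and the cycle is idempotent.

Disposition is atomic per file: an accepted file is archived (renamed with
a receipt timestamp and digest) and imported in one transaction; a
rejected file is returned to ``download`` together with the itemized QC
report. Either way the upload directory no longer holds it. If the import
itself fails after QC acceptance, the event stays ``pending``, the file
stays recoverable in ``upload`` and an alert notification goes out —
never a silent loss, never a double import (imports are idempotent on the
digest).

Transport is a local-filesystem abstraction; a remote transport (e.g.
sFTP) can implement the same get/put/list/delete surface.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol, Sequence

from pydantic import BaseModel

from .config import BucketConfig, ProjectConfig
from .errors import TransportError
from .qc import (
    ValidationIssue,
    ValidationReport,
    finalize_report,
    render_report,
    validate_submission,
)
from .store import StudyStore

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# transport


class Transport(Protocol):
    """Minimal file-exchange surface; local directories here, but the same
    contract fits any remote store."""

    def list(self, directory: Path) -> list[Path]: ...
    def get(self, path: Path) -> bytes: ...
    def put(self, path: Path, data: bytes) -> None: ...
    def delete(self, path: Path) -> None: ...
    def move(self, src: Path, dst: Path) -> None: ...


class LocalTransport:
    def list(self, directory: Path) -> list[Path]:
        try:
            return [p for p in Path(directory).iterdir() if p.is_file()]
        except OSError as exc:
            raise TransportError(f"cannot list {directory}: {exc}") from exc

    def get(self, path: Path) -> bytes:
        try:
            return Path(path).read_bytes()
        except OSError as exc:
            raise TransportError(f"cannot read {path}: {exc}") from exc

    def put(self, path: Path, data: bytes) -> None:
        try:
            tmp = Path(path).with_suffix(Path(path).suffix + ".part")
            tmp.write_bytes(data)
            tmp.replace(path)  # write-then-rename: never partial files
        except OSError as exc:
            raise TransportError(f"cannot write {path}: {exc}") from exc

    def delete(self, path: Path) -> None:
        try:
            Path(path).unlink()
        except OSError as exc:
            raise TransportError(f"cannot delete {path}: {exc}") from exc

    def move(self, src: Path, dst: Path) -> None:
        try:
            shutil.move(str(src), str(dst))
        except OSError as exc:
            raise TransportError(f"cannot move {src} -> {dst}: {exc}") from exc


# --------------------------------------------------------------------------
# buckets and events


@dataclass(frozen=True)
class Bucket:
    org_id: str
    upload_dir: Path
    download_dir: Path
    archive_dir: Path
    expected_tables: tuple[str, ...]

    @classmethod
    def from_config(
        cls, bc: BucketConfig, base: str | Path = "."
    ) -> "Bucket":
        root = Path(base) / bc.root
        return cls(
            org_id=bc.org_id,
            upload_dir=root / "upload",
            download_dir=root / "download",
            archive_dir=root / "archive",
            expected_tables=tuple(bc.expected_tables),
        )

    def init_dirs(self) -> None:
        for d in (self.upload_dir, self.download_dir, self.archive_dir):
            d.mkdir(parents=True, exist_ok=True)


class IntakeEvent(BaseModel):
    bucket: str
    file: str
    detected_at: str
    disposition: str  # accepted | rejected | pending
    report: Optional[ValidationReport] = None
    digest: str = ""

    model_config = {"frozen": True}


# --------------------------------------------------------------------------
# notification sinks


class Message(BaseModel):
    event_kind: str  # acceptance | rejection | alert
    org: str
    file: str
    body: str
    attachment: Optional[str] = None

    model_config = {"frozen": True}


class DeliveryRecord(BaseModel):
    sink: str
    message: Message
    delivered: bool
    attempts: int

    model_config = {"frozen": True}


class LogSink:
    """Records messages in memory and on the module logger."""

    name = "log"

    def __init__(self):
        self.messages: list[Message] = []

    def deliver(self, message: Message) -> None:
        self.messages.append(message)
        logger.info(
            "notify %s org=%s file=%s", message.event_kind, message.org,
            message.file,
        )


class FileSink:
    """Appends one JSON line per message to a notification log file."""

    name = "file"

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def deliver(self, message: Message) -> None:
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(message.model_dump(), sort_keys=True) + "\n")


def notify(sinks: Sequence, message: Message) -> list[DeliveryRecord]:
    """Deliver to every sink; one retry per sink, then record undelivered.

    Notification failure never blocks or changes a disposition.
    """
    records = []
    for sink in sinks:
        delivered = False
        attempts = 0
        for _ in range(2):
            attempts += 1
            try:
                sink.deliver(message)
                delivered = True
                break
            except Exception:
                logger.warning(
                    "sink %s failed (attempt %d)",
                    getattr(sink, "name", sink), attempts,
                )
        records.append(
            DeliveryRecord(
                sink=str(getattr(sink, "name", sink)),
                message=message,
                delivered=delivered,
                attempts=attempts,
            )
        )
    return records


# --------------------------------------------------------------------------
# scanning and processing


def file_digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def scan(
    bucket: Bucket,
    store: StudyStore,
    transport: Transport | None = None,
) -> list[Path]:
    """New files in the bucket's upload directory, ordered by (mtime, name).

    "New" is tracked by content digest against the intake log, so an
    identical re-drop of processed content is not returned.
    """
    transport = transport or LocalTransport()
    processed = store.processed_digests()
    out = []
    for p in sorted(
        transport.list(bucket.upload_dir),
        key=lambda p: (p.stat().st_mtime, p.name),
    ):
        if file_digest(p) not in processed:
            out.append(p)
    return out


def table_for_file(bucket: Bucket, path: Path, config: ProjectConfig) -> str | None:
    """Infer the dictionary table a submission file carries.

    Convention: the file name starts with the table name
    (``donation.csv``, ``donation__2024-05.csv``).
    """
    stem = path.stem
    candidates = [t for t in bucket.expected_tables if t in config.dictionaries]
    # longest match first so "test_result" beats a hypothetical "test"
    for t in sorted(candidates, key=len, reverse=True):
        if stem == t or stem.startswith(t + "__") or stem.startswith(t + "_20"):
            return t
    return None


def process_submission(
    bucket: Bucket,
    file: Path,
    config: ProjectConfig,
    store: StudyStore,
    sinks: Sequence = (),
    transport: Transport | None = None,
) -> IntakeEvent:
    """Run one file through QC and route it.

    Accept: archive (timestamped, digest-suffixed name) + import + acceptance
    notification. Reject: itemized report and the original file to
    ``download`` + rejection notification. Import failure after acceptance:
    ``pending`` + alert, file left recoverable in upload.
    """
    transport = transport or LocalTransport()
    detected = _dt.datetime.now().isoformat(timespec="seconds")
    digest = file_digest(file)
    sid = digest[:16]

    tname = table_for_file(bucket, file, config)
    try:
        if tname is None:
            raise TransportError(
                f"file name {file.name!r} matches no expected table "
                f"{list(bucket.expected_tables)}"
            )
        report = validate_submission(
            {tname: file},
            config,
            context=store.key_context(),
            submission_id=sid,
        )
    except TransportError as exc:
        # unreadable/empty/unroutable file: a single table-level finding
        issue = ValidationIssue(
            kind="MISSING_COLUMN",
            table=tname or "",
            row=0,
            field="",
            observed=file.name,
            expected=f"readable CSV with a header row ({exc})",
            severity="reject",
        )
        report = finalize_report(sid, [issue], 0)

    if report.accepted:
        try:
            result = store.import_submission({tname: file}, report, config)
            if result.outcome != "committed":
                raise TransportError(result.error or "import rolled back")
        except Exception as exc:
            notify(
                sinks,
                Message(
                    event_kind="alert",
                    org=bucket.org_id,
                    file=file.name,
                    body=(
                        f"submission passed QC but import failed: {exc}; "
                        "file left in upload for recovery"
                    ),
                ),
            )
            return IntakeEvent(
                bucket=bucket.org_id,
                file=file.name,
                detected_at=detected,
                disposition="pending",
                report=report,
                digest=digest,
            )
        stamp = _dt.datetime.now().strftime("%Y%m%dT%H%M%S")
        archived = (
            bucket.archive_dir / f"{file.stem}.{stamp}.{digest[:12]}{file.suffix}"
        )
        transport.move(file, archived)
        store.record_intake(bucket.org_id, file.name, digest, "accepted")
        notify(
            sinks,
            Message(
                event_kind="acceptance",
                org=bucket.org_id,
                file=file.name,
                body=f"submission {sid} accepted; "
                f"{report.checked_rows} rows imported",
            ),
        )
        return IntakeEvent(
            bucket=bucket.org_id,
            file=file.name,
            detected_at=detected,
            disposition="accepted",
            report=report,
            digest=digest,
        )

    rendered = render_report(report, "delimited")
    report_path = bucket.download_dir / f"{file.stem}.qc_report.csv"
    transport.put(report_path, rendered.encode("utf-8"))
    transport.move(file, bucket.download_dir / file.name)
    store.record_intake(bucket.org_id, file.name, digest, "rejected")
    notify(
        sinks,
        Message(
            event_kind="rejection",
            org=bucket.org_id,
            file=file.name,
            body=f"submission {sid} rejected with "
            f"{len(report.issues)} issue(s)",
            attachment=rendered,
        ),
    )
    return IntakeEvent(
        bucket=bucket.org_id,
        file=file.name,
        detected_at=detected,
        disposition="rejected",
        report=report,
        digest=digest,
    )


def init_buckets(config: ProjectConfig, base: str | Path = ".") -> list[Bucket]:
    buckets = [Bucket.from_config(bc, base) for bc in config.buckets]
    for b in buckets:
        b.init_dirs()
    return buckets


def run_cycle(
    config: ProjectConfig,
    store: StudyStore,
    sinks: Sequence = (),
    base: str | Path = ".",
    transport: Transport | None = None,
) -> list[IntakeEvent]:
    """One pass over all buckets.

    Within a bucket, new files are processed in ascending table dependency
    level (then mtime, then name) so a parent table dropped together with
    its children is imported first and the children validate against it.
    Per-file failures are contained; idempotent per digest, so invoking
    twice back-to-back yields an empty second pass.
    """
    events: list[IntakeEvent] = []
    for b in init_buckets(config, base):
        try:
            new_files = scan(b, store, transport)
        except TransportError as exc:
            logger.error("bucket %s unscannable: %s", b.org_id, exc)
            continue
        def level_of(p: Path) -> int:
            t = table_for_file(b, p, config)
            return config.dictionaries[t].level if t else 99
        ordered = sorted(
            new_files, key=lambda p: (level_of(p), p.stat().st_mtime, p.name)
        )
        for f in ordered:
            try:
                events.append(
                    process_submission(b, f, config, store, sinks, transport)
                )
            except Exception:
                logger.exception(
                    "bucket %s: failed to process %s", b.org_id, f.name
                )
    return events


def watch(
    config: ProjectConfig,
    store: StudyStore,
    sinks: Sequence = (),
    base: str | Path = ".",
    interval: float = 5.0,
    max_cycles: int | None = None,
) -> list[IntakeEvent]:
    """Polling listener: run intake cycles every ``interval`` seconds.

    ``max_cycles`` bounds the loop (None = run until interrupted).
    """
    all_events: list[IntakeEvent] = []
    cycles = 0
    while max_cycles is None or cycles < max_cycles:
        all_events.extend(run_cycle(config, store, sinks, base))
        cycles += 1
        if max_cycles is not None and cycles >= max_cycles:
            break
        time.sleep(interval)
    return all_events
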