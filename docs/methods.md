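# Methods

This note documents the model behind each subsystem, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical/design choices made where the design was genuinely open.

## The configuration model

A study is fully described by one YAML file: `dictionaries` (tables →
ordered fields with type, length, enumerated codes, key roles, PII class,
date bounds, privacy transform), `lookups` (versioned value→group maps),
`qc_policy` (per-check severity), `buckets` (per-organization exchange
areas), `reports` (source selections, ordered transforms, a target
schema, cross-field hooks) and opaque `settings`. Parsing resolves and
validates every cross-reference and reports **all** dangling references
at once, so a config author fixes a file in one pass. Unknown top-level
keys warn rather than fail: older configurations must keep running on
newer code (loose coupling). A per-user file shallow-merges over the
project file — a top-level key in the user file replaces the project one
wholesale; deep merging was rejected because its conflict semantics are
ambiguous and the use case (local paths, credentials) is top-level.

Field semantic types are `text`, `integer`, `decimal`, `date`,
`datetime`, `code`. `code` and a non-empty allowed-code set imply each
other. Dictionary diffs are itemized per field and per attribute
(added/removed/modified); replaying a change-list onto the old schema
reproduces the new one, which is the tested contract for dictionary
version management.

## QC engine

Checks run in a fixed discipline chosen to keep reports actionable:

* An empty cell on a required field is `REQUIRED` and nothing else.
* `TYPE` is checked before `LENGTH`/`DATE`/`ENUM`, and a `TYPE` failure
  suppresses that cell's downstream checks — one root cause per cell.
* Dates are ISO-8601 only (`YYYY-MM-DD`). A value of the right shape that
  is not a real calendar date (checked against the standard library's
  calendar) or violates the field's declared bounds is `DATE`; anything
  else is `TYPE`. Submitters' local date formats are an intake transform
  concern, not a QC leniency — determinism requires one dialect.
* Key checks: the first occurrence of a duplicated primary key is never
  flagged, each later one is; foreign keys are checked against the
  referenced table's key set, drawn from the study store and from
  parent tables present in the same submission (tables are processed in
  ascending dependency level). Empty foreign-key cells are a `REQUIRED`
  concern, not an orphan.
* Header reconciliation emits table-level (`row = 0`) findings:
  `MISSING_COLUMN` per absent declared field (suppressing per-row noise
  for that column) and `UNKNOWN_COLUMN` per extra.

Severities come from `qc_policy`; the default rejects everything except
`UNKNOWN_COLUMN` (warn), so a submitter's convenience columns do not
bounce a delivery. Issues are ordered `(table, row, field)`, which makes
rendered reports byte-reproducible. The delimited rendering carries every
issue attribute plus submission id and verdict and parses back
losslessly; an empty accepted report is a bare header line.

The verdict is whole-file: a submission is imported entirely or returned
entirely. Partial acceptance would leave submitters guessing which rows
survived.

## Study store

SQLite is the embedded backend, behind a thin class so another relational
engine could present the same surface. The dictionary is materialized
with STRICT column types (integer/decimal type violations are refused by
the engine), `NOT NULL` for required fields, `CHECK` constraints for
lengths, enumerated codes and date shape, and declared primary/foreign
keys with enforcement on. Calendar validity of dates is *not* expressible
as a portable SQL check and is enforced only by the rule engine; the
database's redundant-QC guarantee covers type, length, enumeration,
required-ness and key integrity.

Imports are all-or-nothing inside one transaction: a mid-import
constraint violation (possible when a severity was deliberately
downgraded to warn) rolls the whole submission back and names the
violating row. Imports are idempotent on the submission id (a content
digest), so replaying the archive is safe for audit. Parent-level rows
that re-arrive with an existing key (periodic refreshes) are upserted,
with every overwritten value recorded in an audit relation — append-only
versioning was the alternative and was rejected to keep the data tables
canonical-one-row-per-entity.

Lookup recoding writes the study grouping into a derived column named
after the lookup; source columns are never modified (byte-identical
before/after, tested). Unmapped source values receive a distinguished
sentinel and are counted, never errored: unknown codes are data.
Identifier changes live in a change-trail relation; resolution follows
the chain to its terminus with cycle detection, and foreign keys are
canonicalized at import while the trail preserves the original.

Privacy minimization for fields so declared happens **at import**, not at
reporting: the store never holds more identifying precision than the
study needs (month-level birth dates serialized `YYYY-MM`; 3-digit ZIP
prefixes). Column checks for such fields are relaxed to the minimized
domain. Truncations are idempotent; a date a truncate rule cannot parse
is an error (fail closed), and a postal code that is not 3/5/9 digits is
dropped to empty rather than passed through.

## Intake workflow

Transport is a local-filesystem abstraction (list/get/put/move/delete);
a remote transport can implement the same interface. Listening is by
polling, not OS file events, for portability. New files are recognized by
content digest, which gives idempotent cycles and makes a re-drop of
already-accepted content a no-op; scan order is `(mtime, name)`. Within a
cycle, files are processed in ascending table dependency level so a
parent table dropped together with its children imports first — without
this, clean child submissions would be spuriously rejected as orphans.

Accepted files are archived under a name suffixed with a receipt
timestamp and digest (the archive is the audit trail; original names
alone would collide across deliveries). Rejected files are returned to
`download/` together with the rendered report, so submitters retrieve
both. If import fails *after* QC acceptance, the event is `pending`, the
file stays in `upload/` for recovery, and an alert is emitted — never a
silent loss, and the digest-keyed import prevents double-writing on
retry. Notification sinks get one retry and an undelivered record;
notification can never change a disposition.

## Survey model

Three long-format relations absorb all round-to-round change: questions
(one row per question per round, equivalent questions sharing a question
id), responses (one row per respondent per round with completion and
consent flags), answers (one row per answered question). Registering new
rounds or questions never alters any relation's columns.

Equivalency is **curated**: the analyst supplies an explicit
text→question-id map at registration; exact-text matches are offered as
suggestions only. Automated semantic matching of reworded questions was
deliberately not attempted — a wrong silent merge is worse than a manual
mapping step. The `completed` flag is taken from the platform export and
never derived from answer counts.

Consent is enforced twice: ingest writes no answer rows for
non-consenting respondents (while still recording the response, flagged
nonconsenting), and a database trigger refuses direct answer inserts for
nonconsenting responses. Raw exports may legitimately contain answers
from respondents who withdrew consent late; those answers are counted as
suppressed and discarded. The analytic pivot includes only consented
responses and is lossless: melting it reproduces the answer relation.

## Reporting

Transforms are a small closed vocabulary (rename, lookup recode,
constant, cross-field map, privacy) applied in declared order; the
spec digest is order-sensitive, so a reordering is a visible spec change.
Arbitrary code hooks are an extension point, not configuration. Built
rows are validated against the target schema with the same engine used
for inbound submissions, plus cross-field hooks of the form "*X* required
when *Y* = *v*"; an emitted report is therefore itself a valid submission
under the reporting dictionary, mirroring the second QC stage a
coordinating center runs on receipt. Hook fields are verified against the
target schema before any row is processed. Files are written
write-then-rename with a digest-bearing receipt; a withheld (rejected)
report is never written.

## Simulator

The generator emulates the structure the framework manages: a donor
roster with time-invariant characteristics, donations hanging off donors
(count per donor drawn from a gamma-Poisson mixture, defaults mean 2.0
and dispersion 1.0), one-to-a-few assay results per donation, ~10%
missingness on optional self-reported fields, and survey rounds with
configurable question churn, consent rate and respondent count. Default
study conditions: 2 organizations, 500 donors split between them, 3
survey rounds, 30% churn, 90% consent, 2% per-cell corruption spread
evenly over the seven injectable kinds. Identifiers and free-text values
come from a fictional namespace; nothing resembling real personal data is
produced.

Corruption is per-cell Bernoulli with the kind drawn from the configured
mix restricted to what the field can express (e.g. `ENUM` only on coded
fields). Constraints keep the ledger exact: at most one corruption per
cell; type/length/date/enum/required corruptions land only on non-key
fields; duplicate-key corruptions only on rows whose original key no
child row references (otherwise the lost key would orphan children as a
side effect); orphaned-FK values use a reserved prefix that can never
collide with a real key. Every cell-level corruption is self-checked at
generation time to trigger exactly its own QC issue. Generation and
corruption use separate string-seeded PRNG streams, and all output is
written with fixed field order and line terminators, so identical
seed+config+dictionary give byte-identical files and ledgers.

What the simulator does **not** emulate: realistic seroprevalence or
assay dynamics (values are dictionary-valid, not biologically
calibrated), realistic name/address data, submitter formatting quirks
(non-ISO dates, encodings), or adversarial CSV malformation beyond the
empty-file case. Passing tests therefore demonstrate the correctness of
the *mechanism* — detection, routing, storage, gating — on structurally
faithful data, not robustness to every real-world file pathology.

## Problem sizes and determinism in the test suite

The test and acceptance runs use desk-scale studies (tens to a few
hundred donors; the ledger-equivalence check uses 20 seeds at 500 donors
each, roughly 280 injected errors per seed), which exercise every code
path while keeping the whole suite in seconds. Property-based tests run
with fixed Hypothesis profiles and explicit seeds; all simulation draws
go through seeded PRNGs so failures reproduce exactly.

## Known limitations

* Single-process, embedded-database deployment; no server, replication,
  or row-level security. Extract allow-lists in report specs are the only
  governance primitive.
* Report extraction currently supports one source table per report;
  multi-table joins would extend the selection model.
* The QC engine accepts RFC-4180 CSV in UTF-8 only; transport-level
  transformation of other dialects is out of scope.
* Cross-field QC hooks cover the "required-when" family; richer
  predicates are an extension point.
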