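"""Seedable simulator of a complete multicenter study.

Generates the full data environment the framework manages — per-organization
donor, donation and testing submissions plus multi-round survey exports —
entirely from the study dictionary, so every workflow is exercisable
offline with no real data. Two halves:

* :func:`generate_study` — a clean study: donors with time-invariant
  characteristics (birth date, blood group), donations referencing donors
  with visit dates and self-reported codes, testing rows referencing
  donations with assay codes and in-range numeric results, and survey
  rounds with question churn and consent flags. Clean output passes QC
  with zero issues by construction.
* :func:`corrupt` — controlled error injection: each cell is independently
  corrupted with a configured probability using a kind drawn from a
  configured mix (type-breaking token, over-length string, impossible or
  out-of-bounds date, out-of-enumeration code, blanked required cell,
  duplicated primary-key row, orphaned foreign key), and every corruption
  is recorded exactly once in a ground-truth :class:`ErrorLedger`. Each
  corrupted value is self-checked at generation time to trigger exactly
  its own QC issue, so ledger↔report equivalence is exact.

Identifiers and values come from a fictional namespace; nothing resembling
real personal data is generated, even synthetically.

Determinism: identical (seed, config, dictionary) produce byte-identical
files and ledgers across runs and platforms.
"""

from __future__ import annotations

import copy
import csv
import random
from collections import Counter
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, model_validator

from .config import FieldSpec, ProjectConfig, TableSchema
from .errors import ConfigError, UsageError
from .qc import check_row

#: Row/cell-level corruption kinds the injector can produce.
INJECTABLE_KINDS = (
    "TYPE",
    "LENGTH",
    "DATE",
    "ENUM",
    "REQUIRED",
    "DUP_KEY",
    "FK_ORPHAN",
)


class SimConfig(BaseModel):
    """Study-condition knobs for the simulator.

    Defaults describe a small two-organization donor cohort: 500 donors
    split across organizations, about two donations per donor, three
    survey rounds with 30% question churn, 90% research consent, and a 2%
    per-cell corruption rate spread over all injectable kinds.
    """

    seed: int = 0
    n_orgs: int = 2
    n_donors: int = 500
    donations_mean: float = 2.0
    donations_dispersion: float = 1.0
    n_rounds: int = 3
    n_questions: int = 10
    question_churn: float = 0.3
    consent_rate: float = 0.9
    n_respondents: Optional[int] = None
    error_rate: float = 0.02
    error_mix: dict[str, float] = {}

    model_config = {"validate_assignment": True}

    @model_validator(mode="before")
    @classmethod
    def _default_mix(cls, data):
        if isinstance(data, dict) and not data.get("error_mix"):
            data = {**data, "error_mix": {k: 1.0 for k in INJECTABLE_KINDS}}
        return data

    @model_validator(mode="after")
    def _invariants(self):
        if not (0.0 <= self.question_churn <= 1.0):
            raise ConfigError("question_churn must be within [0, 1]")
        if not (0.0 <= self.consent_rate <= 1.0):
            raise ConfigError("consent_rate must be within [0, 1]")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError("error_rate must be within [0, 1)")
        unknown = set(self.error_mix) - set(INJECTABLE_KINDS)
        if unknown:
            raise ConfigError(
                f"error_mix names unknown kinds: {sorted(unknown)}"
            )
        if self.n_orgs < 1 or self.n_donors < 1:
            raise ConfigError("need at least one organization and one donor")
        return self


@dataclass(frozen=True)
class LedgerEntry:
    kind: str
    org: str
    table: str
    row: int  # 1-based data row in the written file
    field: str
    original: str
    corrupted: str


@dataclass
class ErrorLedger:
    """Ground truth for every injected corruption."""

    entries: list[LedgerEntry] = dc_field(default_factory=list)

    def for_org(self, org: str) -> list[LedgerEntry]:
        return [e for e in self.entries if e.org == org]

    def issue_multiset(self, org: str | None = None) -> Counter:
        """Multiset of (kind, table, row, field) — the exact identity the
        QC engine reports, for ledger↔report comparison."""
        return Counter(
            (e.kind, e.table, e.row, e.field)
            for e in self.entries
            if org is None or e.org == org
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(
                ["kind", "org", "table", "row", "field", "original",
                 "corrupted"]
            )
            for e in self.entries:
                w.writerow(
                    [e.kind, e.org, e.table, e.row, e.field, e.original,
                     e.corrupted]
                )


@dataclass
class SurveyRound:
    label: str
    questions: list[tuple[str, Optional[tuple[str, ...]]]]
    export_rows: list[dict]


@dataclass
class StudyData:
    """A full simulated study: per-org table rows plus survey rounds."""

    orgs: dict[str, dict[str, list[dict[str, str]]]]
    survey_rounds: list[SurveyRound]

    def org_ids(self) -> list[str]:
        return sorted(self.orgs)


# --------------------------------------------------------------------------
# clean generation


def _org_ids(sim: SimConfig, config: ProjectConfig) -> list[str]:
    if config.buckets and len(config.buckets) >= sim.n_orgs:
        return [b.org_id for b in config.buckets[: sim.n_orgs]]
    return [f"O{i + 1}" for i in range(sim.n_orgs)]


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth's method; lam is small (a handful of donations/tests per parent)
    import math

    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


def _count_draw(rng: random.Random, mean: float, dispersion: float) -> int:
    if dispersion and dispersion > 0:
        lam = rng.gammavariate(dispersion, mean / dispersion)
        return _poisson(rng, lam)
    return _poisson(rng, mean)


def _value_for(rng: random.Random, spec: FieldSpec) -> str:
    """A dictionary-valid value for one non-key field."""
    if spec.semantic_type == "code":
        return rng.choice(spec.allowed_codes)
    if spec.semantic_type in ("date", "datetime"):
        if spec.date_bounds:
            lo, hi = spec.date_bounds
        else:
            import datetime as _dt

            lo, hi = _dt.date(2020, 1, 1), _dt.date(2024, 12, 31)
        span = (hi - lo).days
        d = lo + __import__("datetime").timedelta(days=rng.randrange(span + 1))
        if spec.semantic_type == "datetime":
            return d.isoformat() + "T12:00:00"
        return d.isoformat()
    if spec.semantic_type == "integer":
        digits = min(spec.max_length or 4, 4)
        return str(rng.randrange(10 ** (digits - 1), 10**digits))
    if spec.semantic_type == "decimal":
        return f"{rng.uniform(0.1, 250.0):.2f}"
    # text: ZIP-like fields (declared via their privacy transform) get
    # 5-digit codes from a fictional range; other text gets letter tokens
    if spec.privacy and spec.privacy.transform == "truncate-zip-to-3":
        return f"{rng.randrange(90000, 99999)}"
    n = min(spec.max_length or 8, 8)
    return "".join(rng.choice("abcdefghijklmnop") for _ in range(n))


def _maybe_empty(rng: random.Random, spec: FieldSpec, value: str) -> str:
    # optional categorical/text cells carry ~10% missingness, mirroring
    # self-reported fields; numeric results stay filled
    if (
        not spec.required
        and spec.key_role == "none"
        and spec.semantic_type in ("text", "code")
        and rng.random() < 0.10
    ):
        return ""
    return value


def generate_study(sim: SimConfig, config: ProjectConfig) -> StudyData:
    """Generate a clean simulated study from the dictionary.

    Table population is driven by dependency level: level-1 tables get the
    donor roster (``n_donors`` split across organizations), and each row of
    a deeper table hangs off a sampled parent row, with child counts drawn
    from the configured donation distribution.
    """
    rng = random.Random(f"{sim.seed}-generate")
    orgs = _org_ids(sim, config)
    per_org = max(1, sim.n_donors // len(orgs))
    tables = config.tables_by_level()
    data: dict[str, dict[str, list[dict[str, str]]]] = {}
    all_donor_ids: list[str] = []

    for org in orgs:
        org_tables: dict[str, list[dict[str, str]]] = {}
        pk_values: dict[str, list[str]] = {}
        for schema in tables:
            rows: list[dict[str, str]] = []
            parent = _parent_table(schema)
            if parent is None:
                seeds = [f"{org}D{i + 1:05d}" for i in range(per_org)]
                parent_of = [None] * len(seeds)
            else:
                seeds, parent_of = [], []
                mean = (
                    sim.donations_mean
                    if schema.level == 2
                    else 1.5  # assays per donation
                )
                for ppk in pk_values[parent]:
                    n = (
                        _count_draw(rng, mean, sim.donations_dispersion)
                        if schema.level == 2
                        else 1 + (rng.random() < 0.5)
                    )
                    for j in range(n):
                        seeds.append(f"{ppk}{schema.name[0].upper()}{j + 1:02d}")
                        parent_of.append(ppk)
            for pk_val, ppk in zip(seeds, parent_of):
                row: dict[str, str] = {}
                for spec in schema.fields:
                    if spec.key_role == "primary":
                        row[spec.name] = pk_val
                    elif spec.key_role == "foreign":
                        row[spec.name] = ppk or ""
                    else:
                        row[spec.name] = _maybe_empty(
                            rng, spec, _value_for(rng, spec)
                        )
                rows.append(row)
            org_tables[schema.name] = rows
            pk_values[schema.name] = [r[schema.primary_key[0]] for r in rows]
            if parent is None:
                all_donor_ids.extend(pk_values[schema.name])
        data[org] = org_tables

    survey_rounds = _generate_surveys(sim, rng, sorted(all_donor_ids))
    return StudyData(orgs=data, survey_rounds=survey_rounds)


def _parent_table(schema: TableSchema) -> Optional[str]:
    for fk in schema.foreign_keys:
        return fk.foreign_target[0]
    return None


_DOMAINS: list[Optional[tuple[str, ...]]] = [
    ("Y", "N"),
    ("0", "1", "2", "3+"),
    None,  # free text
]


def _generate_surveys(
    sim: SimConfig, rng: random.Random, all_donors: list[str]
) -> list[SurveyRound]:
    n_resp = sim.n_respondents or min(len(all_donors), 100)
    rounds: list[SurveyRound] = []
    q_counter = 0
    prev_questions: list[tuple[str, Optional[tuple[str, ...]]]] = []
    for r in range(1, sim.n_rounds + 1):
        if not prev_questions:
            keep: list = []
        else:
            n_keep = round(len(prev_questions) * (1.0 - sim.question_churn))
            keep = prev_questions[:n_keep]
        questions = list(keep)
        while len(questions) < sim.n_questions:
            q_counter += 1
            domain = _DOMAINS[q_counter % len(_DOMAINS)]
            questions.append(
                (f"Survey item {q_counter:03d} (fictional wording)", domain)
            )
        respondents = rng.sample(all_donors, min(n_resp, len(all_donors)))
        export_rows = []
        for rid in sorted(respondents):
            consented = rng.random() < sim.consent_rate
            completed = rng.random() < 0.9
            answers: dict[str, str] = {}
            p_answer = 0.8 if completed else 0.3
            for text, domain in questions:
                if rng.random() < p_answer:
                    answers[text] = (
                        rng.choice(domain)
                        if domain
                        else f"free-text-{rng.randrange(1000):03d}"
                    )
            export_rows.append(
                {
                    "respondent_id": rid,
                    "consented": "1" if consented else "0",
                    "completed": "1" if completed else "0",
                    "answers": answers,
                }
            )
        rounds.append(
            SurveyRound(
                label=f"R{r}", questions=questions, export_rows=export_rows
            )
        )
        prev_questions = questions
    return rounds


# --------------------------------------------------------------------------
# corruption


def corrupt(
    study: StudyData, sim: SimConfig, config: ProjectConfig
) -> tuple[StudyData, ErrorLedger]:
    """Inject dictionary-violating corruptions into a clean study.

    Each eligible cell is corrupted independently with probability
    ``error_rate`` using a kind drawn from ``error_mix`` restricted to the
    kinds that field can express. At most one corruption lands per cell;
    duplicate-key and orphaned-FK corruptions operate on key cells only and
    are constrained so they cannot cascade into other tables' findings.
    """
    rng = random.Random(f"{sim.seed}-corrupt")
    mix = sim.error_mix
    out = copy.deepcopy(study.orgs)
    ledger = ErrorLedger()

    for org in sorted(out):
        org_tables = out[org]
        referenced = _referenced_pks(org_tables, config)
        for schema in config.tables_by_level():
            rows = org_tables.get(schema.name, [])
            pk_field = schema.primary_key[0]
            parent_pks = _parent_pk_sets(org_tables, schema, config)
            for idx, row in enumerate(rows):
                for spec in schema.fields:
                    if rng.random() >= sim.error_rate:
                        continue
                    kinds = _applicable_kinds(
                        spec, row, idx, schema, referenced, mix
                    )
                    if not kinds:
                        continue
                    weights = [mix[k] for k in kinds]
                    kind = rng.choices(kinds, weights=weights, k=1)[0]
                    original = row[spec.name]
                    corrupted = _corrupt_value(
                        kind, spec, rng, rows, idx, pk_field, parent_pks
                    )
                    row[spec.name] = corrupted
                    _self_check(kind, spec, schema, corrupted)
                    ledger.entries.append(
                        LedgerEntry(
                            kind=kind,
                            org=org,
                            table=schema.name,
                            row=idx + 1,
                            field=spec.name,
                            original=original,
                            corrupted=corrupted,
                        )
                    )
    return StudyData(orgs=out, survey_rounds=study.survey_rounds), ledger


def _referenced_pks(org_tables, config: ProjectConfig) -> dict[str, set[str]]:
    """Per parent table, the set of its keys referenced by any child row
    (in the clean data). DUP_KEY must not land on a referenced parent row,
    or the lost original key would orphan children as a side effect."""
    refs: dict[str, set[str]] = {}
    for schema in config.tables_by_level():
        for fk in schema.foreign_keys:
            tgt = fk.foreign_target[0]
            bucket = refs.setdefault(tgt, set())
            for row in org_tables.get(schema.name, []):
                if row.get(fk.name):
                    bucket.add(row[fk.name])
    return refs


def _parent_pk_sets(org_tables, schema: TableSchema, config) -> dict[str, set[str]]:
    out = {}
    for fk in schema.foreign_keys:
        tgt_table, _ = fk.foreign_target
        tgt_schema = config.dictionaries[tgt_table]
        out[fk.name] = {
            r[tgt_schema.primary_key[0]]
            for r in org_tables.get(tgt_table, [])
        }
    return out


def _applicable_kinds(
    spec: FieldSpec, row, idx: int, schema: TableSchema, referenced, mix
) -> list[str]:
    if spec.key_role == "primary":
        ok = (
            idx > 0
            and row[spec.name] not in referenced.get(schema.name, set())
        )
        return ["DUP_KEY"] if ok and "DUP_KEY" in mix else []
    if spec.key_role == "foreign":
        return ["FK_ORPHAN"] if "FK_ORPHAN" in mix and row[spec.name] else []
    if row[spec.name] == "":
        return []
    kinds = []
    if spec.semantic_type in ("integer", "decimal", "date", "datetime"):
        kinds.append("TYPE")
    if spec.semantic_type == "text" and spec.max_length is not None:
        kinds.append("LENGTH")
    if spec.semantic_type == "date":
        kinds.append("DATE")
    if spec.semantic_type == "code":
        kinds.append("ENUM")
    if spec.required:
        kinds.append("REQUIRED")
    return [k for k in kinds if k in mix]


def _corrupt_value(
    kind: str,
    spec: FieldSpec,
    rng: random.Random,
    rows,
    idx: int,
    pk_field: str,
    parent_pks: dict[str, set[str]],
) -> str:
    if kind == "TYPE":
        return "#invalid#"
    if kind == "LENGTH":
        return "X" * (spec.max_length + 5)
    if kind == "DATE":
        if spec.date_bounds and rng.random() < 0.5:
            lo = spec.date_bounds[0]
            return (lo - __import__("datetime").timedelta(days=1)).isoformat()
        return f"{2021 + rng.randrange(3)}-02-30"
    if kind == "ENUM":
        bad = "Z" * max(1, min(spec.max_length or 3, 3))
        while bad in spec.allowed_codes:  # pragma: no cover - fictional codes
            bad = bad[:-1] + "9"
        return bad
    if kind == "REQUIRED":
        return ""
    if kind == "DUP_KEY":
        donor_row = rows[rng.randrange(idx)]
        return donor_row[pk_field]
    if kind == "FK_ORPHAN":
        original = rows[idx][spec.name]
        bad = "ZZ" + original[2:]
        if bad in parent_pks.get(spec.name, set()):  # pragma: no cover
            raise UsageError(
                f"FK corruption collided with a real key: {bad!r}"
            )
        return bad
    raise UsageError(f"unknown corruption kind {kind!r}")  # pragma: no cover


def _self_check(kind: str, spec: FieldSpec, schema: TableSchema, value: str):
    """Generation-time guarantee: a cell-level corruption triggers exactly
    its own QC issue and nothing else."""
    if kind in ("DUP_KEY", "FK_ORPHAN"):
        return  # row-level kinds are guaranteed structurally
    issues = check_row({spec.name: value}, schema, 1)
    kinds = [i.kind for i in issues]
    if kinds != [kind]:
        raise RuntimeError(
            f"corruption self-check failed: {kind} on "
            f"{schema.name}.{spec.name} -> {kinds}"
        )


# --------------------------------------------------------------------------
# writing


def write_org_files(
    study: StudyData, base: str | Path, config: ProjectConfig
) -> dict[str, dict[str, Path]]:
    """Write each organization's tables as CSV under ``base/<org>/``.

    Deterministic byte output: fixed field order, ``\\n`` terminators.
    """
    out: dict[str, dict[str, Path]] = {}
    for org in study.org_ids():
        org_dir = Path(base) / org
        org_dir.mkdir(parents=True, exist_ok=True)
        out[org] = {}
        for tname, rows in study.orgs[org].items():
            schema = config.dictionaries[tname]
            path = org_dir / f"{tname}.csv"
            _write_table(path, schema, rows)
            out[org][tname] = path
    return out


def _write_table(path: Path, schema: TableSchema, rows) -> None:
    cols = [f.name for f in schema.fields]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(cols)
        for row in rows:
            w.writerow([row.get(c, "") for c in cols])


def table_bytes(schema: TableSchema, rows) -> bytes:
    import io

    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    cols = [f.name for f in schema.fields]
    w.writerow(cols)
    for row in rows:
        w.writerow([row.get(c, "") for c in cols])
    return buf.getvalue().encode("utf-8")


def write_survey_exports(
    study: StudyData, base: str | Path
) -> dict[str, Path]:
    """Write each round's raw export as a wide CSV (one column per question
    text), the layout survey platforms commonly deliver."""
    out = {}
    for rnd in study.survey_rounds:
        path = Path(base) / f"survey_{rnd.label}.csv"
        qtexts = [t for t, _ in rnd.questions]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["respondent_id", "consented", "completed", *qtexts])
            for row in rnd.export_rows:
                w.writerow(
                    [
                        row["respondent_id"],
                        row["consented"],
                        row["completed"],
                        *[row["answers"].get(q, "") for q in qtexts],
                    ]
                )
        out[rnd.label] = path
    return out


def drop_into_buckets(
    study: StudyData, config: ProjectConfig, base: str | Path
) -> dict[str, list[Path]]:
    """Drop each organization's files into its bucket upload directory, the
    way a submitter would."""
    from .intake import init_buckets

    buckets = {b.org_id: b for b in init_buckets(config, base)}
    out: dict[str, list[Path]] = {}
    for org in study.org_ids():
        if org not in buckets:
            raise UsageError(f"no bucket configured for organization {org!r}")
        b = buckets[org]
        out[org] = []
        for tname, rows in study.orgs[org].items():
            schema = config.dictionaries[tname]
            path = b.upload_dir / f"{tname}.csv"
            _write_table(path, schema, rows)
            out[org].append(path)
    return out
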