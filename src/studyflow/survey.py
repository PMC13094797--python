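"""Long-format survey store with cross-round question equivalency.

Survey questions change between rounds; storing answers wide (one column
per question) would mean restructuring tables with every round. Instead
three long-format relations absorb all change:

* ``survey_question`` — every question ever asked, one row per
  (question_id, round); equivalent questions across rounds share a
  question_id, so reworded repeats stay linkable.
* ``survey_response`` — one row per respondent per round, recording
  completion and research consent.
* ``survey_answer`` — one row per answered question, linked to its
  response and question.

Consent is a hard gate: answers are never stored for a respondent whose
response is flagged nonconsenting — even when the raw platform export
contains them (consent can be withdrawn late in the process). The
respondent is still recorded as having responded. A database trigger
backs the gate so even direct inserts cannot bypass it.

Equivalency is curated: the analyst supplies an explicit mapping from
question text (or a stable key) to an existing question_id at round
registration. Exact-text matches are offered as suggestions only; no
semantic matching is attempted.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel

from .errors import UsageError
from .store import StudyStore

_SURVEY_DDL = [
    (
        'CREATE TABLE IF NOT EXISTS "survey_question" (\n'
        "  question_id TEXT NOT NULL, round TEXT NOT NULL,\n"
        "  text TEXT NOT NULL, answer_domain TEXT,\n"
        "  PRIMARY KEY (question_id, round)\n) STRICT"
    ),
    (
        'CREATE TABLE IF NOT EXISTS "survey_response" (\n'
        "  response_id TEXT PRIMARY KEY, respondent_id TEXT NOT NULL,\n"
        "  round TEXT NOT NULL, completed INTEGER NOT NULL,\n"
        "  consented INTEGER NOT NULL,\n"
        "  UNIQUE (respondent_id, round)\n) STRICT"
    ),
    (
        'CREATE TABLE IF NOT EXISTS "survey_answer" (\n'
        "  response_id TEXT NOT NULL, question_id TEXT NOT NULL,\n"
        "  answer TEXT NOT NULL,\n"
        "  PRIMARY KEY (response_id, question_id),\n"
        '  FOREIGN KEY (response_id) REFERENCES "survey_response" '
        "(response_id)\n) STRICT"
    ),
    # the consent gate, enforced by the engine itself
    (
        "CREATE TRIGGER IF NOT EXISTS consent_gate "
        'BEFORE INSERT ON "survey_answer" '
        "WHEN (SELECT consented FROM survey_response "
        "      WHERE response_id = NEW.response_id) = 0 "
        "BEGIN SELECT RAISE(ABORT, 'answers require consent'); END"
    ),
]


class SurveyQuestion(BaseModel):
    question_id: str
    round: str
    text: str
    answer_domain: Optional[tuple[str, ...]] = None
    new: bool = False

    model_config = {"frozen": True}


class IngestSummary(BaseModel):
    round: str
    responses: int
    answers: int
    suppressed_answers: int
    rejected_rows: tuple[str, ...] = ()
    rejected_answers: tuple[str, ...] = ()

    model_config = {"frozen": True}


class SurveyManager:
    """Survey registry and response store bound to a :class:`StudyStore`."""

    def __init__(self, store: StudyStore):
        self.store = store
        conn = store.conn
        for ddl in _SURVEY_DDL:
            conn.execute(ddl)
        conn.commit()

    # -- question registry ---------------------------------------------------

    def rounds(self) -> list[str]:
        return [
            r[0]
            for r in self.store.conn.execute(
                "SELECT DISTINCT round FROM survey_question ORDER BY round"
            )
        ]

    def registry(self, round: str | None = None) -> list[SurveyQuestion]:
        sql = (
            "SELECT question_id, round, text, answer_domain "
            "FROM survey_question"
        )
        params: tuple = ()
        if round is not None:
            sql += " WHERE round=?"
            params = (round,)
        out = []
        for qid, rnd, text, domain in self.store.conn.execute(sql, params):
            out.append(
                SurveyQuestion(
                    question_id=qid,
                    round=rnd,
                    text=text,
                    answer_domain=tuple(domain.split("|")) if domain else None,
                )
            )
        return out

    def suggest_equivalency(
        self, questions: Sequence[tuple[str, Optional[Sequence[str]]]]
    ) -> dict[str, str]:
        """Exact-text suggestions only: texts already in the registry map to
        their existing question_id. A curation aid, never applied silently."""
        known = {
            text: qid
            for qid, _, text, _ in self.store.conn.execute(
                "SELECT question_id, round, text, answer_domain "
                "FROM survey_question"
            )
        }
        return {
            text: known[text] for text, _ in questions if text in known
        }

    def register_round(
        self,
        round: str,
        questions: Sequence[tuple[str, Optional[Sequence[str]]]],
        equivalency_map: Mapping[str, str] | None = None,
    ) -> list[SurveyQuestion]:
        """Register a round's questions.

        ``questions`` is an ordered list of (text, answer_domain);
        ``equivalency_map`` maps question text to an existing question_id.
        Unmatched questions get fresh ids and come back flagged ``new``.
        """
        conn = self.store.conn
        if round in self.rounds():
            raise UsageError(f"round {round!r} already registered")
        equivalency_map = dict(equivalency_map or {})
        assigned: dict[str, str] = {}
        out: list[SurveyQuestion] = []
        next_id = self._next_question_number()
        for text, domain in questions:
            qid = equivalency_map.get(text)
            new = qid is None
            if new:
                qid = f"Q{next_id:04d}"
                next_id += 1
            if qid in assigned:
                raise UsageError(
                    f"round {round!r}: questions {assigned[qid]!r} and "
                    f"{text!r} both map to {qid}"
                )
            assigned[qid] = text
            out.append(
                SurveyQuestion(
                    question_id=qid,
                    round=round,
                    text=text,
                    answer_domain=tuple(domain) if domain else None,
                    new=new,
                )
            )
        with conn:
            for q in out:
                conn.execute(
                    "INSERT INTO survey_question "
                    "(question_id, round, text, answer_domain) "
                    "VALUES (?,?,?,?)",
                    (
                        q.question_id,
                        q.round,
                        q.text,
                        "|".join(q.answer_domain) if q.answer_domain else None,
                    ),
                )
        return out

    def _next_question_number(self) -> int:
        row = self.store.conn.execute(
            "SELECT MAX(CAST(substr(question_id, 2) AS INTEGER)) "
            "FROM survey_question WHERE question_id GLOB 'Q*'"
        ).fetchone()
        return (row[0] or 0) + 1

    # -- response ingest -----------------------------------------------------

    def ingest_responses(
        self,
        export: Iterable[Mapping[str, object]],
        round: str,
    ) -> IngestSummary:
        """Ingest a platform export for a registered round.

        ``export`` rows carry respondent_id, consented, completed, and an
        ``answers`` mapping of question text/id -> answer. One response row
        per respondent; for consenting respondents one answer row per
        answered question; for nonconsenting respondents the response row
        is written flagged nonconsenting and every answer in the export is
        suppressed — this covers consent withdrawn after answering.
        """
        if round not in self.rounds():
            raise UsageError(f"round {round!r} is not registered")
        by_text = {
            q.text: q.question_id for q in self.registry(round)
        }
        valid_ids = set(by_text.values())
        conn = self.store.conn
        responses = answers = suppressed = 0
        rejected_rows: list[str] = []
        rejected_answers: list[str] = []
        seen: set[str] = set()
        with conn:
            for row in export:
                rid = str(row["respondent_id"])
                if rid in seen or self._has_response(rid, round):
                    rejected_rows.append(rid)
                    continue
                seen.add(rid)
                consented = _as_bool(row.get("consented"))
                completed = _as_bool(row.get("completed"))
                response_id = f"{round}:{rid}"
                conn.execute(
                    "INSERT INTO survey_response "
                    "(response_id, respondent_id, round, completed, consented)"
                    " VALUES (?,?,?,?,?)",
                    (response_id, rid, round, int(completed), int(consented)),
                )
                responses += 1
                raw_answers = row.get("answers") or {}
                for key, answer in raw_answers.items():
                    if answer in ("", None):
                        continue
                    qid = by_text.get(str(key)) or (
                        str(key) if str(key) in valid_ids else None
                    )
                    if qid is None:
                        rejected_answers.append(f"{rid}:{key}")
                        continue
                    if not consented:
                        suppressed += 1
                        continue
                    conn.execute(
                        "INSERT OR IGNORE INTO survey_answer "
                        "(response_id, question_id, answer) VALUES (?,?,?)",
                        (response_id, qid, str(answer)),
                    )
                    answers += 1
        return IngestSummary(
            round=round,
            responses=responses,
            answers=answers,
            suppressed_answers=suppressed,
            rejected_rows=tuple(rejected_rows),
            rejected_answers=tuple(rejected_answers),
        )

    def _has_response(self, respondent_id: str, round: str) -> bool:
        return (
            self.store.conn.execute(
                "SELECT 1 FROM survey_response "
                "WHERE respondent_id=? AND round=?",
                (respondent_id, round),
            ).fetchone()
            is not None
        )

    # -- analytic tables -----------------------------------------------------

    def answers_frame(
        self,
        question_ids: set[str] | None = None,
        rounds: set[str] | None = None,
    ) -> pd.DataFrame:
        """The consented answer relation as a tidy frame:
        (respondent_id, round, question_id, answer)."""
        df = pd.read_sql_query(
            "SELECT r.respondent_id, r.round, a.question_id, a.answer "
            "FROM survey_answer a "
            "JOIN survey_response r ON a.response_id = r.response_id "
            "WHERE r.consented = 1",
            self.store.conn,
        )
        if question_ids is not None:
            df = df[df["question_id"].isin(question_ids)]
        if rounds is not None:
            df = df[df["round"].isin(rounds)]
        return df.reset_index(drop=True)

    def derive_analytic(
        self,
        question_ids: set[str] | None = None,
        rounds: set[str] | None = None,
    ) -> pd.DataFrame:
        """Pivot the long answer store into an analysis-ready wide table:
        one row per (respondent, round), one column per question_id, empty
        cells where unanswered. The pivot is lossless: melting it back
        reproduces the underlying answer rows."""
        all_qids = {
            r[0]
            for r in self.store.conn.execute(
                "SELECT DISTINCT question_id FROM survey_question"
            )
        }
        if question_ids is not None:
            unknown = set(question_ids) - all_qids
            if unknown:
                raise UsageError(
                    f"unknown question ids: {sorted(unknown)}"
                )
        df = self.answers_frame(question_ids, rounds)
        cols = sorted(question_ids if question_ids is not None else all_qids)
        if df.empty:
            wide = pd.DataFrame(columns=["respondent_id", "round", *cols])
            return wide
        wide = df.pivot_table(
            index=["respondent_id", "round"],
            columns="question_id",
            values="answer",
            aggfunc="first",
        )
        wide = wide.reindex(columns=cols).fillna("").reset_index()
        wide.columns.name = None
        return wide.sort_values(["respondent_id", "round"]).reset_index(
            drop=True
        )

    def consent_violations(self) -> int:
        """Answer rows attached to nonconsenting responses. Always 0 by
        construction; exposed so audits can assert it."""
        return self.store.conn.execute(
            "SELECT COUNT(*) FROM survey_answer a "
            "JOIN survey_response r ON a.response_id = r.response_id "
            "WHERE r.consented = 0"
        ).fetchone()[0]

    def relation_columns(self) -> dict[str, list[str]]:
        """Column structure of the three survey relations; stable across
        round registrations (the schema-stability property)."""
        out = {}
        for t in ("survey_question", "survey_response", "survey_answer"):
            out[t] = [
                r[1]
                for r in self.store.conn.execute(f'PRAGMA table_info("{t}")')
            ]
        return out


def melt_analytic(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide analytic table back to the tidy answer relation (the
    round-trip inverse of :meth:`SurveyManager.derive_analytic`)."""
    long = wide.melt(
        id_vars=["respondent_id", "round"],
        var_name="question_id",
        value_name="answer",
    )
    long = long[long["answer"] != ""]
    return (
        long.sort_values(["respondent_id", "round", "question_id"])
        .reset_index(drop=True)
    )


def read_survey_export(path: str | Path, round: str) -> list[dict]:
    """Read a raw survey-platform CSV export into ingest rows.

    Wide layout: columns respondent_id, consented, completed, then one
    column per question (header = question text or id). Long layout:
    columns respondent_id, consented, completed, question, answer.
    """
    text = Path(path).read_text(encoding="utf-8")
    reader = csv.DictReader(io.StringIO(text))
    fields = reader.fieldnames or []
    meta = {"respondent_id", "consented", "completed", "round"}
    if {"question", "answer"} <= set(fields):
        rows: dict[str, dict] = {}
        for raw in reader:
            rid = raw["respondent_id"]
            row = rows.setdefault(
                rid,
                {
                    "respondent_id": rid,
                    "consented": raw.get("consented", ""),
                    "completed": raw.get("completed", ""),
                    "answers": {},
                },
            )
            if raw.get("question"):
                row["answers"][raw["question"]] = raw.get("answer", "")
        return list(rows.values())
    out = []
    for raw in reader:
        answers = {
            k: v for k, v in raw.items() if k not in meta and v not in ("", None)
        }
        out.append(
            {
                "respondent_id": raw["respondent_id"],
                "consented": raw.get("consented", ""),
                "completed": raw.get("completed", ""),
                "answers": answers,
            }
        )
    return out


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("1", "true", "yes", "y")
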