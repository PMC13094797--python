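"""Survey registry, consent-gated ingest, and analytic pivots."""

import sqlite3

import pytest

import studyflow as sf
from studyflow.errors import UsageError
from studyflow.survey import SurveyManager, melt_analytic, read_survey_export


@pytest.fixture()
def mgr(store):
    return SurveyManager(store)


Q1 = [
    ("Have you felt well this month?", ("Y", "N")),
    ("How many donations this year?", ("0", "1", "2", "3+")),
    ("Any recent travel?", ("Y", "N")),
    ("Describe symptoms, if any.", None),
    ("Vaccinated this season?", ("Y", "N")),
]


class TestRegisterRound:
    def test_identity_round_keeps_all_question_ids(self, mgr):
        r1 = mgr.register_round("R1", Q1)
        sugg = mgr.suggest_equivalency(Q1)
        r2 = mgr.register_round("R2", Q1, sugg)
        assert [q.question_id for q in r1] == [q.question_id for q in r2]
        assert sum(q.new for q in r2) == 0

    def test_reworded_question_keeps_id_via_curated_map(self, mgr):
        r1 = mgr.register_round("R1", Q1)
        reworded = list(Q1)
        reworded[0] = ("Did you feel well during the past month?", ("Y", "N"))
        curated = dict(mgr.suggest_equivalency(reworded))
        curated[reworded[0][0]] = r1[0].question_id
        r2 = mgr.register_round("R2", reworded, curated)
        assert r2[0].question_id == r1[0].question_id
        rows = mgr.store.conn.execute(
            "SELECT COUNT(*) FROM survey_question WHERE question_id=?",
            (r1[0].question_id,),
        ).fetchone()[0]
        assert rows == 2  # one registry row per round

    def test_partial_overlap_counts(self, mgr):
        ten = Q1 + [
            (f"Extra item {i}?", ("Y", "N")) for i in range(5)
        ]
        mgr.register_round("R1", ten)
        seven = ten[:7]
        three_new = [(f"Novel item {i}?", None) for i in range(3)]
        sugg = mgr.suggest_equivalency(seven)
        r2 = mgr.register_round("R2", seven + three_new, sugg)
        assert sum(q.new for q in r2) == 3
        total = mgr.store.conn.execute(
            "SELECT COUNT(*) FROM survey_question"
        ).fetchone()[0]
        assert total == 20

    def test_two_questions_one_id_is_usage_error(self, mgr):
        r1 = mgr.register_round("R1", Q1)
        qid = r1[0].question_id
        bad_map = {"A?": qid, "B?": qid}
        with pytest.raises(UsageError):
            mgr.register_round("R2", [("A?", None), ("B?", None)], bad_map)

    def test_duplicate_round_label_rejected(self, mgr):
        mgr.register_round("R1", Q1)
        with pytest.raises(UsageError):
            mgr.register_round("R1", Q1)


class TestIngest:
    def make_round(self, mgr):
        return mgr.register_round("R1", Q1)

    def test_consent_mix_arithmetic(self, mgr):
        qs = self.make_round(mgr)
        t = [q.text for q in qs]
        export = [
            {"respondent_id": "D1", "consented": "1", "completed": "1",
             "answers": {t[i]: "Y" for i in range(5)}},
            {"respondent_id": "D2", "consented": "1", "completed": "0",
             "answers": {t[0]: "N", t[1]: "2"}},
            {"respondent_id": "D3", "consented": "0", "completed": "1",
             "answers": {t[i]: "Y" for i in range(5)}},
        ]
        s = mgr.ingest_responses(export, "R1")
        assert s.responses == 3
        assert s.answers == 7
        assert s.suppressed_answers == 5
        assert mgr.consent_violations() == 0
        flags = dict(
            mgr.store.conn.execute(
                "SELECT respondent_id, consented FROM survey_response"
            )
        )
        assert flags == {"D1": 1, "D2": 1, "D3": 0}

    def test_duplicate_respondent_round_keeps_first(self, mgr):
        t = [q.text for q in self.make_round(mgr)]
        export = [
            {"respondent_id": "D1", "consented": "1", "completed": "1",
             "answers": {t[0]: "Y"}},
            {"respondent_id": "D1", "consented": "1", "completed": "1",
             "answers": {t[0]: "N"}},
        ]
        s = mgr.ingest_responses(export, "R1")
        assert s.responses == 1
        assert s.rejected_rows == ("D1",)
        val = mgr.store.conn.execute(
            "SELECT answer FROM survey_answer"
        ).fetchone()[0]
        assert val == "Y"

    def test_empty_export(self, mgr):
        self.make_round(mgr)
        s = mgr.ingest_responses([], "R1")
        assert (s.responses, s.answers, s.suppressed_answers) == (0, 0, 0)

    def test_unregistered_question_itemized(self, mgr):
        self.make_round(mgr)
        export = [
            {"respondent_id": "D1", "consented": "1", "completed": "1",
             "answers": {"Never registered?": "Y"}},
        ]
        s = mgr.ingest_responses(export, "R1")
        assert s.answers == 0
        assert s.rejected_answers == ("D1:Never registered?",)

    def test_unregistered_round_is_usage_error(self, mgr):
        with pytest.raises(UsageError):
            mgr.ingest_responses([], "R9")

    def test_consent_gate_holds_under_adversarial_export(
        self, config, store
    ):
        """Raw exports always carry answers for non-consenters (late
        withdrawal); none may be stored."""
        mgr = SurveyManager(store)
        sim = sf.SimConfig(seed=13, n_donors=40, consent_rate=0.5)
        study = sf.generate_study(sim, config)
        adversarial = 0
        for rnd in study.survey_rounds:
            sugg = mgr.suggest_equivalency(rnd.questions)
            mgr.register_round(rnd.label, rnd.questions, sugg)
            adversarial += sum(
                len(r["answers"])
                for r in rnd.export_rows
                if r["consented"] == "0"
            )
            mgr.ingest_responses(rnd.export_rows, rnd.label)
        assert adversarial > 0
        assert mgr.consent_violations() == 0
        total_suppressed = adversarial  # every nonconsented answer suppressed
        stored = mgr.store.conn.execute(
            "SELECT COUNT(*) FROM survey_answer"
        ).fetchone()[0]
        all_answers = sum(
            len(r["answers"])
            for rnd in study.survey_rounds
            for r in rnd.export_rows
        )
        assert stored == all_answers - total_suppressed

    def test_database_trigger_backs_the_gate(self, mgr):
        self.make_round(mgr)
        mgr.ingest_responses(
            [{"respondent_id": "D9", "consented": "0", "completed": "1",
              "answers": {}}],
            "R1",
        )
        with pytest.raises(sqlite3.IntegrityError):
            mgr.store.conn.execute(
                "INSERT INTO survey_answer VALUES ('R1:D9', 'Q0001', 'Y')"
            )


class TestAnalytic:
    def test_single_respondent_wide_row(self, mgr):
        qs = mgr.register_round("R1", Q1[:2])
        t = [q.text for q in qs]
        mgr.ingest_responses(
            [{"respondent_id": "D1", "consented": "1", "completed": "1",
              "answers": {t[0]: "Y", t[1]: "3+"}}],
            "R1",
        )
        wide = mgr.derive_analytic()
        assert wide.shape == (1, 4)  # respondent, round, 2 questions
        assert wide.loc[0, qs[0].question_id] == "Y"

    def test_question_absent_from_round_yields_empty_cells(self, mgr):
        r1 = mgr.register_round("R1", Q1[:2])
        # round 2 drops the second question
        sugg = mgr.suggest_equivalency(Q1[:1])
        mgr.register_round("R2", Q1[:1], sugg)
        t0 = Q1[0][0]
        for rnd in ("R1", "R2"):
            mgr.ingest_responses(
                [{"respondent_id": "D1", "consented": "1", "completed": "1",
                  "answers": {t0: "Y"}}],
                rnd,
            )
        wide = mgr.derive_analytic()
        q2 = r1[1].question_id
        assert set(wide[q2]) == {""}

    def test_unknown_question_id_is_usage_error(self, mgr):
        mgr.register_round("R1", Q1[:1])
        with pytest.raises(UsageError):
            mgr.derive_analytic(question_ids={"Q9999"})

    def test_pivot_roundtrip_on_random_fixture(self, config, store):
        """melt(derive_analytic(...)) reproduces the stored answer relation
        exactly (50 respondents x 3 rounds, 30% churn)."""
        mgr = SurveyManager(store)
        sim = sf.SimConfig(
            seed=17, n_donors=120, n_respondents=50, n_rounds=3,
            question_churn=0.3,
        )
        study = sf.generate_study(sim, config)
        for rnd in study.survey_rounds:
            sugg = mgr.suggest_equivalency(rnd.questions)
            mgr.register_round(rnd.label, rnd.questions, sugg)
            mgr.ingest_responses(rnd.export_rows, rnd.label)
        wide = mgr.derive_analytic()
        long = melt_analytic(wide)
        truth = (
            mgr.answers_frame()
            .sort_values(["respondent_id", "round", "question_id"])
            .reset_index(drop=True)
        )
        assert long.equals(truth)

    def test_schema_stability_across_round_registration(self, config, store):
        mgr = SurveyManager(store)
        mgr.register_round("R1", Q1)
        before = mgr.relation_columns()
        new_qs = [(f"Wave-two item {i}?", None) for i in range(8)]
        mgr.register_round("R2", new_qs)
        assert mgr.relation_columns() == before


class TestExportReader:
    def test_wide_and_long_layouts_agree(self, tmp_path):
        wide = tmp_path / "wide.csv"
        wide.write_text(
            "respondent_id,consented,completed,Q-A,Q-B\n"
            "D1,1,1,Y,N\nD2,0,1,Y,\n"
        )
        long = tmp_path / "long.csv"
        long.write_text(
            "respondent_id,consented,completed,question,answer\n"
            "D1,1,1,Q-A,Y\nD1,1,1,Q-B,N\nD2,0,1,Q-A,Y\n"
        )
        w = read_survey_export(wide, "R1")
        l = read_survey_export(long, "R1")
        assert w == l
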