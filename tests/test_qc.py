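"""Cell, key and submission-level validation behaviour."""

import datetime

import pytest
from hypothesis import given, settings, strategies as st

import studyflow as sf
from studyflow.config import FieldSpec, TableSchema
from studyflow.qc import (
    check_keys,
    check_row,
    finalize_report,
    parse_report,
    render_report,
    validate_submission,
)
from studyflow.errors import TransportError, UsageError


def schema_with(*fields):
    pk = FieldSpec(name="id", type="text", key="primary", required=True)
    return TableSchema(name="t", fields=(pk, *fields))


class TestCheckRow:
    def test_nonnumeric_in_integer_field_is_type(self):
        s = schema_with(FieldSpec(name="age", type="integer"))
        issues = check_row({"id": "1", "age": "forty"}, s, 1)
        assert [i.kind for i in issues] == ["TYPE"]

    def test_code_outside_enumeration(self):
        s = schema_with(
            FieldSpec(name="sex", type="code", codes=["M", "F", "O"])
        )
        issues = check_row({"id": "1", "sex": "X"}, s, 1)
        assert [i.kind for i in issues] == ["ENUM"]

    @pytest.mark.parametrize(
        "value,expect_issue",
        [
            ("2020-02-30", True),   # nonexistent calendar date
            ("2019-12-31", True),   # below lower bound
            ("2025-01-01", True),   # above upper bound
            ("2020-02-29", False),  # real leap day, in bounds
            ("2024-12-31", False),  # boundary inclusive
        ],
    )
    def test_date_calendar_and_bounds(self, value, expect_issue):
        """Agreement with an independent calendar oracle."""
        s = schema_with(
            FieldSpec(
                name="d", type="date",
                date_bounds=["2020-01-01", "2024-12-31"],
            )
        )
        issues = check_row({"id": "1", "d": value}, s, 1)
        kinds = [i.kind for i in issues]
        # oracle: stdlib parse + direct comparison
        try:
            parsed = datetime.date.fromisoformat(value)
            bad = not (
                datetime.date(2020, 1, 1)
                <= parsed
                <= datetime.date(2024, 12, 31)
            )
        except ValueError:
            bad = True
        assert bad == expect_issue
        assert kinds == (["DATE"] if expect_issue else [])

    def test_type_failure_suppresses_downstream_checks(self):
        # a non-date token in a bounded short date field raises TYPE only
        s = schema_with(
            FieldSpec(
                name="d", type="date", max_length=10,
                date_bounds=["2020-01-01", "2020-12-31"],
            )
        )
        issues = check_row({"id": "1", "d": "#invalid-far-too-long#"}, s, 1)
        assert [i.kind for i in issues] == ["TYPE"]

    def test_required_empty_cell(self):
        s = schema_with(FieldSpec(name="v", type="text", required=True))
        issues = check_row({"id": "1", "v": ""}, s, 1)
        assert [i.kind for i in issues] == ["REQUIRED"]

    def test_overlength_text(self):
        s = schema_with(FieldSpec(name="v", type="text", max_length=3))
        issues = check_row({"id": "1", "v": "abcd"}, s, 1)
        assert [i.kind for i in issues] == ["LENGTH"]

    def test_clean_row_no_issues(self):
        s = schema_with(
            FieldSpec(name="age", type="integer"),
            FieldSpec(name="sex", type="code", codes=["M", "F"]),
        )
        assert check_row({"id": "1", "age": "42", "sex": "F"}, s, 1) == []


class TestCheckKeys:
    def test_duplicate_pk_flags_later_occurrence_only(self):
        s = schema_with()
        rows = [{"id": v} for v in ["1", "2", "2", "3"]]
        issues = check_keys(rows, s)
        assert [(i.kind, i.row) for i in issues] == [("DUP_KEY", 3)]

    def test_fk_orphans_equal_set_difference(self):
        """Brute-force oracle: rows referencing ids outside the context."""
        donor = FieldSpec(
            name="donor_id", type="text", key="foreign",
            references=["donor", "donor_id"],
        )
        s = schema_with(donor)
        rows = [
            {"id": str(n), "donor_id": d}
            for n, d in enumerate(["7", "8", "7", "8", "8"], 1)
        ]
        ctx = {"donor": {"7"}}
        issues = check_keys(rows, s, ctx)
        expected = sum(1 for r in rows if r["donor_id"] not in ctx["donor"])
        assert len(issues) == expected
        assert {i.kind for i in issues} == {"FK_ORPHAN"}

    def test_empty_table_is_vacuous(self):
        assert check_keys([], schema_with()) == []

    def test_no_primary_key_is_usage_error(self):
        f = FieldSpec(name="id", type="text", key="primary")
        s = TableSchema(name="t", fields=(f,))
        bare = s.model_copy(
            update={"fields": (FieldSpec(name="x", type="text"),)}
        )
        with pytest.raises(UsageError):
            check_keys([], bare)


class TestValidateSubmission:
    def test_clean_synthetic_submission_accepted(
        self, config, small_study, tmp_path
    ):
        _, study = small_study
        files = sf.write_org_files(study, tmp_path, config)
        for org, fs in files.items():
            report = validate_submission(fs, config, submission_id=org)
            assert report.accepted
            assert report.issues == ()

    def test_ledger_multiset_equality(self, config, small_study, tmp_path):
        sim, study = small_study
        corrupted, ledger = sf.corrupt(study, sim, config)
        files = sf.write_org_files(corrupted, tmp_path, config)
        assert ledger.entries, "fixture must inject at least one error"
        for org, fs in files.items():
            report = validate_submission(fs, config, submission_id=org)
            got = {}
            for i in report.issues:
                got[i.key()] = got.get(i.key(), 0) + 1
            want = dict(ledger.issue_multiset(org))
            assert got == want

    def test_missing_required_column_rejects_at_table_level(
        self, config, tmp_path
    ):
        p = tmp_path / "donor.csv"
        p.write_text("donor_id,blood_group\nD1,A+\n")
        report = validate_submission({"donor": p}, config)
        assert not report.accepted
        missing = [i for i in report.issues if i.kind == "MISSING_COLUMN"]
        assert {i.field for i in missing} == {
            "birth_date", "sex", "race", "zip_code"
        }
        assert all(i.row == 0 for i in missing)
        # no per-row REQUIRED noise for the absent column
        assert not any(
            i.kind == "REQUIRED" and i.field == "birth_date"
            for i in report.issues
        )

    def test_unknown_column_warns_but_accepts(self, config, tmp_path):
        p = tmp_path / "donor.csv"
        p.write_text(
            "donor_id,birth_date,blood_group,sex,race,zip_code,extra\n"
            "D1,1980-05-04,A+,F,W,94110,hello\n"
        )
        report = validate_submission({"donor": p}, config)
        assert report.accepted
        assert report.counts == {"UNKNOWN_COLUMN": 1}

    def test_unreadable_file_is_transport_error(self, config, tmp_path):
        p = tmp_path / "donor.csv"
        p.write_text("")
        with pytest.raises(TransportError):
            validate_submission({"donor": p}, config)

    def test_parent_in_same_submission_satisfies_fk(self, config, tmp_path):
        donor = tmp_path / "donor.csv"
        donor.write_text(
            "donor_id,birth_date,blood_group,sex,race,zip_code\n"
            "D1,1980-05-04,A+,F,W,94110\n"
        )
        donation = tmp_path / "donation.csv"
        donation.write_text(
            "donation_id,donor_id,visit_date,donation_type,donation_weight_g\n"
            "V1,D1,2022-03-01,WB,4500\n"
        )
        report = validate_submission(
            {"donation": donation, "donor": donor}, config
        )
        assert report.accepted

    def test_verdict_monotonicity(self, config):
        accepted = finalize_report("s", [], 1)
        assert accepted.accepted
        warn = sf.ValidationIssue(
            kind="UNKNOWN_COLUMN", table="t", row=0, field="x",
            observed="x", expected="", severity="warn",
        )
        reject = sf.ValidationIssue(
            kind="TYPE", table="t", row=1, field="x",
            observed="?", expected="", severity="reject",
        )
        assert finalize_report("s", [warn], 1).accepted
        assert not finalize_report("s", [warn, reject], 1).accepted


class TestOrderInvariance:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_row_permutation_preserves_issue_multiset(
        self, seed, demo_config, tmp_path_factory
    ):
        """Shuffling submitted rows relabels ordinals but leaves the
        (kind, field) issue multiset intact (DUP_KEY excepted by design:
        first occurrence follows the new order, but the count is stable)."""
        import random

        sim = sf.SimConfig(
            seed=seed, n_donors=12, n_orgs=1, error_rate=0.15
        )
        study = sf.generate_study(sim, demo_config)
        corrupted, _ = sf.corrupt(study, sim, demo_config)
        rng = random.Random(seed)
        base = tmp_path_factory.mktemp("perm")
        files = sf.write_org_files(corrupted, base / "a", demo_config)
        for rows in corrupted.orgs["O1"].values():
            rng.shuffle(rows)
        files2 = sf.write_org_files(corrupted, base / "b", demo_config)
        org = next(iter(files))
        r1 = validate_submission(files[org], demo_config)
        r2 = validate_submission(files2[org], demo_config)
        m1 = sorted((i.kind, i.table, i.field) for i in r1.issues)
        m2 = sorted((i.kind, i.table, i.field) for i in r2.issues)
        assert m1 == m2


class TestRenderReport:
    def test_empty_report_is_header_only(self):
        report = finalize_report("s0", [], 3)
        out = render_report(report, "delimited")
        assert out.count("\n") == 1

    def test_line_count_matches_issues(self, config, small_study, tmp_path):
        sim, study = small_study
        corrupted, ledger = sf.corrupt(study, sim, config)
        files = sf.write_org_files(corrupted, tmp_path, config)
        org = corrupted.org_ids()[0]
        report = validate_submission(files[org], config, submission_id=org)
        out = render_report(report, "delimited")
        assert out.count("\n") == 1 + len(report.issues)

    def test_delimited_roundtrip_recovers_issue_multiset(
        self, config, small_study, tmp_path
    ):
        sim, study = small_study
        corrupted, _ = sf.corrupt(study, sim, config)
        files = sf.write_org_files(corrupted, tmp_path, config)
        org = corrupted.org_ids()[0]
        report = validate_submission(files[org], config, submission_id=org)
        back = parse_report(render_report(report, "delimited"))
        assert back.submission_id == report.submission_id
        assert back.verdict == report.verdict
        assert back.issues == report.issues

    def test_human_format_embeds_verdict(self):
        report = finalize_report("sub9", [], 0)
        text = render_report(report, "human")
        assert "sub9" in text and "ACCEPTED" in text
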