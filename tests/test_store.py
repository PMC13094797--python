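"""Study database: schema materialization, atomic import, recoding,
identifier chains, and the redundant-QC property."""

import random
import sqlite3

import pytest

import studyflow as sf
from studyflow.errors import DataIntegrityError, UsageError
from studyflow.qc import validate_submission
from studyflow.store import StudyStore


def org_files(config, tmp_path, seed=3, donors=20, orgs=1):
    sim = sf.SimConfig(seed=seed, n_donors=donors, n_orgs=orgs)
    study = sf.generate_study(sim, config)
    return study, sf.write_org_files(study, tmp_path, config)


class TestCreateSchema:
    def test_demo_dictionary_relation_counts(self, store, config):
        names = store.relation_names()
        data = [n for n in names if n in config.dictionaries]
        lookups = [n for n in names if n.startswith("lookup_")]
        assert len(data) == 3
        assert len(lookups) == 2
        assert "identifier_change" in names

    def test_empty_dictionary_rejected(self, tmp_path):
        cfg = sf.parse_config({"study_id": "x", "dictionaries": {}})
        with pytest.raises(UsageError):
            StudyStore(tmp_path / "x.db").create_schema(cfg)

    def test_recreate_is_idempotent(self, store, config):
        store.create_schema(config)  # same dictionary: no-op, no error

    def test_incompatible_existing_relation(self, tmp_path, config):
        s = StudyStore(tmp_path / "m.db")
        s.conn.execute("CREATE TABLE donor (x TEXT)")
        with pytest.raises(sf.MigrationError):
            s.create_schema(config)

    def test_ddl_dump_contains_constraints(self, store):
        ddl = store.ddl_dump()
        assert "STRICT" in ddl and "CHECK" in ddl and "FOREIGN KEY" in ddl


class TestRedundantQC:
    """Rows the rule engine rejects must also be refused by the database."""

    def test_enum_violation_refused_directly(self, store):
        with pytest.raises(sqlite3.IntegrityError):
            store.raw_insert(
                "donor",
                {"donor_id": "X1", "birth_date": "1990-05",
                 "blood_group": "A+", "sex": "Q", "race": "W",
                 "zip_code": "941"},
            )

    def test_random_violating_rows_refused(self, config, store, tmp_path):
        """Corrupted cells that QC flags at reject severity are refused on
        direct insertion (date-validity corruption aside, which the SQL
        layer checks only for shape)."""
        sim = sf.SimConfig(
            seed=5, n_donors=40, n_orgs=1, error_rate=0.2,
            error_mix={"TYPE": 1, "LENGTH": 1, "ENUM": 1, "REQUIRED": 1},
        )
        study = sf.generate_study(sim, config)
        corrupted, ledger = sf.corrupt(study, sim, config)
        assert len(ledger.entries) >= 20
        refused = 0
        for e in ledger.entries:
            row = dict(corrupted.orgs[e.org][e.table][e.row - 1])
            # privacy-at-import transforms would normally minimize these
            # cells; bypass them the way a buggy loader would
            if e.table == "donor":
                row["birth_date"] = row["birth_date"][:7]
                row["zip_code"] = row["zip_code"][:3] if e.field != "zip_code" else row["zip_code"]
            with pytest.raises(sqlite3.IntegrityError):
                store.raw_insert(e.table, row)
            refused += 1
        assert refused == len(ledger.entries)


class TestImport:
    def test_accepted_import_commits_all_rows(self, config, store, tmp_path):
        study, files = org_files(config, tmp_path)
        report = validate_submission(files["O1"], config, submission_id="s1")
        result = store.import_submission(files["O1"], report, config)
        assert result.outcome == "committed"
        assert result.rows_written == result.rows_attempted
        total = sum(store.row_count(t) for t in config.dictionaries)
        assert total == result.rows_written

    def test_replay_is_committed_noop(self, config, store, tmp_path):
        _, files = org_files(config, tmp_path)
        report = validate_submission(files["O1"], config, submission_id="s1")
        store.import_submission(files["O1"], report, config)
        before = {t: store.row_count(t) for t in config.dictionaries}
        again = store.import_submission(files["O1"], report, config)
        assert again.outcome == "committed"
        assert again.rows_written == 0
        assert {t: store.row_count(t) for t in config.dictionaries} == before

    def test_rejected_report_is_usage_error(self, config, store, tmp_path):
        _, files = org_files(config, tmp_path)
        report = validate_submission(files["O1"], config)
        bad = report.model_copy(update={"verdict": "rejected"})
        with pytest.raises(UsageError):
            store.import_submission(files["O1"], bad, config)

    def test_warned_enum_violation_rolls_back_whole_submission(
        self, config, tmp_path
    ):
        """QC waved the row through (ENUM downgraded to warn) but the
        materialized constraint stops it; nothing is written."""
        config.qc_policy["ENUM"] = "warn"
        sim = sf.SimConfig(seed=7, n_donors=15, n_orgs=1)
        study = sf.generate_study(sim, config)
        study.orgs["O1"]["donor"][7]["sex"] = "Z"
        files = sf.write_org_files(study, tmp_path, config)
        report = validate_submission(files["O1"], config, submission_id="s2")
        assert report.accepted and report.counts.get("ENUM") == 1
        store = sf.open_store(tmp_path / "s.db", config)
        result = store.import_submission(files["O1"], report, config)
        assert result.outcome == "rolled_back"
        assert result.rows_written == 0
        assert "row 8" in result.error
        assert all(store.row_count(t) == 0 for t in config.dictionaries)

    def test_privacy_minimized_at_import(self, config, store, tmp_path):
        _, files = org_files(config, tmp_path)
        report = validate_submission(files["O1"], config, submission_id="s1")
        store.import_submission(files["O1"], report, config)
        for (bd, zp) in store.conn.execute(
            "SELECT birth_date, zip_code FROM donor"
        ):
            assert len(bd) == 7  # YYYY-MM
            assert zp is None or len(zp) == 3

    def test_changed_donor_id_stored_canonically(self, config, store, tmp_path):
        study, files = org_files(config, tmp_path, seed=9)
        donor_file = files["O1"]["donor"]
        report_d = validate_submission(
            {"donor": donor_file}, config, submission_id="d"
        )
        store.import_submission({"donor": donor_file}, report_d, config)
        old = study.orgs["O1"]["donation"][0]["donor_id"]
        new = study.orgs["O1"]["donor"][-1]["donor_id"]
        if old != new:
            store.record_identifier_change("donor", old, new, "2024-01-01")
        don_file = files["O1"]["donation"]
        report = validate_submission(
            {"donation": don_file}, config,
            context=store.key_context(), submission_id="don",
        )
        store.import_submission({"donation": don_file}, report, config)
        stored = {
            r[0]
            for r in store.conn.execute(
                "SELECT DISTINCT donor_id FROM donation"
            )
        }
        assert old not in stored or old == new
        assert new in stored


class TestRecode:
    def seed_donors(self, config, store, tmp_path):
        _, files = org_files(config, tmp_path, seed=11, donors=30)
        report = validate_submission(files["O1"], config, submission_id="s")
        store.import_submission(files["O1"], report, config)

    def test_fully_mapped_lookup(self, config, store, tmp_path):
        self.seed_donors(config, store, tmp_path)
        rep = store.recode("donor", "race", config.lookup("race_group"))
        assert rep.unmapped == 0
        nonnull = store.conn.execute(
            "SELECT COUNT(*) FROM donor WHERE race IS NOT NULL"
        ).fetchone()[0]
        assert rep.mapped == nonnull

    def test_unmapped_value_counted_and_sentinel_written(
        self, config, store, tmp_path
    ):
        self.seed_donors(config, store, tmp_path)
        lk = sf.LookupTable(
            name="race_group",
            source=("donor", "race"),
            versions={1: {"W": "White"}},
        )
        rep = store.recode("donor", "race", lk)
        sentinels = store.conn.execute(
            "SELECT COUNT(*) FROM donor WHERE race_group = ?",
            (sf.UNMAPPED,),
        ).fetchone()[0]
        assert rep.unmapped == sentinels > 0

    def test_version_bump_changes_only_remapped_rows(
        self, config, store, tmp_path
    ):
        self.seed_donors(config, store, tmp_path)
        lk = config.lookup("race_group")
        store.recode("donor", "race", lk, version=1)
        rep2 = store.recode("donor", "race", lk, version=2)
        # oracle: rows whose v1 and v2 groups differ
        differ = {
            c for c in lk.versions[1]
            if lk.versions[1][c] != lk.versions[2].get(c)
        }
        expect = store.conn.execute(
            "SELECT COUNT(*) FROM donor WHERE race IN (%s)"
            % ",".join("?" * len(differ)),
            tuple(differ),
        ).fetchone()[0]
        assert rep2.changed == expect

    def test_originals_never_mutated(self, config, store, tmp_path):
        self.seed_donors(config, store, tmp_path)
        before = store.conn.execute(
            "SELECT donor_id, race FROM donor ORDER BY donor_id"
        ).fetchall()
        store.recode("donor", "race", config.lookup("race_group"))
        after = store.conn.execute(
            "SELECT donor_id, race FROM donor ORDER BY donor_id"
        ).fetchall()
        assert before == after

    def test_wrong_source_is_usage_error(self, config, store):
        lk = config.lookup("race_group")
        with pytest.raises(UsageError):
            store.recode("donation", "donation_type", lk)


class TestIdentifierResolution:
    def test_identity_without_changes(self, store):
        assert store.resolve_identifier("donor", "D1") == "D1"

    def test_chain_following(self, store):
        store.record_identifier_change("donor", "D1", "D9", "2024-01-01")
        store.record_identifier_change("donor", "D9", "D12", "2024-02-01")
        assert store.resolve_identifier("donor", "D1") == "D12"
        assert store.resolve_identifier("donor", "D9") == "D12"

    def test_cycle_detected(self, store):
        store.record_identifier_change("donor", "A", "B", "2024-01-01")
        store.record_identifier_change("donor", "B", "A", "2024-01-02")
        with pytest.raises(DataIntegrityError):
            store.resolve_identifier("donor", "A")

    def test_random_acyclic_chains_agree_with_brute_force(self, store):
        """Oracle: explicit path walk over 300 random acyclic chains."""
        rng = random.Random(0)
        links: dict[str, str] = {}
        nodes = [f"N{i}" for i in range(300)]
        for i, n in enumerate(nodes):
            # only link forward: guarantees acyclicity
            if i + 1 < len(nodes) and rng.random() < 0.7:
                links[n] = nodes[rng.randrange(i + 1, len(nodes))]
        for old, new in links.items():
            store.record_identifier_change("donor", old, new, "2024-01-01")

        def brute(n):
            while n in links:
                n = links[n]
            return n

        for n in nodes:
            assert store.resolve_identifier("donor", n) == brute(n)
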