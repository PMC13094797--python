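# studyflow

Configuration-driven data management for multicenter epidemiologic
studies — the kind of infrastructure behind large blood-donor
serosurveillance and cohort programs, where many collection organizations
submit donor, donation and laboratory-testing files on a schedule, survey
rounds evolve over time, and every delivery must be quality-controlled,
stored canonically, and re-reported downstream.

Everything study-specific lives in **one project-wide YAML configuration
file**: the data dictionaries (field types, lengths, enumerated codes,
primary/foreign keys, identifying-information classes), per-check QC
severities, versioned lookup recodings, per-organization exchange buckets,
and report definitions. The code is generic; adapting the system to a new
study or a dictionary revision means editing configuration, not source.

## What it does

* **QC engine** — validates delimited submissions cell by cell (type,
  length, calendar validity and bounds of dates, enumerated codes,
  required fields) and row by row (duplicate primary keys, orphaned
  foreign keys), producing a byte-reproducible itemized report and an
  atomic accepted/rejected verdict.
* **Intake workflow** — per-organization buckets with `upload/`,
  `download/` and `archive/` directories. New files (tracked by content
  digest) are validated and routed: accepted files are archived and
  imported; rejected files are returned alongside their itemized report;
  stakeholders are notified through pluggable sinks.
* **Study store** — an embedded relational database whose schema is
  derived from the dictionary, with every constraint materialized in SQL
  so the database itself refuses dictionary-violating rows (a redundant,
  passive QC line). Imports are transactional and idempotent; donor
  identifier changes are tracked and resolved to canonical ids; lookup
  recodings write derived columns without ever touching originals.
* **Survey manager** — long-format storage (questions / responses /
  answers) that absorbs round-to-round question churn without schema
  change, curated cross-round question equivalency, a hard consent gate
  (no answers stored for non-consenting respondents, even when the raw
  export contains them), and lossless wide analytic pivots.
* **Reporting** — configuration-driven extraction and transformation into
  outbound files that must pass the same QC engine, plus cross-field
  report hooks, before they are emitted.
* **Privacy transforms** — idempotent, fail-closed minimization of
  indirect identifiers at import (birth dates to `YYYY-MM`, ZIP codes to
  3-digit prefixes, outright drops for direct identifiers).
* **Simulator** — a seedable generator of complete multicenter studies
  (organizations, donors, donations, testing, multi-round surveys) with
  controlled per-cell error injection and a ground-truth error ledger, so
  the whole pipeline is testable offline with exact expected findings.

## Worked example

Validate a hand-written donor file with two deliberate problems:

```python
import tempfile, pathlib
import studyflow as sf
from studyflow.qc import render_report, validate_submission

config = sf.load_demo_config()
csv_text = """\
donor_id,birth_date,blood_group,sex,race,zip_code
D0001,1985-06-17,A+,F,W,94115
D0002,1990-02-30,O-,M,A,94110
D0003,1971-11-02,Q+,F,B,94117
"""
with tempfile.TemporaryDirectory() as td:
    p = pathlib.Path(td) / "donor.csv"
    p.write_text(csv_text)
    report = validate_submission({"donor": p}, config,
                                 submission_id="demo-submission")
print(render_report(report, "human"))
```

prints

```
Submission demo-submission: REJECTED
Rows checked: 3; issues: 2

Table donor:
  DATE (1):
    row 2, field birth_date: got '1990-02-30', expected a real calendar date
  ENUM (1):
    row 3, field blood_group: got 'Q+', expected one of {A+,A-,B+,B-,AB+,AB-,O+,O-}
```

Row 2 fails because 1990-02-30 is not a real calendar date; row 3 because
`Q+` is not an allowable blood-group code. One reject-severity finding
rejects the whole submission — the file would be returned to the
submitter with this report for correction and resubmission.

The `examples/` directory continues from here: `02_simulate_and_intake.py`
runs a simulated two-organization study through the full bucket workflow
(its rejected file's report matches the injected error ledger exactly),
`03_survey_rounds.py` shows question equivalency, consent gating and the
lossless analytic pivot, and `04_report_and_privacy.py` shows lookup
recoding, import-time privacy minimization and configured reporting.

There is also a CLI for running the workflows from a shell or cron:

```bash
studyflow --base work init
studyflow --base work simulate --seed 5 --donors 100 --to-buckets
studyflow --base work run-once
studyflow --base work report build donation_report
```

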