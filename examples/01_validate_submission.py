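"""Validate a small hand-written submission against the demo dictionary.

Builds a three-row donor CSV containing two deliberate problems (a
nonexistent calendar date and an out-of-enumeration blood group), runs the
QC engine, and prints the itemized report. The verdict is atomic: one
reject-severity finding returns the whole file to the submitter.
"""

import tempfile
from pathlib import Path

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
    path = Path(td) / "donor.csv"
    path.write_text(csv_text)
    report = validate_submission({"donor": path}, config,
                                 submission_id="demo-submission")

print(render_report(report, "human"))
# The DATE finding is row 2 (1990-02-30 is not a real date) and the ENUM
# finding is row 3 (Q+ is not an allowable blood group code); the verdict
# is REJECTED, so nothing would be imported.
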