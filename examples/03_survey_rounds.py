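"""Multi-round surveys: question equivalency, consent gating, pivots.

Registers three survey rounds with 30% question churn (carried-over
questions keep their question id), ingests platform exports that include
answers from non-consenting respondents (which must be suppressed), and
derives the wide analytic table. The melt of that table reproduces the
long answer relation exactly.
"""

import studyflow as sf
from studyflow.survey import SurveyManager, melt_analytic

config = sf.load_demo_config()
store = sf.open_store(":memory:", config)
mgr = SurveyManager(store)

sim = sf.SimConfig(seed=23, n_donors=80, n_respondents=40, n_rounds=3,
                   question_churn=0.3, consent_rate=0.8)
study = sf.generate_study(sim, config)

for rnd in study.survey_rounds:
    suggested = mgr.suggest_equivalency(rnd.questions)
    questions = mgr.register_round(rnd.label, rnd.questions, suggested)
    summary = mgr.ingest_responses(rnd.export_rows, rnd.label)
    print(
        f"{rnd.label}: {sum(q.new for q in questions)} new question ids, "
        f"{summary.responses} responses, {summary.answers} answers stored, "
        f"{summary.suppressed_answers} suppressed (no consent)"
    )

print("answers stored for non-consenters:", mgr.consent_violations())

wide = mgr.derive_analytic()
print("analytic table:", wide.shape[0], "rows x", wide.shape[1], "columns")
truth = (mgr.answers_frame()
         .sort_values(["respondent_id", "round", "question_id"])
         .reset_index(drop=True))
print("melt(wide) == answer relation:", melt_analytic(wide).equals(truth))
# Suppressed counts are nonzero because raw exports carry answers even
# for respondents who withdrew consent; the store never keeps them.
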