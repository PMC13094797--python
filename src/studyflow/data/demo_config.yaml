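# Demo study: a two-organization blood-donor cohort with donor, donation
# and testing tables, lookup recodes, two outbound reports and two intake
# buckets. Everything study-specific lives here; the code is generic.
study_id: demo_donor_cohort

qc_policy:
  UNKNOWN_COLUMN: warn

dictionaries:
  donor:
    level: 1
    fields:
      - {name: donor_id, type: text, max_length: 12, required: true, key: primary}
      - {name: birth_date, type: date, required: true, pii: indirect,
         date_bounds: [1940-01-01, 2007-12-31],
         privacy: {transform: truncate-date-to-month, applied_at: import}}
      - {name: blood_group, type: code, max_length: 3, required: true,
         codes: [A+, A-, B+, B-, AB+, AB-, O+, O-]}
      - {name: sex, type: code, max_length: 1, codes: [M, F, O, U]}
      - {name: race, type: code, max_length: 1, codes: [W, B, A, N, P, M, O, U]}
      - {name: zip_code, type: text, max_length: 10, pii: indirect,
         privacy: {transform: truncate-zip-to-3, applied_at: import}}
  donation:
    level: 2
    fields:
      - {name: donation_id, type: text, max_length: 16, required: true, key: primary}
      - {name: donor_id, type: text, max_length: 12, required: true,
         key: foreign, references: [donor, donor_id]}
      - {name: visit_date, type: date, required: true,
         date_bounds: [2020-01-01, 2024-12-31]}
      - {name: donation_type, type: code, max_length: 3, required: true,
         codes: [WB, PLT, PLS, RBC]}
      - {name: donation_weight_g, type: integer, max_length: 5}
  test_result:
    level: 3
    fields:
      - {name: result_id, type: text, max_length: 20, required: true, key: primary}
      - {name: donation_id, type: text, max_length: 16, required: true,
         key: foreign, references: [donation, donation_id]}
      - {name: assay, type: code, max_length: 12, required: true,
         codes: [NC_TOTAL_IG, S_TOTAL_IG, S_IGG_QUANT]}
      - {name: result_value, type: decimal, max_length: 12}
      - {name: result_interpretation, type: code, max_length: 13,
         codes: [positive, negative, indeterminate]}

lookups:
  - name: race_group
    source: [donor, race]
    versions:
      1: {W: White, B: Black, A: Asian, N: AIAN, P: NHPI,
          M: Multiracial, O: Other, U: Unknown}
      2: {W: White, B: Black, A: Asian or Pacific Islander,
          P: Asian or Pacific Islander, N: AIAN, M: Multiracial,
          O: Other, U: Unknown}
  - name: donation_type_group
    source: [donation, donation_type]
    versions:
      1: {WB: Whole blood, PLT: Apheresis, PLS: Apheresis, RBC: Apheresis}

buckets:
  - org_id: O1
    root: buckets/O1
    expected_tables: [donor, donation, test_result]
    schedule: monthly
  - org_id: O2
    root: buckets/O2
    expected_tables: [donor, donation, test_result]
    schedule: monthly

reports:
  - name: donation_report
    source:
      - {table: donation,
         fields: [donation_id, donor_id, visit_date, donation_type]}
    transforms:
      - {op: lookup, lookup: donation_type_group, field: donation_type,
         target: donation_group}
      - {op: rename, field: visit_date, target: collection_date}
    target_schema:
      name: donation_report
      fields:
        - {name: donation_id, type: text, max_length: 16, required: true, key: primary}
        - {name: donor_id, type: text, max_length: 12, required: true}
        - {name: collection_date, type: date, required: true,
           date_bounds: [2020-01-01, 2024-12-31]}
        - {name: donation_type, type: code, max_length: 3, required: true,
           codes: [WB, PLT, PLS, RBC]}
        - {name: donation_group, type: code, max_length: 11, required: true,
           codes: [Whole blood, Apheresis]}
    destination: O1
  - name: testing_report
    source:
      - {table: test_result,
         fields: [result_id, donation_id, assay, result_value,
                  result_interpretation]}
    qc_hooks:
      - {require: result_value, when: result_interpretation, equals: positive}
    target_schema:
      name: testing_report
      fields:
        - {name: result_id, type: text, max_length: 20, required: true, key: primary}
        - {name: donation_id, type: text, max_length: 16, required: true}
        - {name: assay, type: code, max_length: 12, required: true,
           codes: [NC_TOTAL_IG, S_TOTAL_IG, S_IGG_QUANT]}
        - {name: result_value, type: decimal, max_length: 12}
        - {name: result_interpretation, type: code, max_length: 13,
           codes: [positive, negative, indeterminate]}

settings:
  transport: local
  credentials: {user: demo, key: opaque-demo-credential}
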