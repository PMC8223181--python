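# Default data-reporting-quality rubric: 45 indicators over four categories.
#
# Each leaf lists the integer values a scoring cell may take.  Category-wide
# cells (one cell spanning every report item) use the item key "ALL".
# Cells that are structurally inapplicable for every cohort member (dashes
# in the printed rubric) are listed under structural_na and carry no domain.
report_items: [confirmed, deaths, recovered, quarantine, icu]
categories:
  availability:
    total:
      confirmed: [0, 1]
      deaths: [0, 1]
      recovered: [0, 1]
      quarantine: [0, 1]
      icu: [0, 1]
    daily:
      confirmed: [0, 1]
      deaths: [0, 1]
      recovered: [0, 1]
      quarantine: [0, 1]
      icu: [0, 1]
    historical:
      confirmed: [0, 1]
      deaths: [0, 1]
      recovered: [0, 1]
      quarantine: [0, 1]
      icu: [0, 1]
  accessibility:
    ease_of_access:
      ALL: [0, 1]
    english:
      ALL: [0, 1]
    trend_total:
      confirmed: [0, 1]
      deaths: [0, 1]
      recovered: [0, 1]
      quarantine: [0, 1]
      icu: [0, 1]
    trend_daily:
      confirmed: [0, 1]
      deaths: [0, 1]
      recovered: [0, 1]
      quarantine: [0, 1]
      icu: [0, 1]
  granularity:
    age:
      confirmed: [0, 1]
      deaths: [0, 1]
      recovered: [0, 1]
      icu: [0, 1]
    gender:
      confirmed: [0, 1]
      deaths: [0, 1]
      recovered: [0, 1]
      icu: [0, 1]
    comorbidities:
      confirmed: [0, 1]
      deaths: [0, 1, 2]   # 2 = per-patient comorbidities reported on top of aggregate
      recovered: [0, 1]
      icu: [0, 1]
    districts:
      confirmed: [0, 1]
      deaths: [0, 1]
      recovered: [0, 1]
      quarantine: [0, 1]
      icu: [0, 1]
  privacy:
    privacy:
      ALL: [-1, 1]        # -1 = personally identifiable information released
structural_na:
  - [age, quarantine]
  - [gender, quarantine]
  - [comorbidities, quarantine]
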