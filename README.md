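# cdrs

Composite scoring of public-health **data-reporting quality**, built around
the COVID-19 Data Reporting Score (CDRS): a semi-quantitative, 45-indicator
rubric that grades how well an administrative region (a state or union
territory) reports outbreak data to its public.

The package is for epidemiologists and public-health analysts who want to
(a) score a cohort of regions against the rubric from curated scoring
sheets, (b) summarize and rank the cohort, (c) correlate reporting quality
with an external development index, and (d) test the whole pipeline on
synthetic cohorts with planted ground truth — no downloads required.

## The score

The rubric crosses **metrics** with five **report items** (confirmed,
deaths, recovered, quarantine, ICU) in four categories:

| category      | metrics                                             | cells |
|---------------|-----------------------------------------------------|------:|
| availability  | total, daily, historical × 5 items                  | 15    |
| accessibility | ease of access, English (category-wide); trend graphics total/daily × 5 | 12 |
| granularity   | age, gender, comorbidities × 4 items; districts × 5 | 17    |
| privacy       | one category-wide cell, domain {−1, 1}              | 1     |

Every cell holds an integer from its domain — {0,1} almost everywhere,
{0,1,2} for death comorbidity (2 = per-patient detail), {−1,1} for privacy
(−1 = personally identifiable information released). Cells inapplicable to
a region (district stratification for a district-less territory; privacy
for a region that reports nothing) are NA and drop out of every sum.

For state *s* and category *c*, with T the sum of scored values and M, m
the sums of domain maxima/minima over applicable cells:

```
N(c, s)  =  T(c, s) / (M(c, s) − m(c, s))          categorical score
CDRS(s)  =  Σ_c T(c, s) / Σ_c M(c, s)              overall score, in [0, 1]
```

so the privacy category contributes +0.5 without a violation and −0.5 with
one, a region reporting everything scores 1.0, and a silent region scores
0.0. Arithmetic is exact (integer sums, one rational division).

## Worked example

Generate a 29-region synthetic cohort with a planted development index
(population correlation 0.6 against the true scores), score it, summarize
it, and correlate:

```
$ cdrs simulate -n 29 --seed 7 --out-dir sim
wrote 29 synthetic sheets to sim (seed=7)
$ cdrs score sim/sheets.csv sim/meta.csv -o scores.csv --round2
wrote 29 state score(s) to scores.csv
$ cdrs summarize scores.csv
n = 29
five-number summary: min = 0.00, Q1 = 0.13, median = 0.30, Q3 = 0.39, max = 0.67
ranking (score descending, ties alphabetical):
  state15	0.67
  state07	0.65
  ...
$ cdrs correlate scores.csv sim/index.csv
n_pairs = 29
Pearson  r = 0.628, p = 0.0003
Spearman r = 0.600, p = 0.0006
```

The five-number line is the spread of overall scores across the cohort
(here strongly dispersed, as the generator plants quality tiers from
silent to good). The correlation block recovers the planted association
between reporting quality and the index: the estimate 0.628 sits within
sampling error of the planted 0.6, and the small p-values say a cohort of
29 is enough to detect an association of this size.

The same commands run on real curated data: `cdrs validate` checks sheets
against the rubric (exit 1 names the offending state and cell),
`cdrs score` accepts any cohort in the documented long-format CSV, and
`--framework my_rubric.yaml` swaps in an alternative rubric without code
changes.

As a library:

```python
from cdrs import default_framework, full_sheet, cdrs

spec = default_framework()                      # 45 indicators
perfect = full_sheet(spec, "best", lambda i: spec.domain(i).max)
print(cdrs(spec, perfect).cdrs)                 # 1.0
```

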