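# Methods

## Model

The score is a flat composite indicator: a rubric of cells, each an
integer from a finite domain, grouped into categories. No weighting is
applied between cells or categories — every point counts equally, and the
category structure matters only for the per-category normalized scores and
for the privacy applicability rule. The rubric is data (`FrameworkSpec`,
serialized as YAML), so the engine is generic over any rubric of the same
shape; the packaged default has 45 cells in four categories with summed
domain maxima 46 and minimum −1 (the privacy cell).

Category-wide metrics (ease of access, English availability, privacy) are
modeled as a single cell with the sentinel item `ALL`; this preserves the
45-cell count of the printed rubric. Structurally inapplicable pairs
(age/gender/comorbidity stratification of quarantine) are listed in the
schema without a domain, which makes them unrepresentable in sheets rather
than silently zero.

## NA adjustment

A cell that is NA for a particular state is excluded from the total T and
from the bounds M and m of both the categorical score N = T/(M−m) and the
overall score ΣT/ΣM. Two NA rules are *derived*, not trusted from input:

* **privacy** — inapplicable iff every non-privacy cell is 0 or NA (the
  state reports nothing). A sheet whose stored privacy value contradicts
  the derivation is scored by the derivation and flagged by
  `validate_cohort`; this keeps the rule testable and makes a negative
  overall score unreachable: any applicable privacy cell (worth ≥ −1)
  coexists with at least one reported cell (worth ≥ 1).
* **districts** — district-stratification cells should be NA for states
  whose metadata says they have no districts. This one is checked, not
  rewritten, because it depends on metadata rather than sheet content.

With these rules every valid sheet scores in [0, 1]; the engine does not
clamp, and a rubric that could genuinely go negative would surface as is.

Degenerate inputs: a sheet with no applicable cell at all has ΣM = 0 and
raises `UndefinedScoreError`; cohort scoring collects such states into a
failure report instead of aborting. A category with no applicable cell
(or with M = m) has normalized score NA, rendered as the literal `NA`.

Arithmetic is exact — integer sums and one `fractions.Fraction` division —
so equal sheets always produce bit-equal scores and ties in rankings are
genuine. Display rounding (2 decimals) is a rendering choice only.

## Cohort statistics

The five-number summary uses `numpy.quantile`; the quantile convention is
a visible parameter (default `linear`, i.e. linear interpolation between
order statistics) because quartiles of a 29-value sample differ between
conventions and the convention behind the reference cohort's printed
quartiles is not documented. Rankings sort by score descending with
alphabetical tie-break, making output deterministic. Reporting counts
tally states with a cell value ≥ 1 (NA and 0 excluded).

Correlation against an external index inner-joins on case-folded,
whitespace-normalized region names and requires ≥ 3 matched pairs.
Pearson's r and Spearman's rho (mid-ranks for ties) come from
`scipy.stats`, whose two-sided p-values match the t transform
r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom — adequate at cohort sizes
around 29; a seeded permutation p-value (`permutation_spearman_p`) is
available for smaller cohorts. The cross-check in the test suite evaluates
the product-moment formula and the t transform by hand, independent of the
scipy route.

## Inclusion filter

Cohort membership uses cumulative confirmed cases at a cutoff date with
threshold 10: regions with *fewer than* 10 cases are excluded, so a count
of exactly 10 is included. The filter is monotone in the threshold
(property-tested).

## Synthetic cohorts

The generator emulates the study conditions the framework was built for: a
cohort of 29 regions with strongly dispersed quality. Each region draws a
quality tier; within a tier each applicable non-privacy cell independently
reaches its domain maximum with the tier's reporting probability p (the
three-valued death-comorbidity cell draws 2 with probability p, else 1
with probability p, else 0). Defaults:

| parameter | default | why |
|---|---|---|
| `n_states` | 29 | reference cohort size |
| `tier_probs` | none 0.0, low 0.12, mid 0.30, high 0.55 | spans overall scores ≈ 0–0.6 with median ≈ 0.26–0.30 |
| `tier_weights` | 0.07 / 0.28 / 0.40 / 0.25 | ≈ 2 silent regions in 29; a weak majority; a good-but-imperfect top |
| `privacy_violation_rate` | 0.07 | ≈ 2 violations among 27 reporting regions |
| `no_districts_rate` | 0.07 | ≈ 2 district-less territories in 29 |

The base model is independent Bernoulli per cell within a tier; an
optional `dashboard_coupling` flag makes all trend-graphic cells one
all-or-nothing draw, mimicking dashboards that ship every trend plot at
once. What the generator does **not** emulate: correlation between
metrics beyond tiers, regional identities, temporal drift in reporting, or
curation disagreement between human scorers — so green recovery tests
show the pipeline's arithmetic and statistics are sound, not that the
rubric captures real reporting behaviour.

The planted index is `score + noise` rescaled to mean 55, s.d. 12 on the
0–100 scale and clipped. Noise is calibrated in closed form,
`sd_noise = sd_score · sqrt(1/r² − 1)`, which makes the population
correlation equal the target exactly (positive affine maps leave Pearson's
r unchanged; clipping at ±3.75 s.d. is negligible). At n = 1000 the
sampling s.d. of r near 0.6 is ≈ 0.02, so recovery tests assert ±0.05.

All randomness flows from one `numpy.random.default_rng(seed)`; identical
config and seed reproduce cohort, truth and index bit-for-bit.

## Problem sizes in the test suite

Property tests run on small random rubrics (≤ 3 categories × ≤ 3 metrics,
domains ⊆ {0,1,2,3} plus an optional privacy cell): 1000 engine-vs-oracle
pairs and 400 each for monotonicity and NA-neutrality, all from fixed
seeds. Random rubric domains are zero-based (0 = unreported) like the
real rubric; domains with positive minima would legitimately push the
categorical score above 1 and are out of the rubric family this package
models. Recovery tests use cohorts of 100–200 regions and index samples
of n = 1000.

## Known limitations

* Equal weights: the composite treats every cell alike; no sensitivity
  analysis over weightings is provided.
* The engine scores curated sheets; deciding what a region "reports" is
  human judgement outside the package.
* Correlation output is descriptive — no causal or regression modeling.
* The published per-state tables for the real cohort are archived
  externally; without them the suite exercises only synthetic and
  constructed cohorts (see the reproduction tests for the expected file
  layout).
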