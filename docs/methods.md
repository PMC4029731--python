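# Methods

## The analysis

The package reconstructs the diagnostic pathway of ALS patients from
longitudinal claims in which time is only resolved to the calendar
quarter of service.  All logic therefore runs on integer quarter
indices (Q1 2005 = 0 under the default epoch; Q4 2009 = 19); durations
are integer quarters converted to years (× 0.25) only when reported.
Age at a quarter is the calendar-year difference from birth year —
quarter granularity cannot resolve mid-year birthdays.

### Cohorts

A patient enters the **ALS cohort** when all of the following hold,
applied in order for the attrition funnel (the final membership is a
pure conjunction, so the order affects only the funnel counts):

1. the first claim carrying the index code (ICD-9-CM 335.20) falls in
   the diagnosis window (default Q1 2007–Q4 2009);
2. at least `min_als_claims` (default 2) index claims exist — counted
   as claim lines, not distinct quarters, and restricted to the
   diagnosis window by default (`count_claims_in_window_only=False`
   counts them anywhere);
3. age ≥ 65 years at the index quarter;
4. at least 8 whole quarters between enrollment start and the index
   quarter ("enrolled two years or more before diagnosis");
5. membership in the physician-office claims sample.

The quarter of the first index claim is the **diagnosis quarter** and
anchors every lookback window.  The **time-to-diagnosis subcohort**
further requires the diagnosis quarter to fall in a later window
(default Q1 2008–Q4 2009), guaranteeing at least 12 quarters of prior
claims to search for symptoms.  The **comparison cohort** contains every
patient with zero claims in the whole motor-neuron-disease family
(335.X, not just 335.20): a conservative exclusion that keeps possibly
prodromal patients out of the reference rates.

### The first-symptom rule

The symptom catalog assigns each diagnosis of interest a likelihood
tier and an onset category.  Scanning quarters in ascending order from
enrollment through the diagnosis quarter *inclusive* (a same-quarter
onset is a valid zero-lag call), a quarter triggers when it contains

* ≥ 1 diagnosis code classified **high** likelihood, or
* codes for ≥ 2 **distinct** moderate-likelihood diagnoses of interest
  (distinct labels — a repeated single moderate code never triggers,
  and two codes falling under the same family, e.g. 728.3 and 728.71
  under 728.X, count as one diagnosis).

Neither rule takes precedence; the onset category is read from the
union of every definition matched in the triggering quarter (all limb →
limb, all bulbar → bulbar, mixed → both).  Because the moderate 728.X
family overlaps three high-likelihood codes, a code like 728.87 matches
both tiers; this is intentional and category-consistent.  Only the
bulbar/limb tier table participates in onset detection; the
nerve/respiratory/other analysis groups are descriptive.

ICD-9-CM matching: codes are compared as dotted uppercase strings
(undotted inputs get the dot re-inserted after the third character,
fourth for E-codes).  A trailing `X` wildcard matches any completion of
its prefix, covering fourth- and fifth-digit expansions; a family
pattern like `359.X` also covers the bare three-digit root `359`,
which billing extracts occasionally emit.

### Prevalence rate ratios

For each symptom group, the pre-diagnosis prevalence is the percent of
ALS-cohort patients with ≥ 1 matching claim in the 8 quarters before —
and excluding — the diagnosis quarter; the comparison prevalence uses a
fixed calendar window (default Q1 2008–Q4 2009, the same 8-quarter
span) with no per-patient anchoring.  The ratio is computed on
**unrounded** percentages and rounded half-up to one decimal only for
display: published tables of this kind divide unrounded values, so
integer-rounded inputs cannot reproduce every printed ratio.  Degenerate
inputs are flagged rather than raised (positive/0 → an infinite
sentinel; 0/0 → 0).  The reporting filter keeps rows with prevalence
≥ 10% or ratio ≥ 5 (both bounds inclusive) and sorts stably by
descending ratio.  No confidence intervals or hypothesis tests are
attached, by design.

### Lags and test utilization

A symptom's lag is the diagnosis quarter minus the first quarter with a
matching code (at or before diagnosis), independent of the onset rule —
a lone moderate code defines its own symptom's lag even though it
cannot trigger onset.  Lags are binned 0–3 / 4–7 / 8–11 / 12+, which
partition the nonnegative integers.  Test utilization counts each
patient once per procedure group in the 8 quarters before (excluding)
diagnosis; the median time to diagnosis among tested patients is
anchored on the onset call (the convention of the symptom tables, since
the published column header states no anchor).  Subgroup medians with
fewer than `nd_threshold` contributors (default 11) are suppressed as
"not determined"; the source tables do not state their suppression
rule, so the threshold is configurable.

Medians everywhere use midpoint interpolation for even counts, which is
why a median of quarter-multiples can be a non-multiple such as 2.88
(the midpoint of 2.75 and 3.0, displayed at two decimals).

## The synthetic generator

`simulate.SimulationConfig` defaults encode the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_als`, `n_background` | 300 / 3000 | population sizes, chosen near the source cohort scale (272–399 ALS patients) with a 10× comparison pool |
| `onset_mix` | 0.74 / 0.17 / 0.08 | limb/bulbar/both probabilities (renormalized; the published mix sums to 99%) |
| `lead_time_mean_quarters` | limb 10, bulbar 5, both 1 | mean of the geometric onset-to-diagnosis lead time, reflecting the published ordering (limb delays ≈ 2× bulbar; concurrent onset ≈ 1 quarter); only medians are published, so the distribution family is a modelling choice (`fixed` is available) |
| `moderate_pair_fraction` | 0.2 | fraction of limb onsets planted as a distinct moderate pair (719.4 + 729.5) instead of one high code, so the two-moderate rule is exercised in-pipeline |
| `background_rates_pct` | reference-population column of the prevalence tables | 8-quarter period prevalence per symptom group ("< 1" entries taken as 0.5) |
| `als_symptom_rates_pct` | ALS column of the prevalence tables | pre-diagnosis period prevalence planted in the 8-quarter lookback |
| `test_probabilities` | published utilization by onset type | per-test Bernoulli draws in the lookback window ("both" patients treated as limb except for the predominantly bulbar throat/upper-GI exam) |
| `diagnosis_window` | Q1 2008–Q4 2009 | planted index quarters (uniform), so every simulated ALS patient qualifies for the time-to-diagnosis subcohort |

Period prevalences are converted to per-quarter Bernoulli rates by
`r = 1 − (1 − p)^(1/8)` so the planted period prevalence matches the
target in expectation.  Lead times are truncated at enrollment
(onset = max(enrollment, diagnosis − lead)); ground truth records the
truncated value, so recovery checks compare against what was actually
planted.

**Onset identifiability.**  By default, background symptom codes are
planted in ALS patients only for groups whose code families do not
intersect the onset rule table (the nerve/respiratory/other groups).
Otherwise background limb/bulbar codes would fire the rule before the
planted onset and the planted lead time would not be the quantity the
pipeline is asked to recover.  Setting
`inject_onset_groups_in_als=True` lifts the restriction; a dedicated
test demonstrates that this knob produces earlier-than-planted (never
later) onset calls, i.e. genuine false-trigger pressure on the rule's
specificity.

**What the generator does not emulate:** billing idiosyncrasies
(revenue centers, adjudication), mortality, enrollment churn,
correlations between symptom groups, secular trends, and
miscoding/rule-out diagnoses.  Passing recovery tests therefore show
that the pipeline inverts its own generative assumptions at the study's
scale — not that the rule set is clinically valid on real claims.

## Numerical and design choices

* Display rounding is decimal half-up (ratios to 1 decimal,
  percentages to integers, medians to 2 decimals); all computation is
  on unrounded floats.
* Symptom groups whose codes the tier table does not print (e.g.
  cervicalgia, lumbago/backache) are given standard ICD-9-CM families
  chosen by this package; they are package defaults, not published
  code lists, and can be replaced via a user catalog YAML.
* Diagnostic-test groups are keyed by opaque procedure-group
  identifiers rather than licensed CPT/HCPCS codes; the analysis needs
  only group membership.
* Onset proportions are reported over both denominators — classified
  patients and the whole cohort — since published percentages summing
  to 99% leave the denominator ambiguous.
* The throat-pain row of the tier table carries no explicit tier cell
  in the source layout; it is encoded high/bulbar following the
  table's structure.
* Cohort criteria count index *claim lines*, not distinct quarters;
  the alternative (distinct quarters) is one predicate away if needed.

## Problem sizes

The test suite and the acceptance script run the full pipeline at
300 ALS / 3000 comparison patients — the scale at which the recovery
tolerances (3 standard errors for proportions, ± 1 quarter for planted
medians) are meaningful — and check the onset rule against a
brute-force per-quarter oracle on 1000 random histories.  A suite run
completes in a few seconds.

## Limitations

* Quarter granularity floors every duration; a true delay of 2.4 years
  is observed as 9 or 10 quarters depending on calendar alignment.
* The headline counts of the source cohort (399/272 patients, the
  printed prevalence tables) derive from restricted data and are not
  reproducible here; the package reproduces the *method* and the
  arithmetic of the published ratios, and validates the machinery by
  parameter recovery on synthetic data.
* The rule table is era-specific (ICD-9-CM); ICD-10 mapping is out of
  scope.
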