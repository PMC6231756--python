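# Methods

## Model and procedure

The pipeline estimates, for each calendar year and each collapsed
rural–urban stratum, the ratio of two proportions:

- **numerator** p₁ — the share of an intervention's geographically
  classified registrants in the stratum that year (a binomial proportion
  with sample size n₁ = the number of registrants who provided a valid,
  crosswalk-resolvable ZIP);
- **denominator** p₂ — the share of the eligible reference population in
  the stratum, taken from survey-estimated counts (e.g. NSDUH smokers in
  thousands).

The reach ratio ReRa = p₁/p₂ is 1 under proportional representation.
Inference is on the log scale.  The default **fixed-reference** interval

exp( ln(p₁/p₂) ± z·√((1−p₁)/(n₁p₁)) )

treats p₂ as a known constant: the reference estimate comes from a
survey of tens of millions of people, so its sampling variance is
negligible next to the cohort's (and survey design effects are out of
scope).  The **two-sample** Katz interval, adding (1−p₂)/(n₂p₂) under
the root, is available through `AnalysisConfig(interval_variant=
"two_sample")`; it is always at least as wide and converges to the
fixed-reference interval as n₂ → ∞.  Significance is the CI-exclusion
rule on the *unrounded* interval, not a p-value.

Assumptions worth stating: classified registrants are an unbiased sample
of all registrants with respect to geography (ZIP provision may depend
on age and gender — both are audited — but must not depend on stratum;
the synthetic-data tests demonstrate the bias when it does); each
stratum count is binomial within a year; years are analyzed
independently, which over-states the error of cross-year comparisons.

## Geographic classification

Raw postal codes are normalized (whitespace stripped, ZIP+4 truncated,
leading zeros preserved; four-digit entries are rejected as ambiguous
rather than zero-padded) and resolved ZIP → ZCTA → county → RUCC
(2013 vintage by default; the vintage is a config label on the
crosswalk).  ZCTAs that straddle counties are resolved to the county
with the largest population-overlap weight, ties broken by smallest
FIPS, so classification is deterministic and byte-reproducible.  RUCC
1 / 2–3 / 4–9 collapse to Large Metro / Small Metro / Nonmetro.  Any
failure (empty, malformed, unmapped) yields UNCLASSIFIED — tallied in
the classification report, excluded from p₁ and n₁.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | two-sided level of the CI |
| `z` | 1.959964 | critical value; 1.96 gives identical two-decimal output |
| `rounding` | 2 | reporting decimals (round-half-even) |
| `interval_variant` | `fixed_reference` | see above |

## Synthetic-data generator

`SimulationScenario` defaults encode the study conditions of a
2013–2017 US web-based cessation cohort: per-year stratum probabilities
equal to the published cohort panel, reference counts equal to the
reconstructed NSDUH counts (below), classified totals 33,484 / 18,255 /
5,491 / 1,820 / 8,832, and registered cohort sizes equal to those totals
divided by the overall valid-ZIP share 0.5334 (per-year registration
totals are not published).  ZIP provision is Bernoulli with probability
clamp(0.5334 · 1.03^((age−40)/10) · 1.10^[female]), anchored at a
40-year-old man, so the published age and gender relative risks are
directly recoverable from the generated data.  Ages are truncated normal
(mean 40, sd 13, range 18–80) and the gender mix is 50/50 — neither is
published; only the RRs matter for the tests.  Age and gender are
independently blanked at the published optional-field rates (22.78%,
23.39%); a blank covariate contributes a neutral multiplier.  All
generators are pure functions of (scenario, seed), using named PCG64
substreams per component and year so adding a generator never perturbs
another's draws.

The generator emulates the *statistical* structure the analysis assumes
— multinomial strata, weighted many-to-many crosswalk links, covariate-
dependent missingness — and not real US geography (ZIP/county shapes,
populations) or smoking prevalence itself.  Passing recovery tests
therefore show the pipeline is consistent under its own assumptions;
they cannot show that real ZIP provision is independent of geography,
which is exactly the informative-missingness bias one test demonstrates
(the induced bias equals the selection ratio m_c / Σ q m).

## Numerical choices

- Reported values use round-half-even, which matches every published
  two-decimal cell that is reproducible at all.
- Intervals are undefined for p₁ ∈ {0, 1} (log-scale SE degenerates) —
  a typed error, not a clamp.
- A year with no classified records is a typed error; an empty cohort
  report defines the valid-ZIP fraction as 0.
- Stratum tables built from published *percentages* tolerate a summation
  slack of 1e-3 (two published cohort panels sum to 99.99%); tables
  built from counts are exact.
- Problem sizes in the stochastic tests — 5,000 replicates for interval
  coverage, 100,000 records/year for end-to-end recovery, 100,000
  bootstrap replicates, 500 replicates for missingness bias — were
  chosen so each check resolves its tolerance with seconds of
  computation.

## Reconstructed reference counts

Only the yearly smoker totals and one cell (2016 Large Metro, 25,259
thousand) are published as counts; the rest of
`examples/us_smokers_2013_2017.csv` consists of integers solved so each
year's three categories sum exactly to the published total and each
proportion rounds to the published two-decimal percentage.  They are a
faithful reconstruction for pipeline input, not NSDUH microdata.

## Known limitations and discrepancies

- **Five CI endpoints do not reproduce.**  From the published
  two-decimal proportions and yearly totals, the fixed-reference
  interval reproduces all 15 reach-ratio point estimates and 25 of 30 CI
  endpoints; Large Metro 2014 and 2015 lower bounds, Small Metro 2013
  upper, and both Small Metro 2014 bounds differ by 0.01.  No single
  closed form reproduces all 30: the two-sample variant (with reference
  counts in thousands) fixes those five but breaks three others.
  Interval arithmetic over the input-rounding range shows the Small
  Metro 2013/2014 cells are unreachable under the fixed-reference
  formula from *any* inputs consistent with the published table, so the
  original computation presumably used unpublished raw counts and, for
  some cells, a different variance treatment.  The corresponding test
  cases are left failing rather than loosened.
- The published table marks Small Metro 2015, "1.00 (0.96–1.04)", as
  significantly different from 1; the CI-exclusion rule says otherwise
  and this package follows the rule.  Conversely Large Metro 2013's
  unrounded interval (1.0039–1.0261) excludes 1 and is flagged
  significant here though unmarked in the publication.
- The published sample accounting is internally inconsistent
  (59,050/118,574 in one place, 67,854/127,207 in another, per-year
  totals summing to 67,882); the package reproduces each ratio as
  arithmetic and does not adjudicate a single cohort denominator.
- NSDUH survey weighting and design-based variance, and multinomial
  cross-year trend analysis, are out of scope.
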