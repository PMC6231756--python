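# Example data: 2013–2017 US web-based cessation cohort vs NSDUH smokers

These tiny CSVs carry the published summary tables of a five-year
reach-equity study of a free web-based smoking-cessation program,
stratified by the collapsed Rural-Urban Continuum Code scheme
(Large Metro = RUCC 1, Small Metro = RUCC 2–3, Nonmetro = RUCC 4–9).

- `cohort_strata_2013_2017.csv` — per-year stratum percentages among
  geographically classified program registrants.
- `cohort_totals_2013_2017.csv` — per-year counts of registrants with a
  valid, RUCC-assigned ZIP code (the `n1` for the confidence intervals).
- `reference_strata_2013_2017.csv` — per-year stratum percentages among
  US smokers aged 12+, from NSDUH detailed tables.
- `us_smokers_2013_2017.csv` — NSDUH smoker counts in thousands per
  stratum.  Only the 2016 Large Metro count (25,259) and the yearly
  totals are published; the remaining cells are *reconstructed* integers
  solved so each year sums to the published total and every proportion
  rounds to the published two-decimal percentage.

`scripts/acceptance.py` and the test suite feed these tables through the
pipeline to re-derive the study's reach ratios and confidence intervals.
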