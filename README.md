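# intusepi

Epidemiology of childhood intussusception from administrative inpatient
claims data: case ascertainment with the Brighton Collaboration level-1
(definite) diagnostic-certainty criteria, a hospital-volume-stratified
scale-up estimator of the national annual case burden with Wald confidence
intervals, birth-cohort incidence, and the standard descriptive tables
(age-specific admission rates, pathological lead points, treatment
outcomes, complications, case fatality with exact binomial intervals).

The package is aimed at epidemiologists working with partial-coverage
national discharge databases — registries that cover a known fraction of
acute-care beds but an unknown, possibly biased, share of patients. It
ships the published desk-scale inputs of a two-year Japanese inpatient
survey so every headline number recomputes without access to the original
database, and a seeded synthetic claims-data generator so the full
record-level pipeline is testable end to end.

## The estimator

Admissions are screened for ICD-10 code K56.1 at age ≤ 18 years and
restricted to definite (level-1) intussusception: surgical, radiological or
autopsy confirmation. Same-hospital readmissions within a week are tagged
but kept as independent events.

Hospitals are stratified by bed volume (<400, 400–<600, 600–<800, ≥800
beds). Within stratum *i*, with *X_i* cases observed in participating
hospitals during a six-month collection window, *n_i* participating beds
and *N_i* national beds, the annualized per-bed case proportion is
*p_i = 2X_i / n_i* (the factor 2 annualizes the half-year count under a
no-seasonality assumption), and the national annual estimate is

    Y_i = p_i · N_i ,   95% CI:  N_i · ( p_i ± 1.96 · √( p_i (1 − p_i) / n_i ) )

The national total is the sum over strata; dividing by the annual birth
cohort (default 1,090,000) gives incidence per 100,000 infants. Case
proportions (e.g. case fatality) get Clopper–Pearson exact binomial
intervals.

## Worked example

Run the estimator on the shipped 2007 and 2008 stratum tables:

```
$ intusepi estimate --year 2007 --out out07
National annual cases: 1957 (95% CI 1700-2216); incidence 179.5 per 100,000 infants (CI 156.0-203.3)

$ intusepi estimate --year 2008 --out out08
National annual cases: 2081 (95% CI 1802-2361); incidence 190.9 per 100,000 infants (CI 165.3-216.6)
```

So from roughly 450 confirmed infant cases observed per half-year in
hospitals holding ~37% of national beds, the method projects about
1,960–2,080 infantile intussusception cases per year nationwide — an
incidence near 180–191 per 100,000 infants. `out07/estimates.csv` holds
the per-stratum estimates (e.g. stratum 1: 701, CI 597–806) both unrounded
and report-rounded.

The same machinery runs on synthetic record-level data:

```
$ intusepi all --seed 1 --out run1
National annual cases: 238 (95% CI 163-316); incidence 21.8 per 100,000 infants (CI 15.0-29.0)
Cases: 136; male 58.8%; enema success 94.1%; secondary 2.9%; deaths 0
```

Here the registry is a 1:10-scale synthetic database (so the case total is
correspondingly small and the incidence is not meaningful against the
full-size birth denominator); the run demonstrates simulate → screen →
estimate → describe on files only. The library API mirrors the CLI:
`generate_hospitals` / `generate_admissions`, `screen_cases` /
`tag_readmissions`, `tabulate_strata` / `estimate_stratum` /
`aggregate_national` / `exact_binomial_ci`, and `summarize_cases` /
`age_rate_table` / `tabulate_lead_points`.

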