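# Methods

## Problem and data model

Intussusception — the telescoping of one bowel segment into another — is
the leading cause of intestinal obstruction in infants, and its background
incidence is the reference against which rotavirus-vaccine safety signals
are judged. National discharge databases are a natural surveillance
source, but two features complicate naive counting: (1) administrative
coding overstates true cases, so a diagnostic-certainty filter is needed,
and (2) the database covers only part of the country's admissions, so
in-database counts must be scaled up to a national figure.

The package models the data as two flat tables. A *hospital registry* row
is one acute-care hospital: an opaque id, a licensed bed count, and a flag
for database participation. An *admission record* is one inpatient
episode: patient pseudo-id, hospital, age in months, sex, admission and
discharge dates, ICD-10 diagnosis codes, the basis for diagnostic
certainty (surgical / radiological / autopsy / none), treatment
(enema success, surgery, surgery with bowel resection), an optional
lead-point label, an optional complication category, and a death flag.

## Case ascertainment

Screening keeps records that carry a diagnosis code with prefix K561
(codes are normalized by dot-stripping, so "K56.1" and "K561" match), are
at most 18 completed years old at admission (18-year-olds inclusive), and
have level-1 diagnostic certainty. Everything else coded as
intussusception is excluded; Brighton levels 2–4 cannot be evaluated in
claims data lacking signs and symptoms, and are deliberately out of scope.

Readmissions to the same hospital are analytically *independent events*:
nothing is merged or dropped. A row is tagged as a readmission iff the
same patient has an earlier case discharge at the same hospital with a
discharge-to-admission gap of 0–7 whole days (the window is a parameter;
"within a week" is ambiguous between admission- and discharge-anchored
gaps, and the discharge-anchored reading is adopted).

## The stratified scale-up estimator

Patients may be referred differentially to database hospitals, so a single
national expansion factor is biased. The working assumption is that
patients distribute evenly among hospitals of similar size; hospitals are
therefore stratified by bed volume — <400, 400–<600, 600–<800, ≥800 beds —
and beds, not hospitals, are the sampling frame. The published stratum
labels leave exactly 800 beds unassigned ("600 – <800" vs ">800"); the
half-open convention [800, ∞) is adopted.

For stratum *i* with X_i observed cases in n_i participating beds over a
six-month window and N_i national beds:

    p_i = a · X_i / n_i          (annualization a = 2 by default)
    Y_i = p_i · N_i
    CI_i = N_i · ( p_i ± z · √( p_i (1 − p_i) / n_i ) ),  z = 1.96

Numerical conventions, chosen for bit-stable fidelity to the published
computation:

- p_i is an annualized cases-per-bed proportion. Dimensionally unusual,
  but it is the quantity the method defines; the annualization factor is a
  parameter so other collection windows are supported.
- No finite-population correction is applied to the Wald variance even
  though n_i/N_i is large; the plain binomial variance is part of the
  method being implemented.
- z is the literal constant 1.96, not a recomputed normal quantile.
- Wald bounds are clamped to [0, N_i] (they can go negative at small p);
  X_i = 0 yields the degenerate interval (0, 0).
- p_i > 1 raises an error: more annualized cases than beds means the
  inputs are implausible.

Reporting ledger: per-stratum values are rounded half-up; the national
total is the truncation toward zero of the *unrounded* stratum sum (this
reproduces both published totals, whose unrounded sums are 1957.60 and
2081.85); the national CI bounds are the sums of the rounded per-stratum
bounds. Incidence per 100,000 infants divides by an annual-birth constant
(default 1,090,000; a configuration value, not derived from data), and is
returned unrounded — integer reporting is the caller's choice.

The scale-up targets *infantile* incidence: in the record-level pipeline
only cases under 12 months enter the stratum counts, which matches the
published stratum inputs (the two years' X_i sum to 872, exactly the
published age-0 case count) and the birth-cohort denominator.

Known irreproducibles in the published table, asserted as such and not
targeted: the 2007 total lower bound (printed 1743; the stratum lower
bounds sum to 1700 under every rounding scheme tried), the 2007 incidence
CI that depends on it, one stratum estimate printed as a truncation
(278.72 → 278) where all others are rounded, the lead-point table header
(N = 77 over a column summing to 76), and an enema-success figure printed
as 93.0% whose printed ratio 2255/2427 gives 92.9%. Tests assert the
ratios, not the misprints.

## Exact binomial intervals

Case proportions (notably case fatality, 2/2427) are given
Clopper–Pearson intervals — the inversion of the binomial tail
probabilities, computed via the beta quantile
(`statsmodels.stats.proportion.proportion_confint(method="beta")`). The
interval's coverage is ≥ the nominal level for every true proportion;
the suite verifies this exhaustively for all n ≤ 50 over a grid of p, and
checks the implementation against an independent brute-force root-finder
on the binomial CDF.

## Descriptive statistics

Age-specific rates are cases per 1,000 all-cause admissions within age
bins in completed years (0, 1, 2, 3–4, 5–12, 13–18; "3–4" means
3 ≤ age < 5). Percentages and rates are reported half-up at one decimal
(configurable, because the published rounding is demonstrably
inconsistent); medians and IQRs use linear interpolation. An empty case
series yields explicit `None` sentinels for medians and the fatality
interval, never silent zeros. Lead points are grouped under Structural,
Vascular/hematological, Neoplasms and Others using the standard
vocabulary shipped with the package; unknown labels are retained under
"Unclassified" with a warning.

## Synthetic claims-database generator

The generator emulates the study conditions so the whole pipeline is
testable without the (non-public) source database: a national registry of
acute-care hospitals whose volume-class frequencies follow the national
census (7,001 / 466 / 161 / 95 hospitals per class, applied as mixture
weights), with the <400-bed class split into a small-hospital bulk and a
mid-size component so the registry-wide mean matches the national ~118
beds per hospital; a participation flag filled greedily within each
volume class until the class's participating-bed share reaches the
coverage fraction (default 0.45, the database's admission coverage);
and admission records for participating hospitals only.

Case counts per hospital are Poisson with mean beds × rate × days — the
simplest count model consistent with the even-distribution assumption —
with the per-bed daily case rate defaulting to 1.9 × 10⁻⁵ (the observed
in-database half-year case count per participating bed). Admission dates
are uniform over the July 1 – December 31 window, since no within-year
date distribution is published; discharge dates are clipped to the window.
All-cause background admissions use the same Poisson form at 4.8 × 10⁻³
per bed-day, with ages drawn from the published all-cause age-bin margins.

Case marginals default to the published ratios: male 1610/2427, enema
success 2255/2427, resection 52/175 of surgical, lead-point probability by
age bin (1.6/1.2/2.9/2.3/14.9/37.1%), complications 27/2427, deaths
2/2427, same-hospital readmissions 37/2427 with gap 1 + Poisson(1.3) days
(mean ≈ 2.3, capped at the 7-day window). Ages of cases follow a mixture:
92.5% of mass is a shifted gamma in months (shape 2, scale 7.5, shift 2,
truncated below 60 months), the rest uniform to 18 years. The shifted
gamma has mode ≈ 9.5 months, ~36% of cases under 12 months, under 1% below
3 months, and median ≈ 15.5 months — the published median is 17 months; no
two-parameter family meets the mode, infant-share and median constraints
simultaneously, and mode and infant share were preferred since they drive
the estimator. Length of stay is 1 + Poisson(2.5) days non-surgical and
1 + Poisson(7.3) surgical (medians 3 and 8).

Default registry size is 772 hospitals — a 1:10 scale of the 7,723-strong
national registry, keeping default runs fast while preserving stratum
structure; full scale is one configuration value away. One global integer
seed drives named sub-streams (hospitals / cases / background) via
`numpy.random.SeedSequence(entropy=seed, spawn_key=(stream,))`, so
regenerating one table never perturbs another and equal seeds give
byte-identical CSVs.

What the generator does *not* model — and hence what passing tests do not
show about real data: seasonality (dates are uniform; the source data
cannot assess it either), clinical signs and symptoms (absent from claims
data), referral bias between participating and non-participating hospitals
of the same size (the estimator's working assumption is built into the
generator, so the simulation cannot detect its violation), correlation
between lead-point type and age beyond the bin-level secondary
probabilities, and any dependence of coding accuracy on hospital type.

## Pipeline and reproducibility

The CLI stages (`simulate | screen | estimate | describe | all`)
communicate only via CSV files; summary files are written atomically
(temp-then-rename), and each stage writes a JSON manifest with the
package version, seed, configuration hash and input digests. The
record-level path and the published-table path share the same estimator
code, so running `estimate --year 2007|2008` on the shipped stratum
tables reproduces the published national figures exactly.

The parameter-recovery check generates registries of 300 hospitals with
background admissions and readmissions disabled and all cases at level-1
certainty, runs screen → tabulate → estimate over 100 seeds, and requires
the national 95% CI to cover the annualized truth (2 × rate × days ×
national beds) in at least 90 replicates; the estimator-vs-oracle check
compares against a rational-arithmetic transcription of the formula on
1,000 random small inputs at 10⁻⁹ relative tolerance. Problem sizes
throughout the suite are desk-scale by design: the published inputs are
four-stratum tables and the synthetic checks need only a few hundred
hospitals per replicate to exercise every code path.
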