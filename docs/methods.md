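# Methods

## Setting and data model

The pipeline analyses formally documented transfers of adolescents (10 to
<20 years at transfer) on ART, where all public-sector facilities in a
jurisdiction share one patient identifier, so that visits, laboratory tests
and pharmacy dispensings after the transfer can be linked back to the
patient. Three delimited tables are the interface: a cohort table (one row
per transferred patient, with enrolment/ART-start/transfer-out dates, ages,
origin facility and care level, and at-transfer HIV-RNA/CD4), an event
table (identifier, facility, date, source ∈ {visit, lab, pharmacy},
optional analyte and value), and an alias→canonical duplicate map for
patients issued more than one identifier. Admissions are represented as
visits; the analysis never distinguishes them.

All dates are day-resolution calendar dates and all arithmetic is in
integer days; ages derived from dates use 365.25 days/year. Conversions are
fixed as 6 months = 183 days, 18 months = 548 days, 1 analysis year = 365
days. These conventions are config fields, not hard-coded.

## Duplicate resolution

The duplicate map is resolved transitively (C→B, B→A collapses to C→A,
B→A) with cycle detection; resolution rewrites only the identifier field,
preserves the event multiset, and is idempotent. This is deterministic
linkage on the shared identifier — no probabilistic matching on names or
demographics is attempted.

## Transfer classification

A patient transfers successfully if any event in the active source subset
occurs at a facility other than the origin facility *strictly after* the
transfer-out date. Same-day records elsewhere are treated as pre-transfer
administrative contacts and do not qualify; a toggle
(`same_day_qualifies`) flips this reading. The linkage event is the
earliest qualifying record, with date ties broken by source (visit < lab <
pharmacy) then facility name, making classification order-insensitive.
Two delays are derived: from the transfer-out date, and from the last
captured contact at the origin facility on or before transfer-out (falling
back to the transfer-out date when the active subset captured no origin
contact — which also makes the two definitions coincide in that case).
A patient with no events is an ordinary failure, not an error: transfers
out of the jurisdiction are indistinguishable from failed linkage, and the
success proportion is accordingly a lower bound.

## Windowed outcomes

Year-t outcomes (t = 1, 2, 3) anchor on the *successful-transfer date*, not
the transfer-out date, and are assessed only in patients with at least
t + 0.5 years between that date and database closure (default closure
2016-10-15), so denominators shrink with the horizon. Retention is ≥1
visit-stream event in the closed window [anniversary − 183, anniversary +
183]; visits back at the origin facility do not count by default
(`retention_includes_origin` reverses this, an intentionally exposed open
reading). Laboratory values at year t are the single measurement closest to
the anniversary within the same window, with equidistant ties resolved to
the earlier date (favouring the value nearer the previous year's state).
Flags: suppression is HIV-RNA < 400 copies/ml; CD4 recovery is strictly
> 500 cells/µl (descriptive tables sometimes print ≥500;
`cd4_threshold_inclusive` switches the convention). Patients retained at
year 3 without an in-window HIV-RNA are categorized, in priority order:
suppressed measurement shortly after the window (within 183 days of window
end, config-exposed); previously continuously suppressed (≥1 prior
post-transfer HIV-RNA, all <400); later unsuppressed; no evidence.

The perinatal-infection proxy is enrolment in HIV care before 13 years
(alternative cutoff 10 via config); the age split at transfer is 10–14
vs 15–19 years.

## Statistics

* Binomial proportions: exact Clopper–Pearson 95% intervals
  (beta-quantile inversion via statsmodels); the normal approximation does
  not reproduce published lower bounds at these sample sizes.
* Paired suppression comparisons (at transfer vs year t, both measured):
  exact McNemar — two-sided binomial with p = ½ on the discordant counts.
* Paired CD4 comparisons: Wilcoxon signed-rank, exact for ≤25 non-zero
  untied differences, otherwise normal approximation with Pratt handling of
  zeros.
* Age-group contrasts: Pearson chi-square on the 2×2 table without
  continuity correction; degenerate margins return statistic 0, p = 1.
* Predictors of successful transfer: maximum-likelihood logistic
  regression with the five a-priori covariates (perinatal proxy, sex, age
  band at transfer, suppression at transfer, origin care level),
  complete-case on at-transfer HIV-RNA (the only covariate with
  missingness), Wald 95% CIs. The age term defaults to the binary 15–19 vs
  10–14 contrast; a per-year continuous coding is available because a
  binary contrast with an implausibly tight CI in routine outputs usually
  indicates the continuous coding was used. Quasi-separation is detected
  (divergent coefficient or standard error after a BFGS refit) and flagged
  per covariate rather than silently reported.
* Display rounding is half-away-from-zero, one decimal in tables; every
  reported percentage carries its numerator and denominator so it is
  recomputable.

Figure-style yearly outputs emit virologic/immunologic percentages against
both candidate denominators — patients assessed (with an in-window
measurement) and all retained patients — since either reading is defensible;
the assessed denominator is the primary one.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes rather than any
real facility network. Per patient: sex (P(female) = 0.533), transfer age
band (P(10–14) = 0.722), origin level (P(tertiary) = 0.793), transfer-out
date uniform over 2004-03-01..2014-12-31; ART/enrolment history drawn to
give plausible ages and durations. A patient is out-of-scope (e.g.
out-of-province transfer) with probability 0.05 and then emits no
post-transfer events; otherwise transfer succeeds with probability 0.85.
Successful transfers link after a log-normal delay with median 56 days and
σ = ln(134/27)/(2·0.6745) ≈ 1.19 (matching the skewed 27–134 IQR around
56), then attend a destination clinic at semi-regular ~84-day intervals
until an exponential dropout (hazard 0.05/year) or closure. Yearly HIV-RNA
(CD4) is measured with probability 0.89/0.85/0.80 (0.87/0.80/0.72) at years
1/2/3, suppressed with probability 0.80 — i.i.d. per measurement by
default; a first-order Markov option (persistence 0.9) exists because
within-patient correlation is plausible but unquantified. Each true contact
is captured in the visit/lab/pharmacy streams with probability
0.95/0.85/0.55; pharmacy events occur only on visit dates. With probability
0.02 a patient's post-transfer events are recorded under a second
identifier, exercising duplicate resolution. Attrition hazard and visit
frequency are not published quantities; the defaults are chosen to give
retention on the scale of routine programmes (~90% early) and are
config-exposed, not claims.

Two deliberate generator properties:

* every latent-success patient is guaranteed ≥1 captured post-transfer
  event (the linkage visit is force-captured in the vanishingly rare case
  all streams miss every contact), so the classifier's observed success
  equals latent truth exactly and parameter-recovery tests are exact rather
  than almost-sure;
* identical (config, seed) yield byte-identical output files.

What the generator does **not** emulate: facility geography, regimen or
resistance dynamics, mortality, silent transfers, re-engagement after gaps,
and correlation between covariates and success (the logistic-model tests
therefore simulate covariate effects directly). Passing tests demonstrate
the pipeline's correctness and internal consistency on data with this
structure — not the field accuracy of any specific published estimate.

## Problem sizes and numerics

Parameter-recovery and acceptance runs use 5000-patient cohorts (binomial
SE on the success proportion ≈ 0.56 percentage points), oracle-equivalence
checks use ≥1000 random small event sets against exhaustive brute-force
scans, and logistic coverage checks use 100 replicates of n = 1500 with
direct covariate simulation; these sizes make Monte-Carlo error small
relative to the 3-standard-error test bands. All window boundaries are
closed; all classifier scans are deterministic given the sort order
(date, source rank, facility). Empty cohorts, empty event streams, zero
discordant pairs, all-zero difference vectors and degenerate 2×2 margins
are defined cases, not errors.

## Known limitations

Out-of-jurisdiction transfers and mortality are unobservable, so "failed
transfer" conflates them with true disengagement; the delay observed from
captured streams is an upper bound on the true linkage delay; the
destination facility recorded is wherever the first captured record
appears, which under partial coverage need not be the true first site;
and no intended-destination concordance is assessed (the intended site is
not part of the data model).
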