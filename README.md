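# cohortlink

Tracking what happens to HIV-positive adolescents **after** they are formally
transferred out of their HIV-care facility, using deterministic record
linkage across routine health-information streams.

## The problem

In decentralized HIV programmes, adolescents on antiretroviral therapy (ART)
are frequently transferred from specialist paediatric facilities to primary
care. From the originating clinic's point of view their follow-up ends at
the transfer-out date, so retention, virologic and immunologic outcomes
after transfer are invisible — unless every facility's visit, laboratory and
pharmacy systems share one patient identifier, in which case the patient's
post-transfer record can be reassembled by linkage. `cohortlink` implements
that analysis as a reusable pipeline:

1. **records_io** — typed readers/writers for the three delimited tables
   (cohort, events, duplicate-identifier map), validation, and transitive
   duplicate resolution producing one canonical event stream per patient.
2. **ascertainment** — the core classifier. *Successful transfer* is a
   record (visit, lab or pharmacy) at a facility other than the origin,
   strictly after the transfer-out date; the first such record is the
   linkage event. *Retention at year t ∈ {1,2,3}* is ≥1 visit within ±183
   days of (successful-transfer date + t·365 days), assessed only in
   patients with ≥ t + 0.5 years of potential follow-up before database
   closure. HIV-RNA/CD4 at year t are the measurements closest to the
   anniversary within the same window, flagged as suppressed (<400
   copies/ml) or CD4 >500 cells/µl.
3. **source_sensitivity** — re-runs the classifier per data-source subset
   (visits / lab / pharmacy / all) to show how ascertainment depends on
   which streams are available.
4. **stats_report** — exact Clopper–Pearson intervals, exact McNemar and
   Wilcoxon signed-rank paired tests, chi-square age-group comparisons, the
   adjusted logistic model of transfer success, and table/figure assembly.
5. **synthetic_cohort** — a generator emulating the linked provincial
   tables (transfer-success probability, log-normal linkage delay,
   visit/attrition process, declining lab completeness, per-source capture,
   duplicate identifiers, out-of-province transfers), with a latent `truth`
   table for parameter-recovery testing.

## Worked example

```bash
cohortlink simulate --n 460 --seed 7 --out demo
cohortlink report --patients demo/patients.csv --events demo/events.csv \
                  --duplicates demo/duplicates.csv --out demo_report
```

The simulator prints the latent truth it generated:

```
wrote 460 patients, 19348 events, 4 duplicate pairs to demo
             metric  numerator  denominator  proportion
            success        366          460    0.795652
success_within_18mo        351          366    0.959016
        retained_y1        353          366    0.964481
        ...
```

and the report step prints what the pipeline *observed* from the captured
event streams alone:

```
successful transfer: 366/460 = 79.6% (95% CI 75.6-83.2%)
report written to demo_report
```

Here the pipeline recovered every latent success (366/460 = 79.6%, a draw
around the generative value 0.85 × 0.95 = 80.75%), with an observed median
linkage delay of 59.5 (IQR 26–138) days against a configured log-normal
median of 56 — slightly right-shifted because an uncaptured linkage visit
defers detection to the next captured contact. `demo_report/` contains
`table1.csv` (characteristics by transfer success), `table2.csv` (adjusted
odds ratios), `table3.csv` (per-source sensitivity), `figure2.csv`
(retention/suppression/CD4 per year, overall and by age band 10–14 vs
15–19, every percentage with its numerator and denominator) and
`summary.json`.

The same operations are available as a library:

```python
from cohortlink import AnalysisConfig, run_pipeline, proportion_ci
from cohortlink.synthetic_cohort import CohortGenConfig, generate

gc = generate(CohortGenConfig(n_patients=460, seed=7))
outcomes, assessments = run_pipeline(gc.patients, gc.events, gc.duplicates,
                                     AnalysisConfig())
k = sum(oc.success for oc in outcomes.values())
print(proportion_ci(k, len(gc.patients)))
# ProportionCI(numerator=366, denominator=460, point=79.565..., lower=75.586..., upper=83.158...)
```

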