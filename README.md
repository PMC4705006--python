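# habsi

Automated surveillance and classification of **healthcare-associated
bloodstream infections (HABSI)** from flat-table electronic-medical-record
extracts, with a ground-truth synthetic cohort generator and the full
diagnostic-test evaluation machinery.

Hospital infection-control programs traditionally find HABSIs by having
infection control personnel read microbiology reports and charts — accurate
but slow and labor-intensive. A rule-based system can screen the same data
streams daily and flag candidate infections for human confirmation. This
package implements such a rule engine end to end, for epidemiologists and
informaticists who want a tested, configurable reference implementation
that can be validated against a labeled cohort before being pointed at
real exports.

## The rules

* **Episode linkage.** Re-admissions within 2 calendar days of discharge are
  linked to the previous stay and treated as one hospitalization episode.
* **Hospital-acquired rule.** A blood culture qualifies when its specimen
  log-in time (the proxy for collection time and infection onset) is
  **≥ 48 h** after admission of the merged episode.
* **Organism confirmation.** A recognized pathogen in any draw confirms the
  culture. A common skin commensal (coagulase-negative staphylococci and
  kin) confirms only when the same organism grows in ≥ 2 separate draws
  logged within 2 days *and* a vital-sign flag (fever strictly > 38.0 °C,
  hypothermia, age-banded tachycardia/tachypnea) is raised within ±24 h of
  the first draw.
* **Clinical sepsis (CSEP).** Signs plus a new antimicrobial order within
  48 h, with no blood-culture growth within ±48 h and no positive culture
  from another site within ±7 days.
* **Deduplication.** Candidates within 48 h merge into one (possibly
  polymicrobial) event; a repeat of the same organism within 14 days is
  persistent BSI, absorbed into the existing event.
* **Classification.** CSEP → SEC (matching organism at another site within
  ±7 days) → PRIM_CRBSI (central line in the 48-h lookback *and* concordant
  catheter-tip culture) → PRIM_CLABSI (line, no tip evidence) → PRIM_OTHER.
* **Recall day.** Laboratory report revisions later than 7 days after the
  final report are never applied — deliberately modelling a system that
  stops re-reading old reports, a known false-positive source.

Detection is evaluated per patient as a diagnostic test: sensitivity
Se = TP/(TP+FN), specificity Sp = TN/(TN+FP), PPV, NPV with exact
Clopper–Pearson 95 % CIs, and chance-corrected agreement by Cohen's
κ = (p_o − p_e)/(1 − p_e).

## Worked example

```sh
python examples/evaluate_performance.py
```

```
evaluated patients: 17994
sensitivity   98.16%   (95% CI 94.72-99.62)
specificity   99.96%   (95% CI 99.92-99.98)
ppv           95.81%   (95% CI 91.55-98.30)
npv           99.98%   (95% CI 99.95-100.00)
kappa          0.97    (95% CI 0.95-0.99)
```

A month of hospital-wide surveillance (17,994 evaluated patients, 163 true
HABSIs): the system caught 160 of 163 cases while raising only 7 false
alarms — high sensitivity and NPV mean little is missed, the 95.8 % PPV
means nearly every alert survives human review, and κ ≈ 0.97 is
near-perfect agreement with the reference standard.

The other examples each exercise one capability:
`simulate_cohort.py` (synthetic cohort with planted truth),
`detect_and_classify.py` (a hand-built CRBSI patient with a persistent
repeat culture), `monthly_surveillance_report.py` (monthly incidence /
classification-mix / confirmation-delay tables).

The same flows are scriptable from the shell:

```sh
habsi simulate --seed 7 --n-patients 2000 --out cohort/
habsi detect   --in cohort/ --out events.csv --funnel funnel.json
habsi evaluate --events events.csv --reference cohort/reference_labels.csv --out metrics.json
habsi report   --events events.csv --in cohort/ --start 2012-10-01 --end 2012-10-31 --out monthly.csv
```

## Layout

| path | contents |
| --- | --- |
| `src/habsi/records.py`, `io.py`, `organisms.py` | domain types, CSV schemas, organism catalog |
| `src/habsi/linkage.py` | episode linkage, patient-days |
| `src/habsi/rules.py` | screening rules (48-h clock, signs, commensal corroboration, sepsis pathway) |
| `src/habsi/classify.py` | dedup criteria, classification, pipeline driver |
| `src/habsi/simulate.py` | synthetic cohort generator |
| `src/habsi/metrics.py`, `report.py` | evaluation statistics, monthly tables |
| `src/habsi/cli.py` | `habsi` command-line entry points |
| `docs/methods.md` | models, parameters, numerical choices, limitations |
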