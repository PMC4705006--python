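# Methods

## Problem and model

A healthcare-associated bloodstream infection (HABSI) is operationalized
here, as in hospital practice, through a cascade of deterministic rules over
routine data streams: hospitalization intervals, culture results keyed by
laboratory log-in time, nursing vital signs, device intervals, and
antimicrobial orders. The package is a rule *engine*, not a statistical
classifier: every decision is reproducible from the input tables and the
configuration, and every stage (linkage → candidate screening → dedup →
classification → evaluation) is exposed separately.

Specimen **log-in time** stands in for collection time and infection onset
throughout. This is an administrative proxy; a delayed courier makes a
community-onset culture look hospital-acquired (one of the error modes the
synthetic cohort can plant).

## Rule parameters

All thresholds live in `RulesConfig` (YAML-overridable); defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `min_hai_hours` | 48 | hospital-acquired clock, inclusive, from the *first* admission of a merged episode |
| `readmit_gap_days` | 2 | calendar-date re-admission linkage window, inclusive |
| `fever_c` | 38.0 | fever is strictly `> 38.0 °C`; exactly 38.0 is not fever |
| `hypothermia_c` | 36.0 | strictly below |
| `adult_hr_bpm` / `adult_rr_pm` | 90 / 20 | tachycardia / tachypnea cut-offs (strictly above) |
| `infant_hr_bpm` / `infant_rr_pm` | 180 / 60 | pediatric cut-offs, applied up to `infant_age_days` = 365 |
| `commensal_window_days` | 2 | max calendar-date spread between corroborating commensal draws |
| `sign_window_hours` | 24 | sign flag must sit within ± this of the first commensal draw |
| `recall_days` | 7 | report revisions later than this after the final report are ignored |
| `csep_blood_window_hours` | 48 | sepsis pathway: no blood-culture growth within ± this |
| `csep_abx_hours` | 48 | new antimicrobial must start within this after the sign |
| `csep_nonblood_window_days` | 7 | no positive non-blood culture within ± this |
| `polymicrobial_hours` | 48 | candidate onsets within this merge into one event |
| `persistent_days` | 14 | same-organism repeat within this of the last isolate is absorbed |
| `secondary_window_days` | 7 | SEC site-match window around onset |
| `line_lookback_hours` | 48 | central line must overlap `[onset − 48 h, onset]` |

The re-admission window, the 48-hour rule (inclusive), and the strict fever
inequality are fixed points of the surveillance definition; the
deduplication, secondary-attribution, and line-association windows follow
NHSN-era conventions and are deliberately configurable because sites differ.

### Design choices where the design was open

* **Commensal status** is decided purely by membership of the organism code
  in a configurable set, defaulting to the NHSN-style common commensals
  (coagulase-negative staphylococci, *Micrococcus*, non-diphtheriae
  *Corynebacterium*, non-anthracis *Bacillus*, *Cutibacterium*,
  viridans-group streptococci, *Aerococcus*).
* **Clinical sepsis exclusion uses any blood-culture growth**, confirmed or
  not. A single commensal draw is not a confirmed BSI, but it is also not a
  culture-negative sepsis picture; excluding it keeps the pathways mutually
  exclusive and means an uncorroborated commensal case degrades to a miss
  rather than re-surfacing under a different label.
* **Catheter-tip specimens are excluded from the secondary-site match.** A
  colonized tip is laboratory evidence about the line (CRBSI), not a second
  infected body site; otherwise every tip-concordant event would be
  classified SEC under the CSEP > SEC > CRBSI precedence.
* **Persistent-BSI gap is rolling**: measured from the most recent isolate
  already absorbed into the event, matching the "continuing infection"
  semantics (day 3 → 13 → 26 of the same organism is one event).
* **Patient-day counting**: admission day counts, discharge day does not
  (standard census convention).
* **Classification precedence** is total and deterministic:
  CSEP > SEC > PRIM_CRBSI > PRIM_CLABSI > PRIM_OTHER.

## Daily screening vs batch

`detect_candidates(..., as_of_ts=day)` sees only reports finalized by
`day` and revisions up to `day` (and within the recall window). Culture-
pathway candidates are stable: once a report is finalized and in-window
revisions have been applied, the candidate persists with the same onset as
the as-of date advances. A *sepsis* candidate is inherently provisional — it
can retract when a blood culture drawn in its window later finalizes with
growth. Consequently the invariant tested is convergence: a screen run at
or after the last finalization-plus-recall date equals the batch run, and
finalized culture candidates never retract.

## The synthetic cohort

`CohortConfig` defaults describe a one-month, 10,000-patient surveillance
period with an HABSI rate of 14.7 episodes/1000 patients, a 1.23 %
single-draw specimen rate, 2 % single-draw commensal contaminants, 5 %
re-admissions, and a subtype mix of 15 % CRBSI, 20 % CLABSI, 35 % other
primary, 20 % secondary, 10 % clinical sepsis (no published mix exists;
these were fixed once as a plausible tertiary-care split). Planted cases
satisfy every rule by construction — onset ≥ 48 h into the episode (or
early in a linked re-admission, exercising the episode clock), two-set
draws 50 min apart, fever bursts within the sign window, antimicrobial
starts, devices and tip/urine cultures matching the intended subtype, and
persistent repeat draws that must be absorbed.

Planted negatives are the near-misses the rules exist to reject:
community-onset cultures (< 48 h), single-draw commensals without
corroboration, fever without antimicrobials, antimicrobials without fever,
incidental central lines, and — when enabled — reports revised *after* the
recall day, which the detector deliberately never re-reads (false
positives, and nothing but false positives). Two further knobs degrade true
commensal cases into misses: `commensal_single_draw_prob` withholds the
corroborating draw and `fever_miss_prob` keeps the temperature at or below
38.0 °C (the antipyretic-style miss); both produce false negatives only.

Baseline vitals are drawn strictly below every screening threshold
(Gaussian, clipped), so each detection or false alarm is attributable to a
planted mechanism. That is a deliberate idealization: real nursing streams
contain incidental fevers and tachycardias in patients who are *also* on
antibiotics, so a clean-cohort sensitivity/specificity of 1.0 demonstrates
that the engine implements the rules exactly — not that the rules would
achieve that performance on real data. Ward structure, organism
frequencies, and lengths of stay are simple categorical/exponential models;
transfers, free-text symptoms, antibiograms, and time-to-positivity are not
modelled.

## Evaluation statistics

Patient-level confusion is set algebra over detected / reference /
population patient-id sets; any labelled patient outside the population is
a fatal error. Proportions get exact Clopper–Pearson 95 % CIs (via the beta
distribution); Cohen's κ uses the 2×2 closed form with the large-sample
standard error `sqrt(p_o(1−p_o)/(N(1−p_e)²))`, clipped to [−1, 1]. The CI
method for the published proportions is not documented anywhere
authoritative, so printed CI bounds are displayed but not treated as exact
targets. Display rounding is 2 decimals, half-up (`round_half_up`), applied
only at the reporting edge; full precision is carried internally.

Confirmation delay is whole days from onset date to confirmation date,
grouped by month of confirmation; the period summary is the **unweighted
mean of monthly means** (a busy month does not dominate), with the SD taken
across monthly means. Incidence is `1000 × events / denominator` for
patient or patient-day denominators, with undefined strata flagged rather
than NaN-propagated. Pearson correlation comes from `scipy.stats.pearsonr`
with degenerate series rejected.

## Problem sizes and numerical notes

The test suite exercises cohorts of 300–10,000 patients; the acceptance
script uses the full 10,000-patient month (a few seconds end to end). All
randomness flows from a single integer seed through
`numpy.random.default_rng`; with a fixed seed the simulate → detect →
evaluate chain is byte-identical across runs, which the suite asserts at
file level. Timestamps are minute-resolution, timezone-naive; all window
comparisons are inclusive at both ends unless described otherwise
(fever and the rate thresholds are strict inequalities; the 48-h rule is
inclusive at exactly 48 h; a re-admission gap of exactly 2 calendar days
merges).

## Known limitations

* Rules reconstruct hospital practice from its published description plus
  NHSN conventions; site-specific rule books differ in the device and
  sign/symptom lists, and those lists are configuration here.
* No free-text/NLP symptom extraction (chills, apnea) and no
  antipyretic-adjusted fever inference — the fever criterion misses
  treated-fever cases by design.
* CRBSI evidence is catheter-tip concordance only; differential
  time-to-positivity is not in the data model.
* Ward-level attribution of onset is not implemented.
* Human confirmation (`confirmation_ts`) is an input carried through for
  delay statistics; the package does not model the review workflow.
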