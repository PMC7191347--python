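# Methods

## The phenotyping model

`arfpheno` treats ventilation-therapy phenotyping as a deterministic rule
evaluation over timestamped structured records. Each ICU stay contributes a
stream of records from four tables (treatment paths, medications, nurse
charts, respiratory charts), every record carrying an integer offset in
minutes from ICU admission; negative offsets denote pre-admission events.
The model's core assumptions are:

1. **Modality is recoverable from terms.** Structured menu selections and
   hierarchical treatment paths contain stable substrings ("intub",
   "non-invasive ventilation", device names) that identify the modality of
   each record. Free text appears only in the nurse-chart oxygen-device
   detail field, where high-flow nasal insufflation hides behind dozens of
   spellings; a normalizer (lowercase, punctuation→space, whitespace
   collapse, token search, flow-rate parse) recovers it.
2. **Repetition separates signal from noise.** A single record of a
   modality is as likely a charting slip as a therapy; requiring more than
   one record per (stay, modality) before the modality counts is the main
   guard against spurious entries.
3. **Order, not duration, defines the phenotype.** Whether a noninvasive
   strategy failed (ended in intubation) or followed extubation is read
   from the relative order of the *earliest* NIV and invasive timestamps.
   No duration or gap threshold is imposed; consequently all labels are
   invariant to a constant shift of a stay's offsets.
4. **Corroboration across record types.** Invasive ventilation should
   co-occur with peri-intubation pharmacology (induction agents,
   neuromuscular blockers, continuous sedatives); high-flow support is
   charted by nurses rather than ordered, so an HFNI event requires both
   repeated oxygen-device chart rows and an NIV-family treatment event.
   High-flow charting without any NIV record excludes the stay, mirroring
   the hierarchical treatment coding in which high-flow is a refinement of
   noninvasive ventilation — this also means NIPPV↔HFNI crossover
   phenotypes are structurally impossible, and when both kinds of evidence
   exist the stay is routed to the HFNI branch.

The decision tree then reads: invasive evidence only → P0; NIV only →
P1 (NIPPV) or P2 (HFNI); NIV first then invasive → P3/P4 (failure);
invasive first then NIV → P5/P6 (extubation to NIV). Stays whose events
are all filtered away by the repetition rule are logged as
`SINGLE_RECORD_ONLY` exclusions.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_records` | 2 | records needed per (stay, modality); 2 encodes "more than one record" |
| `tie_rule` | `niv-first` | coincident earliest NIV and invasive timestamps → failure branch; simultaneous charting almost always reflects NIV attempted peri-intubation. Configurable to `invasive-first`. |
| `uncorroborated_invasive_policy` | `retain` | medications *verify* rather than gate invasive ventilation; uncorroborated events are flagged, and a strict mode excludes the stay (`UNCORROBORATED`) |
| `readmission_policy` | `keep-first` | keep unit visit 1 and exclude later visits; `drop-all` removes every stay of a readmitted patient |
| high-flow boundary | 15 L/min | nasal-cannula entries at or above this explicit flow count as HFNI, below as conventional low-flow oxygen |
| adult age | ≥ 18 years | inclusion threshold; ages censored as "> 89" map to the sentinel 90 with a `censored_age` flag, preserving the filter and median arithmetic without inventing a tail distribution |

The lexicon and the peri-intubation drug list ship as YAML package data
and are unit-tested as data; both are replaceable by config files of the
same schema. Multi-transition stays (e.g. NIV → intubation → NIV again)
are classified by the **first** NIV-vs-invasive transition — repeated
sequences are a known charting-error mode, and the first transition is the
one that distinguishes failure from extubation — with the transition count
logged per stay so downstream users can audit them.

## The synthetic cohort generator

The source data for this class of algorithm is access-controlled, so the
generator emits the same five-table schema with ground-truth labels. Per
requested stay it samples demographics against per-phenotype targets —
truncated normal for age (bounds 18–90) and APACHE (≥ 0) with
σ = IQR/1.349, log-normal for ICU length of stay with
σ = asinh(IQR/2m)/0.6745 so the median is exact — whose defaults are the
published cohort's medians/IQRs, mortality and sex/ethnicity proportions.
Distribution families are an implementation choice: the classifier only
consumes record order, so marginal medians/IQRs are all that need to be
faithful. It then lays down the record stream that realizes the phenotype:
invasive blocks (2–4 hierarchical treatment rows + respiratory-chart rows
+ two peri-intubation medication rows), NIPPV blocks (2–4 NIV treatment
rows), high-flow blocks (NIV treatment rows plus 2–4 nurse-chart
oxygen-device rows, canonical or variant spelling), ordered strictly for
the failure/extubation phenotypes. 7.4% of stays (configurable) start
therapy before ICU admission, i.e. at negative offsets.

Noise processes are off by default — the error modes are known but their
real-world rates are not, so the noise-free stream is the reference
condition — and model, when enabled: one spurious record of an unused
therapy (`p_spurious_single_record`), continued recording of the prior
therapy after a switch (`p_continued_recording`, realized as 1–3 extra
rows of the pre-switch therapy after the switch time), missing
corroborating medications (`p_missing_medication`), high-flow spelling
variants (`p_hfni_variant_spelling`, default 0.5), and extra
NIV→invasive→NIV repeat sequences (`n_repeat_sequences`). All randomness
derives from a single `numpy` generator seed; a fixed config yields
byte-identical CSVs.

What passing tests on this generator do **not** show: robustness to the
free-text chaos of real nurse charting beyond the shipped variant list, to
inconsistent treatment-record semantics across hospitals, or to data-entry
errors that produce *repeated* wrong records (which defeat the
single-record guard by construction). The generator's noise processes are
stylized single-cause versions of the real failure modes.

## Validation machinery

Stratified sampling draws ⌈fraction·n⌉ stays per phenotype (deterministic
per seed). Metric definitions are standard: per-class precision
TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean; micro-averages pool
TP/FP/FN (and equal accuracy for exhaustive single-label output — asserted
on every report); macro-averages weight classes equally; weighted averages
weight by true-class support. All three are reported explicitly because a
bare "weighted average" is ambiguous. Zero-division precision (a class
never predicted) is defined as 0 with a warning. The computation is
delegated to scikit-learn; the tests pin it to a hand-enumerated 3-class
confusion-matrix oracle. Quartiles use linear interpolation throughout, so
the descriptive tables are reproducible to the digit.

## Numerical and degenerate-input choices

- Offsets are integers (minutes); fractional inputs truncate toward zero
  with a row-level warning, unparsable ones are skipped (or fatal in
  strict mode) with diagnostics naming table and row.
- Blank offsets are *missing*, not errors: stays whose ventilation records
  all lack timestamps are excluded (`NO_TIMESTAMPS`) rather than dropped
  silently; a single timestamped record family keeps the stay eligible.
- Exclusion precedence is fixed (MINOR > READMISSION > NO_VENT_RECORDS >
  LOW_FLOW_ONLY > NO_TIMESTAMPS) so each stay gets exactly one reason and
  the included/excluded sets always partition the input.
- Empty tables, empty classes and zero denominators are defined outcomes
  (empty outputs, zero contribution, `None` rates) rather than errors.
- Records referencing unknown stays are dropped with a logged diagnostic.

## Problem sizes

The default test and reproduction runs use 10 stays per phenotype for
exact-recovery checks (70 stays, ~500 records), exhaustive enumeration of
135 modality-subset × offset-ordering cases against the decision-tree
oracle, and 2,000 stays per phenotype (14,000 stays) for generator
marginal fidelity, where sample medians land within a few percent of the
configured targets. These sizes were chosen as the smallest at which each
property is sharp: exact recovery and enumeration need no replication, and
median fidelity at n=2,000 bounds sampling error near 2–6%.

## Known limitations

- The shipped lexicon covers the terms documented for one tele-ICU export;
  other systems will need lexicon config files of their own.
- Pre-ICU intubation intent (patients brought to the ICU to be intubated)
  is not separated from in-ICU NIV failure; the 0.8%-scale early-failure
  subgroup is left to downstream analysis.
- Readmissions are excluded, not modeled as their own cohort.
- The manual chart-review reference standard itself cannot be reproduced;
  validation here is against synthetic ground truth plus the published
  derived rates.
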