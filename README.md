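# ardscreen

Retrospective case-finding for the acute respiratory distress syndrome (ARDS)
in ICU electronic health records, built around a **physiologic persistence
rule**: a patient screens positive when the Berlin physiologic criteria —
PaO₂/FiO₂ (P/F) < 300 mm Hg together with PEEP ≥ 5 cm H₂O — are *sustained*
for at least 72 h (or ≥ 48 h with death on the third day), rather than met at
a single time point. Transient hypoxaemia is extremely common in critically
ill patients, so single-time-point "modified Berlin" screens capture a
heterogeneous acute hypoxaemic respiratory failure (AHRF) population and
inflate apparent ARDS prevalence; requiring persistence enriches strongly for
adjudicated ARDS.

The package is aimed at researchers assembling ARDS cohorts from ICU
databases (MIMIC-IV-style extracts) who need a tested, configurable screen
plus the statistics to validate it against expert chart review.

## What it does

- **Harmonisation** (`ardscreen.harmonize`) — pairs each P/F ratio with the
  nearest-in-time PEEP (±2 h tolerance, ties toward the earlier value) and
  aggregates into 24-h windows anchored at ICU admission; a window
  *qualifies* when its mean P/F contemporaneous with PEEP ≥ 5 cm H₂O is
  below 300 mm Hg.
- **Screening** (`ardscreen.screen`) — finds the first unbroken run of
  qualifying windows per stay and grades persistence into nested cohorts:
  any-time ⊇ ≥24 h ⊇ ≥48 h ⊇ ≥72 h (the 72-h class includes the ≥48 h +
  death-on-day-3 variant). The first qualifying stay per subject is retained.
- **Enrichment** (`ardscreen.enrich`) — Boolean keyword rule-sets with
  negation masking run against radiology report text (0–48 h after onset, or
  any time), and ICD-9/10 code-set matching. Six illustrative nested
  rule-sets (T1 narrowest … T6 broadest) and an illustrative code-set
  ({J80, 518.82, 518.5, J96.00*}) ship as configurable defaults.
- **Evaluation** (`ardscreen.evaluate`) — confusion matrices against
  three-class adjudication (ARDS / possible ARDS / non-ARDS AHRF),
  sensitivity/specificity/PPV/NPV/accuracy with Wilson (default) or
  Clopper–Pearson intervals, Cohen's κ, finite-population margins of error
  for review-sample sizing, per-window PPV gradients, and 2×2 odds ratios.
- **Synthetic cohorts** (`ardscreen.synth`) — a seeded generator producing
  stays, blood-gas/PEEP/ventilator events, report text, ICD codes and latent
  adjudication labels with calibrated operating characteristics, so the full
  pipeline is testable without credential-gated clinical data.

## Worked example

```python
import ardscreen as a
from ardscreen.screen import cascade_counts, in_window
from ardscreen.enrich import default_rulesets, enrich_cohort
from ardscreen.evaluate import confusion, dx_metrics

bundle = a.simulate_cohort(a.whole_icu_calibration(n_subjects=2000, seed=42))
results = a.screen_cohort(bundle)
print("cascade:", cascade_counts(results))

h72 = results[in_window(results, "72")]
labels = bundle.labels[bundle.labels["stay_id"].isin(set(h72["stay_id"]))]
print(f"72-h cohort: {len(h72)} subjects, "
      f"adjudicated ARDS fraction {(labels['label'] == 'ARDS').mean():.3f}")

flags = enrich_cohort(bundle, h72, default_rulesets()["T3"])
m = dx_metrics(confusion(labels, dict(zip(flags["stay_id"], flags["icd_hit"]))))
print(f"ICD enrichment: sens {m.sensitivity.value:.2f} "
      f"({m.sensitivity.ci_low:.2f}-{m.sensitivity.ci_high:.2f}), "
      f"spec {m.specificity.value:.2f}")
```

Output:

```
cascade: {'anytime': 1999, '24': 1968, '48': 701, '72': 662}
72-h cohort: 662 subjects, adjudicated ARDS fraction 0.503
ICD enrichment: sens 0.77 (0.72-0.81), spec 0.48
```

Reading it: in a whole-ICU mixture where about two thirds of screen-positive
subjects are fast resolvers (hypoxaemia clearing within 48 h), nearly every
subject meets the criteria at some point, but only a third sustains them for
72 h; within that enriched cohort roughly half carry a definite ARDS label,
and ICD codes are sensitive (0.77) but unspecific (0.48) — codes alone cannot
replace adjudication.

The same workflow is available from the shell:

```bash
ards simulate --n 2000 --seed 42 --preset whole-icu --out data/
ards screen   --data data/ --out out/ --window 72
ards enrich   --data data/ --screen out/screen_results.csv --out out/
ards evaluate --data data/ --screen out/screen_results.csv \
              --flags out/enrich_flags.csv --out out/metrics.json
ards report   --data data/ --screen out/screen_results.csv --seed 42
```

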