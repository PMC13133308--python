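# Methods

This note records the scientific and numerical choices behind `ardscreen`:
what the screen computes, what the synthetic cohorts emulate (and what they
do not), and where the design was genuinely open.

## The screening model

The screen operationalises the physiologic component of the Berlin ARDS
definition — P/F < 300 mm Hg with PEEP ≥ 5 cm H₂O — with an added
persistence requirement. Its rationale: transient hypoxaemia is ubiquitous
in ICU populations and mostly does not represent ARDS, whereas diffuse
alveolar damage (the histological correlate of ARDS) is uncommon when
hypoxaemic impairment lasts under 72 h. Persistence is therefore an
*enrichment* device, not a case definition: a 72-h screen-positive cohort
still contains substantial non-ARDS AHRF, and screen-negative patients are
never adjudicated, so the pipeline estimates PPV within screened cohorts,
not sensitivity over the whole ICU population.

### Harmonisation

Blood-gas PaO₂ is matched to the FiO₂ of the same draw (identical timestamp
or nearest within 5 min); the resulting P/F point is paired with the
nearest-in-time PEEP within a tolerance (default ±2 h, configurable). Exact
distance ties break toward the *earlier* PEEP — the setting already in
effect. Unpaired points are kept but excluded from window means. PaO₂ is
assumed mm Hg; kPa sources must pre-convert (×7.50062) — deliberately not
automatic, to avoid silent unit guessing. FiO₂ values in (1, 100] are read
as percentages; values above 100 are rejected row-wise.

### Windowing and onset

24-h windows are anchored at ICU admission, not at first hypoxaemia. An
admission anchor is deterministic and independent of the quantity being
detected; anchoring at first hypoxaemia would make the window grid a
function of the screen's own output. Onset is then *defined* as the start of
the first qualifying window. A window qualifies when the mean P/F over
points with paired PEEP ≥ 5 cm H₂O is below 300 mm Hg; a window with no
eligible point is undefined and never qualifies.

### Persistence grading

- ≥24 h = 1 qualifying window, ≥48 h = 2 consecutive, ≥72 h = 3 consecutive
  — duration is counted in whole 24-h windows because the screen itself is
  built from 24-h means.
- The 72-h class also admits 2 consecutive windows with death on the third
  day after onset, operationalised as death_time ∈ [onset+48 h, onset+72 h).
  The half-open right edge keeps the rule disjoint from qualification by
  survival: it can never fire for a patient alive at onset+72 h.
- "Sustained" means consecutive: a broken run restarts the count.
- Only *complete* 24-h windows extend a run. A trailing partial window is
  reported (its mean and qualification are computed) but cannot count as a
  day of persistence — otherwise a patient discharged alive at 50 h with a
  2-h sliver of qualifying data would grade as 72-h persistent. Censoring by
  death is already handled explicitly by the death-on-day-3 rule, so this
  choice only affects survivors discharged mid-window.
- Patients dying within 48 h of onset are flagged (`excluded_early_death`)
  mirroring the design exclusion of early deaths from persistence cohorts.
- For subjects with multiple stays, the first stay (by admission time)
  meeting any screening criterion represents the subject.

The four cohorts nest by construction (72 h ⊆ 48 h ⊆ 24 h ⊆ any-time); this
monotonicity is asserted as a property test and is the backbone of the PPV
gradient across windows.

### Keyword and ICD enrichment

Keyword rules are Boolean expressions (AND/OR/NOT) over case-insensitive
substring patterns; stems like `opacit` deliberately hit inflected forms
without tokenisation-dependent behaviour. Negation masking drops a term
occurrence preceded by a negation cue (`"no "`, `"without "`, `"resolved"`)
within the same sentence; sentences split on `. ; :` — crude but
deterministic, and optional (on by default). Rules are applied in two
windows relative to onset: 0–48 h and any time during admission.

The shipped T1–T6 rule-sets are a *nested illustrative family* of strictly
increasing breadth, and the default code-set {J80, 518.82, 518.5, J96.00*}
is likewise illustrative: published keyword/code lists for this task are not
redistributable here, so both are user-configurable (YAML), and every
accuracy figure the package reports is computed against whatever rules are
supplied. Nesting gives the family a useful testable property: widening a
rule can only add positives.

## Evaluation layer

2×2 accuracy is computed against the definite-ARDS adjudication label. The
intermediate "possible ARDS" category is excluded from 2×2 computations by
default (the convention under which published ICD sensitivity figures such
as 756/993 reproduce exactly); counting possibles as negatives, or widening
the positive definition to ARDS-or-possible, are explicit options. Metrics
with zero margins are undefined (`None`), never 0.

Binomial intervals default to Wilson, with Clopper–Pearson as the exact
alternative; both delegate to `statsmodels.stats.proportion.proportion_confint`
and are cross-checked in tests against an independently coded closed form
and direct Beta-quantile inversion. Wilson endpoints are snapped to exact
0/1 at boundary counts, where the closed form attains them analytically but
floating arithmetic can stray by ~1e-18. Cohen's κ for the three adjudication
categories is computed from the agreement table (p_o = trace/total, p_e from
the margins) so that both components are reported, and is cross-checked
against scikit-learn. The finite-population margin of error
z·√(p(1−p)/n)·√((N−n)/(N−1)) sizes review samples drawn without replacement
from a finite screen-positive population — reviewing 2,000 of 3,940 at
p = 0.5 gives ±1.5%. Odds ratios use the sample (a·d)/(b·c) with a log-scale
Wald interval and a flagged Haldane–Anscombe correction for zero cells.
Report-style rounding is half-away-from-zero. No multiplicity correction is
applied anywhere: the metrics are descriptive.

## Synthetic cohorts

The generator emulates the statistical structure the screen depends on, with
one RNG stream per subject keyed on (seed, subject index) so that enlarging
a cohort never reshuffles existing subjects.

- **Classes.** A latent label per subject: definite ARDS, possible ARDS,
  non-ARDS AHRF, plus FAST_RESOLVER (hypoxaemia clearing within 48 h,
  labelled non-ARDS AHRF). The *within-screen* preset (the default
  calibration) uses the adjudicated 72-h-cohort mixture 49.65 / 6.4 / 43.95%
  with no fast resolvers; the *whole-ICU* preset gives fast resolvers a 65%
  share, reflecting the observed predominance of rapid resolution among
  ever-screen-positive patients.
- **Trajectories.** P/F is log-normal around day-wise class medians
  (ARDS 170/189/196, possible 189/190/199, non-ARDS 196/205/212 mm Hg for
  days 1–3; day-3 values persist). Spreads are matched to published IQRs by
  moment matching, σ = ln(q3/q1)/(2·0.6745). Blood gases are drawn 4×/24 h;
  FiO₂ uniform 0.35–0.80 with PaO₂ back-computed. PEEP is normal around
  class/day medians, clipped at 5 cm H₂O during support. Fast resolvers run
  a low day-1 median (230) then jump to 420 mm Hg *and* lose PEEP support
  after 36 h, so their later P/F points are unpaired — by construction they
  can reach the any-time and 24-h screens but never the 72-h screen.
- **Death.** A per-day discrete hazard per class (small on days 1–2, then
  0.030/0.020/0.056 per day for ARDS/possible/non-ARDS), death time uniform
  within the day, truncating the stay. This loosely reproduces ICU
  mortality around 28% (ARDS) and 35% (non-ARDS) over typical stays and
  yields ~2% early-death exclusions; the timing distribution is invented —
  real death-time dynamics are not modelled.
- **ICD codes.** An ARDS-related code is emitted with probability 0.76 for
  ARDS (the calibrated code sensitivity) and 1−0.47 for non-ARDS (calibrated
  specificity 0.47); possible-ARDS uses 0.65, an interpolant chosen once
  (no published value exists). Unrelated codes are added with probability
  0.4 for realism.
- **Reports.** Every subject gets a neutral baseline report; with a
  class-conditional probability a marker report lands within 0–48 h of
  admission carrying the sentence for the *narrowest* rule level the subject
  emits. A single latent uniform per subject against the cumulative per-rule
  emission ladder makes keyword hits monotone across the nested T1–T6
  family. The T3 rung is calibrated at 0.49 (ARDS) / 0.24 (non-ARDS);
  T1 (0.43/0.22) and T6 (0.77/0.71) anchor the ends and the remaining rungs
  are monotone interpolants chosen once. Negated distractor sentences are
  injected with probability 0.1 to exercise negation masking.

**What passing tests do and do not show.** The generator reproduces
marginal operating characteristics (class mixture, code and keyword
emission rates, daily P/F levels), so recovery tests demonstrate that the
pipeline measures without bias what the data contain. It does not emulate
real EHR pathologies — irregular and informative sampling, charting errors,
unit mixtures within one stay, report language diversity, correlated
comorbidity structure, multiple ICU admissions per subject — so passing
tests say nothing about robustness to those; multi-stay logic is exercised
with hand-built fixtures instead.

One quantitative consequence of the design: 72-h retention differs slightly
by class (non-ARDS trajectories sit closer to the 300 mm Hg threshold and
carry higher early mortality), so the ARDS fraction among screen-positives
drifts ~1–2 pp above the configured 49.65%. The review-sample PPV test
therefore allows a pre-specified ±3 pp band between the screened
population's ARDS fraction and the raw mixture, plus finite-population
sampling error for the 2,000-subject sample itself.

## Problem sizes and numerical details

- Parameter-recovery runs use 20,000 subjects (the acceptance script's
  cohort), giving binomial standard errors near 0.5 pp on the recovered
  rates; recovery assertions use 3 standard errors. Module-level property
  tests use 100–5,000 subjects.
- All interval arithmetic is float hours; timestamps are minute-resolution
  ISO-8601 in files. Tolerance comparisons carry a 1e-12 h guard against
  float rounding at window edges.
- The cohort-level harmonisation/screening paths are vectorised numpy
  re-implementations of the per-stay operations; equivalence against the
  per-stay reference is asserted on randomized cohorts.
- Degenerate inputs: an empty cohort yields an empty result with a zero
  cascade; a stay with no eligible measurements yields all-undefined
  windows; FiO₂ = 0 raises; review samples larger than their pool are
  truncated to the pool.

## Known limitations

- The screen uses the physiologic Berlin component only: no imaging or
  oedema-origin criteria, so it grades AHRF persistence, not ARDS itself.
- Chart adjudication is out of scope; labels are inputs (or latent synthetic
  truth), never outputs.
- kPa blood gases are not auto-detected.
- The shipped rule-sets/code-set are illustrative defaults, not validated
  instruments; site-specific lists should be supplied for real analyses.
- Sensitivity/specificity of the *persistence screen itself* against
  whole-ICU ARDS status is not estimable from screen-positive review alone,
  and the package does not pretend otherwise.
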