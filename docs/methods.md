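# Methods

This note documents the models and procedures implemented in
`weightclean`, the defaults chosen where the published rule descriptions
are incomplete, what the synthetic generator does and does not emulate,
and the numerical conventions that make every run reproducible.

## Data model

All computation happens on whole-day offsets from each patient's index
date; windows are closed integer intervals, the collection window
defaulting to [−730, +730] days. Raw vitals strings are parsed by
stripping every character except digits, decimal separators and signs; a
single comma with no period is read as a European decimal point, and a
string with more than one surviving separator or no digits parses to
"absent" (logged, never raised). Negative parsed weights are preserved at
ingestion — raw EHR extracts demonstrably contain implausible values, and
deciding what is implausible is exactly the cleaning algorithms' job.

Height is collapsed to one value per patient: the modal recorded value,
with two special cases — a patient with exactly two recorded values takes
the later-dated one, and a modal tie among three or more records is
broken toward the most recently recorded tied value (a consistent
extension of the two-value rule). BMI is weight (kg) / height (m)².

Every cleaning run returns a `CleanResult` whose exclusion ledger assigns
each removed record a reason code from a fixed enumeration and the step
that removed it; for non-aggregating rules, retained ∪ excluded is an
exact partition of the input, which the test suite asserts on randomized
inputs.

## The twelve rules: reconstruction choices

The cutoff values, window widths and thresholds follow the published
descriptions. Where a description under-determines the computation, the
following choices were made (all exposed in `AllDataConfig` /
`PeriodConfig`):

* **Within-patient statistics** use the sample SD (n−1). Patients with
  fewer than two records have no SD and skip SD-based steps; the 3-SD
  rule (`chan_raffa`) additionally requires three surviving records. The
  3-SD rule is computed within patient by default (that is what groups
  these rules conceptually); a cohort-wide variant is a config switch.
  Both it and the residual rule are single-pass — no refit after removal.
* **`maguen`'s conditional residual** comes from a linear mixed model
  with population intercept and slope plus correlated per-patient random
  intercept and slope (time in years), fitted by REML via statsmodels
  `MixedLM`; the conditional residual is observed minus the
  patient-specific (BLUP) fitted value. The threshold 10 is interpreted
  in kilograms and is configurable. Degenerate inputs (fewer than two
  patients with two or more records) or a singular/non-converging fit
  fall back to independent per-patient OLS lines, flagged
  `ols_fallback` in the result.
* **`breland`'s ratio bounds** are not printed in the source; the
  defaults [2/3, 3/2] are a documented reconstruction, closed at the
  bounds (a ratio of exactly 1.5 survives). A record is removed when its
  ratio to *every* available time-ordered neighbor falls strictly outside
  the bounds. Because a spike makes its innocent neighbors' ratios
  implausible too, the screen removes interior records rejected by both
  neighbors first and re-evaluates on the spliced series until stable;
  only when no interior record is flagged may a flagged endpoint
  (single-neighbor) be removed. This makes an isolated spike — and only
  the spike — disappear from a (100, 160, 100) series.
* **`maciejewski`'s rolling rule** is given only conceptually in the
  source; the reconstruction slides a 5-record window per patient in
  time order, flags a window when its sample SD exceeds
  max(3 kg, 10% of the window mean), removes the record farthest from
  the flagged window's median (ties remove the larger weight), and
  repeats until no window is flagged. Patients with fewer records than
  the window pass through unchanged.
* **`littman`'s two SD clauses** are combined so the CV condition gates
  the deviation rule: only when SD > 10% of the mean are records with
  |w − mean| > SD removed; both inequalities strict, computed once.
* **Anchors** default to days 0/182/365; "closest to anchor" ties break
  toward the earlier day, then the lower record id. `rosenberger`'s K
  defaults to 2 with ±30-day windows at 182-day spacing across the whole
  collection window (both directions from the index). `kazerooni_lim`'s
  window width is not printed in the source; ±30 days is the default.
* **`noel`'s fiscal quarters** start in October (the convention of the
  system the rule comes from); calendar quarters via
  `fiscal_year_start_month=1`. Patient-quarter medians are anchored at
  the quarter midpoint (start + 45 days) for downstream window
  extraction; `jackson`'s window means anchor at their anchor day.
* **The two change caps** differ deliberately: `goodrich` drops the
  whole patient when any consecutive between-period change exceeds
  45 kg, while `janney` drops only the later record of the offending
  pair and continues the walk from the kept one — matching the
  patient-level vs. record-level phrasing of the two source rules.

## Outcome metrics

Baseline weight is the cleaned measurement (or aggregate, mapped to its
period day) on the day closest to the index within a ±30-day window for
the predictor analysis and ±60 days for the weight-change analysis; the
follow-up weight repeats the rule at index + 365 days. Percent change
uses baseline as denominator; a 0 kg baseline (retainable by the
cutoff-free rules) yields a missing outcome rather than a division. The
≥5% loss/gain thresholds are inclusive. Facility rates are unadjusted
percentages among patients with a non-missing outcome, ranked descending
with ties broken by facility id; facilities with no eligible patients are
flagged and unranked. The predictor harness is a logistic regression of
the binary outcome on weight (intercept + one slope), reporting the
per-kg odds ratio with a Wald 95% CI; degenerate outcomes and complete
separation raise a named error.

## Synthetic generator

The generator emulates the marginals of a large primary-care cohort:

* visit counts: negative binomial with mean 12.2 and SD 24.9
  (dispersion from the moment identity k = μ²/(σ²−μ)), floored at 2,
  with 5% of patients forced to a single measurement;
* baseline weight: normal(94.3, 22.0) kg truncated below at 35 kg;
* three trajectory classes (loss/maintain/gain) with probabilities
  (0.15, 0.70, 0.15) and linear slopes centered at −1.5 / 0 / +2.2 kg
  per 365 days (SDs 1.0 / 0.3 / 1.0) — class probabilities are a
  package choice, as only the slope centers and the smallness of the
  loss class are published;
* measurement noise SD 1.5 kg; weights recorded to 0.1 kg; visit days
  uniform over the window; heights ~ normal(1.76, 0.07) m truncated to
  [1.45, 2.05]; 10 facilities assigned at random; index dates uniform
  over a calendar year.

Contamination rates default to sub-1% per type (extreme 0.2%, pound-entry
0.2%, digit typo 0.1%, same-day duplicate 0.4%): gross weight errors are
rare in practice, and the benchmark is only meaningful if the clean bulk
dominates. Extreme draws span [0, 700] kg with mass on both tails, exact
0 and 674 included, plus a 227–340 kg slab that sits inside the widest
cutoffs but outside the narrowest, so rules disagree on it by
construction. `extreme_avoid_kg` restricts draws to fall outside a given
interval when a test needs analytically forced removal. Every corrupted
record stores its true value and label, so recall/specificity are exact.

What the generator does **not** emulate: per-facility case-mix beyond
random assignment, non-linear or pregnancy-related trajectories, visit
clustering around care episodes, the extreme heavy tail of measurement
counts (one real patient had thousands), or correlated
contamination (e.g. a scale mis-calibrated for a whole clinic-day).
Passing tests therefore demonstrate correctness of the rules and the
relative behavior of the algorithm families under realistic marginals —
not performance guarantees on any particular health system's data.

## Comparison harness and bootstrap

All algorithms run independently on the same immutable cohort; the `raw`
pseudo-algorithm is registered alongside the twelve so every table has
the no-cleaning reference. For aggregating rules, the descriptive table
counts contributing raw measurements for retention but computes moments
on the aggregate values.

The bootstrap resamples patients with replacement (default 1,000 patients
× 100 replicates); a patient drawn k times contributes all records k
times, relabeled so within-patient rules treat the copies independently.
One shared resample per replicate is processed by every algorithm, for
comparability. Replicate means and sample SDs of retained weights are
summarized by the median and empirical 80%/95% quantile intervals using
the type-7 (linear-interpolation) quantile convention. With a single
replicate the "interval" collapses to that replicate's statistic exactly,
and constant-weight cohorts give SD intervals of exactly [0, 0] — both
asserted in tests.

## Problem sizes and numerics

Test and acceptance runs are sized for a single CPU: oracle-equivalence
checks use 200 random mini-cohorts (≤10 patients × ≤10 records) against
naive loop-based re-implementations with exact record-set equality;
contamination-recall runs use 2,000 patients; the mean-stability pattern
(retained means within 2 kg while retention spans > 40 percentage points)
uses 10,000 patients, chosen so the smallest retained subgroup's sampling
error is well inside the band being tested; spike-recovery uses 500
patients with +20 kg single-visit spikes on patients having ≥5
measurements (with ≤3 visits, a random-slope model can absorb a spike
into the patient's own trajectory, so sparse patients are not a fair
test of a residual rule); CI calibration uses 200 replicates at n=5,000.
The mixed model is fitted once per cleaning run by L-BFGS under REML; on
noise-free data its residuals are zero only to optimizer tolerance
(~1e-4 kg), while the per-patient OLS path is exact to machine precision
— tests assert accordingly. In the oracle-equivalence suite `maguen`
runs on its OLS path, since a mixed model has no "naive" independent
re-implementation; the mixed path is validated by the spike-recovery
simulation instead.

## Known limitations

* The rules are reconstructions from published summaries, not the
  original studies' code; parameters left unprinted (Breland ratios,
  Maciejewski thresholds, Kazerooni windows, Rosenberger's K) are
  explicit config defaults, and conclusions sensitive to them should be
  re-run across plausible settings.
* `evaluate_cleaning` is record-level and refuses aggregating rules;
  patient-level evaluation of `jackson`/`noel` must go through the
  outcome metrics.
* Same-day duplicate measurements are preserved at ingestion and left to
  each algorithm, none of which targets them specifically.
* The latent-class trajectory analysis that motivates some of these
  comparisons is out of scope; the generator's linear classes exist to
  give the cleaning rules a known signal, not to fit trajectory models.
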